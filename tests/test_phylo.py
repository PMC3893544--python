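import itertools
import math

import dendropy
import numpy as np
import pytest

from hgtkit import phylo, synth
from hgtkit.io import MSA, SeqRecord, read_newick


class TestProteinDistance:
    def _msa(self, rows):
        return MSA([SeqRecord(f"r{i}", s, moltype="protein")
                    for i, s in enumerate(rows)])

    def test_identical_rows_zero(self):
        dm = phylo.protein_distance(self._msa(["MKLV", "MKLV"]))
        assert dm.matrix[0, 1] == 0.0

    def test_p_and_poisson_values(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAC"]
        p = phylo.protein_distance(self._msa(rows), correction="p")
        assert p.matrix[0, 1] == pytest.approx(0.1)
        poi = phylo.protein_distance(self._msa(rows), correction="poisson")
        assert poi.matrix[0, 1] == pytest.approx(-math.log(0.9))

    def test_saturated_pair_errors(self):
        with pytest.raises(ValueError):
            phylo.protein_distance(self._msa(["AAAA", "CCCC"]), correction="poisson")

    def test_pairwise_gap_deletion(self):
        dm = phylo.protein_distance(self._msa(["MK-V", "MKLV"]), correction="p")
        assert dm.matrix[0, 1] == 0.0

    def test_distance_increases_with_branch_length(self, ref_db):
        import scipy.stats
        tax = ref_db.taxonomy
        pdm = tax.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tax.tree.taxon_namespace}
        xs, ys = [], []
        for fam in ref_db.families[:15]:
            dm = phylo.protein_distance(fam.alignment, correction="p",
                                        on_saturation="clamp")
            for i, a in enumerate(dm.labels):
                for j in range(i + 1, len(dm.labels)):
                    xs.append(pdm.patristic_distance(taxa[a], taxa[dm.labels[j]]))
                    ys.append(dm.matrix[i, j])
        rho, _ = scipy.stats.spearmanr(xs, ys)
        assert rho > 0.5


def _splits(tree):
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    out = set()
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 2 <= len(side) <= len(leaves) - 2:
            if ref in side:
                side = frozenset(leaves) - side
            out.add(side)
    return out


def _all_topologies(labels):
    """All unrooted leaf-labelled topologies by stepwise addition."""
    if len(labels) == 3:
        yield {"children": [{"leaf": l} for l in labels]}
        return

    def clone(node):
        if "leaf" in node:
            return {"leaf": node["leaf"]}
        return {"children": [clone(c) for c in node["children"]]}

    def edges(node, path=()):
        for i, c in enumerate(node["children"]):
            yield path + (i,)
            if "children" in c:
                yield from edges(c, path + (i,))

    def insert(tree, path, leaf):
        t = clone(tree)
        node = t
        for i in path[:-1]:
            node = node["children"][i]
        old = node["children"][path[-1]]
        node["children"][path[-1]] = {"children": [old, {"leaf": leaf}]}
        return t

    for base in _all_topologies(labels[:-1]):
        for path in list(edges(base)):
            yield insert(base, path, labels[-1])


def _topology_splits(tree, labels):
    ref = sorted(labels)[0]
    out = set()

    def leafset(node):
        if "leaf" in node:
            return frozenset([node["leaf"]])
        return frozenset().union(*(leafset(c) for c in node["children"]))

    def walk(node):
        for c in node.get("children", []):
            s = leafset(c)
            if 2 <= len(s) <= len(labels) - 2:
                out.add(s if ref not in s else frozenset(labels) - s)
            walk(c)

    walk(tree)
    return out


def _ls_fit(tree, labels, D):
    """Least-squares branch lengths for one topology; returns RSS."""
    # collect edges as leaf bipartitions (including terminal edges)
    edge_sets = []

    def leafset(node):
        if "leaf" in node:
            return frozenset([node["leaf"]])
        return frozenset().union(*(leafset(c) for c in node["children"]))

    def walk(node):
        for c in node.get("children", []):
            edge_sets.append(leafset(c))
            walk(c)

    walk(tree)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edge_sets)))
    d = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        d[r] = D[i, j]
        for c, es in enumerate(edge_sets):
            if (labels[i] in es) != (labels[j] in es):
                A[r, c] = 1.0
    b, *_ = np.linalg.lstsq(A, d, rcond=None)
    return float(((A @ b - d) ** 2).sum())


def _random_additive(labels, rng):
    """Distance matrix generated from a random tree with positive lengths."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=len(labels),
        rng=__import__("random").Random(int(rng.integers(1e9))))
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.2, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
    return D, tree


class TestNjTree:
    def test_additive_four_taxon_exact(self):
        # tree: ((a:1,b:2):1,(c:1,d:2)) -> additive matrix
        D = np.array([[0, 3, 3, 4],
                      [3, 0, 4, 5],
                      [3, 4, 0, 3],
                      [4, 5, 3, 0]], float)
        t = phylo.nj_tree(phylo.DistanceMatrix(list("abcd"), D))
        assert _splits(t) == {frozenset(["c", "d"])}
        pdm = t.phylogenetic_distance_matrix()
        tx = {x.label: x for x in t.taxon_namespace}
        for i, a in enumerate("abcd"):
            for j, b in enumerate("abcd"):
                if i < j:
                    assert pdm.patristic_distance(tx[a], tx[b]) == pytest.approx(D[i, j])

    def test_three_taxa_star_exact_lengths(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = phylo.nj_tree(phylo.DistanceMatrix(list("abc"), D))
        lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lens == {"a": 0.0, "b": 2.0, "c": 3.0}

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(ValueError):
            phylo.DistanceMatrix(["a", "b"], D)

    def test_nj_matches_least_squares_best_topology(self, rng):
        """On additive 6-taxon matrices NJ recovers the topology with the
        minimum least-squares fit over all 105 exhaustively enumerated
        unrooted topologies."""
        labels = list("abcdef")
        topos = list(_all_topologies(labels))
        assert len(topos) == 105
        for _ in range(3):
            D, _tree = _random_additive(labels, rng)
            nj = phylo.nj_tree(phylo.DistanceMatrix(labels, D))
            rss = [(_ls_fit(t, labels, D), i) for i, t in enumerate(topos)]
            best_i = min(rss)[1]
            assert _topology_splits(topos[best_i], labels) == _splits(nj)

    def test_matches_independent_nj_implementation(self, rng):
        """Cross-check topologies against scikit-bio's neighbor joining."""
        import skbio
        labels = [f"t{i}" for i in range(7)]
        for _ in range(5):
            D, _ = _random_additive(labels, rng)
            ours = phylo.nj_tree(phylo.DistanceMatrix(labels, D))
            sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
            sk_nwk = str(sk).strip()
            theirs = read_newick(sk_nwk)
            assert _splits(ours) == _splits(theirs)


class TestBootstrap:
    def test_identical_sequences_degenerate(self):
        msa = MSA([SeqRecord(x, "MKLVMKLV", moltype="protein") for x in "abcd"])
        res = phylo.bootstrap_support(msa, n_replicates=10, seed=0)
        assert res.degenerate and res.supports == {}

    def test_same_seed_identical_supports(self, ref_db):
        msa = ref_db.families[0].alignment
        a = phylo.bootstrap_support(msa, n_replicates=30, seed=7)
        b = phylo.bootstrap_support(msa, n_replicates=30, seed=7)
        assert a.supports == b.supports

    def test_supports_in_range(self, ref_db):
        res = phylo.bootstrap_support(ref_db.families[1].alignment,
                                      n_replicates=50, seed=1)
        assert all(0.0 <= v <= 100.0 for v in res.supports.values())

    def test_deep_clean_split_high_support(self):
        """Long alignments with a deep clean split give near-unanimous
        bootstrap support for the true bipartition."""
        t1 = read_newick("((a:0.1,b:0.1):0.4,(c:0.1,d:0.1):0.4);")
        t2 = read_newick("(e:0.1,f:0.1,g:0.1);")
        msa, _ = synth.simulate_divergence_alignment(t1, t2, 0.0, 2.0,
                                                     n_sites=2000, seed=0)
        sub = MSA([r for r in msa.records if r.id in "abcd"])
        res = phylo.bootstrap_support(sub, n_replicates=100, seed=3)
        ab = frozenset(["c", "d"])
        assert res.supports[ab] >= 95.0

    def test_invalid_replicates_rejected(self, ref_db):
        with pytest.raises(ValueError):
            phylo.bootstrap_support(ref_db.families[0].alignment, n_replicates=0)


class TestPlacementTest:
    TREE = "((q:0.1,(d1:0.1,d2:0.1)100:0.2)90:0.5,(r1:0.1,r2:0.1)100:0.3,o:0.6);"

    def test_query_inside_donor_clade_supported(self):
        t = read_newick(self.TREE)
        assert phylo.placement_test(t, "q", ["d1", "d2"], ["r1", "r2"]) == \
            "hgt_supported"

    def test_query_sister_to_recipients_native(self):
        t = read_newick("((q:0.1,(r1:0.1,r2:0.1)100:0.2)90:0.5,"
                        "(d1:0.1,d2:0.1)100:0.3,o:0.6);")
        assert phylo.placement_test(t, "q", ["d1", "d2"], ["r1", "r2"]) == "native"

    def test_low_support_unresolved(self):
        t = read_newick("((q:0.1,(d1:0.1,d2:0.1)100:0.2)40:0.5,"
                        "(r1:0.1,r2:0.1)100:0.3,o:0.6);")
        assert phylo.placement_test(t, "q", ["d1", "d2"], ["r1", "r2"],
                                    min_support=75) == "unresolved"

    def test_missing_query_rejected(self):
        t = read_newick(self.TREE)
        with pytest.raises(ValueError):
            phylo.placement_test(t, "zz", ["d1"], ["r1"])

    def test_synthetic_hgt_genes_place_in_donor_clade(self, ref_db):
        """Planted foreign genes nest with the donor clade; native genes
        with the recipient lineage (easy regime, several seeds)."""
        from hgtkit.pipeline import _align_to_family
        tax = ref_db.taxonomy
        for seed in range(3):
            txm = synth.simulate_recipient_transcriptome(
                ref_db, n_native=2, n_hgt=2, n_contaminants=0,
                emit_retention_isoform=False, seed=seed)
            for i, tid in enumerate(sorted(
                    t for t, lab in txm.truth.labels.items() if lab == "hgt")):
                fam = ref_db.families[2 + i]
                rows = [SeqRecord(tid, txm.truth.proteins[tid], moltype="protein")]
                aligned = _align_to_family(rows, fam)
                boot = phylo.bootstrap_support(aligned, n_replicates=50,
                                               seed=seed)
                assert phylo.placement_test(boot.tree, tid, tax.donor_species,
                                            [tax.sister, tax.recipient]) == \
                    "hgt_supported"
            for i, tid in enumerate(sorted(
                    t for t, lab in txm.truth.labels.items() if lab == "native")):
                fam = ref_db.families[i]
                rows = [SeqRecord(tid, txm.truth.proteins[tid], moltype="protein")]
                aligned = _align_to_family(rows, fam)
                boot = phylo.bootstrap_support(aligned, n_replicates=50,
                                               seed=seed)
                verdict = phylo.placement_test(boot.tree, tid, tax.donor_species,
                                               [tax.sister])
                assert verdict == "native"
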