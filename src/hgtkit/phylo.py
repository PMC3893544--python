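"""Distance-based phylogenetics: NJ trees, bootstrap support, clade placement.

The HGT conclusion in scope rests on clade membership plus bootstrap
support — a foreign gene nests inside the donor clade with strong support
and away from the recipient's own lineage — which neighbor joining
establishes on desk-scale data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .io import MSA

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("distances must be non-negative")


def protein_distance(msa: MSA, correction: str = "poisson",
                     on_saturation: str = "error") -> DistanceMatrix:
    """Pairwise distances with pairwise gap deletion.

    ``p``: mismatches / compared columns.  ``poisson``: -ln(1-p).  A
    saturated pair (p=1 under poisson) or a pair with no comparable columns
    raises, or is clamped just below saturation with ``on_saturation='clamp'``
    (used by bootstrap resampling, where occasional saturated replicates are
    expected).
    """
    if len(msa.records) < 2:
        raise ValueError("need >= 2 rows")
    if correction not in ("p", "poisson"):
        raise ValueError("correction must be 'p' or 'poisson'")
    rows = [np.frombuffer(r.seq.encode(), dtype="S1") for r in msa.records]
    gap = np.bytes_("-")
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != gap) & (rows[j] != gap)
            m = int(ok.sum())
            if m == 0:
                if on_saturation == "clamp":
                    p = 0.95
                else:
                    raise ValueError(f"no comparable columns for pair "
                                     f"({msa.records[i].id}, {msa.records[j].id})")
            else:
                p = float((rows[i][ok] != rows[j][ok]).sum()) / m
            if correction == "poisson":
                if p >= 1.0:
                    if on_saturation == "clamp":
                        p = 1.0 - 1e-6
                    else:
                        raise ValueError("saturated pair (p=1); poisson distance undefined")
                d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix([r.id for r in msa.records], D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically lowest pair
    of cluster labels (a cluster is labelled by its smallest leaf).  Negative
    branch lengths are clamped to zero with the deficit logged.  The result
    is unrooted, represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    labels = list(dm.labels)
    D = dm.matrix.copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = D[np.ix_(active, active)].sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * D[active[ai], active[aj]] - r[ai] - r[aj]
                key_pair = tuple(sorted((labels[active[ai]], labels[active[aj]])))
                cand = (q, key_pair, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = clamp(0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2)))
        bj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))))
        new = dendropy.Node()
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        newdist = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = newdist
        D[active, k] = newdist
        D[k, k] = 0.0
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [a for a in active if a not in (i, j)] + [k]
    # final three clusters join at the (trifurcating) root
    i, j, k = active
    root = dendropy.Node()
    bi = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    bj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    bk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    for idx, b in ((i, bi), (j, bj), (k, bk)):
        nodes[idx].edge.length = b
        root.add_child(nodes[idx])
    if deficit > 0:
        logger.info("NJ clamped negative branch lengths (total deficit %.4g)", deficit)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial splits as canonical frozensets (side without the first taxon)."""
    all_leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = all_leaves[0]
    out = {}
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        if ref in side:
            side = frozenset(all_leaves) - side
        out[side] = nd
    return out


@dataclass
class BootstrapResult:
    tree: dendropy.Tree
    supports: dict[frozenset, float]
    degenerate: bool = False
    n_replicates: int = 0


def bootstrap_support(msa: MSA, n_replicates: int = 100, seed: int = 0,
                      correction: str = "poisson") -> BootstrapResult:
    """NJ tree with column-bootstrap support percentages.

    Columns are resampled with replacement per replicate; support of each
    original bipartition is the percentage of replicate trees containing it,
    written as internal-node labels.  An alignment of identical sequences is
    degenerate: the (star-like) tree is returned flagged, without supports.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .io import SeqRecord
    if len({r.seq for r in msa.records}) == 1:
        logger.warning("all sequences identical; bootstrap degenerate")
        dm = protein_distance(msa, correction="p")
        return BootstrapResult(nj_tree(dm), {}, degenerate=True)
    tree = nj_tree(protein_distance(msa, correction=correction, on_saturation="clamp"))
    splits = _bipartitions(tree)
    hits = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = msa.n_cols
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = MSA([SeqRecord(r.id, "".join(r.seq[c] for c in cols), moltype=r.moltype)
                   for r in msa.records])
        try:
            rtree = nj_tree(protein_distance(rep, correction=correction,
                                             on_saturation="clamp"))
        except ValueError:
            continue
        rsplits = _bipartitions(rtree)
        for s in hits:
            if s in rsplits:
                hits[s] += 1
    supports = {s: 100.0 * h / n_replicates for s, h in hits.items()}
    for s, nd in splits.items():
        nd.label = f"{supports[s]:.0f}"
    return BootstrapResult(tree, supports, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# Clade placement test
# ---------------------------------------------------------------------------

def placement_test(tree: dendropy.Tree, query_id: str,
                   donor_group: list[str], recipient_group: list[str],
                   min_support: float = 75.0) -> str:
    """Classify a query leaf as ``hgt_supported``, ``native`` or ``unresolved``.

    ``hgt_supported``: the smallest clade containing the query and any donor
    member excludes all recipient-lineage members and has support at least
    ``min_support`` (percent).  ``native``: the query joins the recipient
    lineage before any donor.  Anything else is unresolved.
    """
    all_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if query_id not in all_leaves:
        raise ValueError(f"query {query_id!r} not in tree")
    donors = set(donor_group) & all_leaves
    recips = set(recipient_group) & all_leaves
    if not donors or not recips:
        raise ValueError("donor and recipient groups must both be present in the tree")

    # every edge splits the unrooted tree; the query-containing side of an
    # edge is a candidate enclosing clade, supported by the edge's value
    candidates: list[tuple[int, set, float | None]] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if len(side) == len(all_leaves):
            continue
        qside = side if query_id in side else all_leaves - side
        if len(qside) < len(all_leaves):
            candidates.append((len(qside), qside, _node_support(nd)))

    def smallest_with(targets: set[str]):
        best = None
        for size, qside, sup in candidates:
            if qside & targets and (best is None or size < best[0]):
                best = (size, qside, sup)
        return best if best else (len(all_leaves), all_leaves, None)

    size_d, set_d, sup_d = smallest_with(donors)
    size_r, set_r, _ = smallest_with(recips)
    if size_d < size_r:
        if not (set_d & recips):
            if sup_d is None or sup_d >= min_support:
                return "hgt_supported"
            return "unresolved"
        return "unresolved"
    if size_r < size_d and not (set_r & donors):
        return "native"
    return "unresolved"


def _node_support(node: dendropy.Node) -> float | None:
    if node is None or node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None
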