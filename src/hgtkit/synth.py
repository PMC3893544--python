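"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design of a parasitic-plant HGT screen: a
taxonomy-labelled reference protein database built by gene-family simulation,
a recipient transcriptome containing native genes, planted foreign (HGT)
genes copied from a distant donor clade, and host-contaminant transcripts;
staged paired-end read sets in which contaminants get zero coverage in
host-free stages; codon alignments under M0/M2a/branch-site regimes;
two-cluster protein alignments with a known fraction theta of rate-shifted
sites; and qPCR Ct tables with planted fold changes.

Determinism: every public function takes a seed or ``numpy.random.Generator``
and identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import selection as sel
from .io import MSA, CtTable, SeqRecord, read_newick

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_BASES = "ACGT"

# codons per amino acid for reverse translation
_AA_CODONS: dict[str, list[str]] = {}
for _c in sel.CODONS:
    _AA_CODONS.setdefault(str(sel.CODON_AA[sel.CODON_INDEX[_c]]), []).append(_c)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class Taxonomy:
    """Species tree with rank-level lineage labels and role designations.

    ``recipient`` is the parasite species being screened (its sequences are
    *not* emitted into the reference database); ``sister`` its closest
    relative inside ``ingroup_rank``; ``donor_species`` the clade whose rank
    name is ``donor_rank`` (hosts and HGT donors).
    """

    tree: dendropy.Tree
    lineages: dict[str, list[str]]
    recipient: str
    sister: str
    ingroup_rank: str
    donor_rank: str
    donor_species: list[str]

    def reference_species(self) -> list[str]:
        return [s for s in self.lineages if s != self.recipient]


def default_taxonomy() -> Taxonomy:
    """Study-like taxonomy: an ingroup order containing the recipient and its
    sister, a distant donor order (the hosts), and an outgroup.

    Branch lengths are amino-acid substitutions/site.  The recipient-to-donor
    path length is 1.2 subs/site, the recipient-to-sister path 0.3 —
    recipient gene families are deeply diverged from the donor clade, which
    is the regime in which the alien-ratio screen is informative.
    """
    nwk = ("(((recipient:0.15,sister_taxon:0.15):0.45,"
           "(donor_A:0.08,donor_B:0.08):0.52):0.15,outgroup_sp:0.55);")
    tree = read_newick(nwk)
    lineages = {
        "recipient": ["Eukaryota", "Viridiplantae", "Lamiales", "recipient"],
        "sister_taxon": ["Eukaryota", "Viridiplantae", "Lamiales", "sister_taxon"],
        "donor_A": ["Eukaryota", "Viridiplantae", "Brassicales", "donor_A"],
        "donor_B": ["Eukaryota", "Viridiplantae", "Brassicales", "donor_B"],
        "outgroup_sp": ["Eukaryota", "Viridiplantae", "Solanales", "outgroup_sp"],
    }
    return Taxonomy(tree, lineages, "recipient", "sister_taxon",
                    "Lamiales", "Brassicales", ["donor_A", "donor_B"])


# ---------------------------------------------------------------------------
# Protein family simulation (Poisson substitutions + geometric indels)
# ---------------------------------------------------------------------------

class _Site:
    __slots__ = ("uid",)
    _counter = itertools.count()

    def __init__(self):
        self.uid = next(self._counter)


def _mutate_protein(seq: list[tuple[int, str]], t: float, rng: np.random.Generator,
                    indel_rate: float, indel_mean: float,
                    column_order: list[int], new_uid) -> list[tuple[int, str]]:
    """One branch of evolution on a (site-id, residue) list."""
    seq = list(seq)
    n = len(seq)
    if n == 0:
        return seq
    n_sub = rng.poisson(t * n)
    for _ in range(n_sub):
        pos = int(rng.integers(len(seq)))
        uid, old = seq[pos]
        idx = int(rng.integers(19))  # uniform over the 19 non-identical residues
        if idx >= _AA_INDEX[old]:
            idx += 1
        seq[pos] = (uid, AMINO_ACIDS[idx])
    n_indel = rng.poisson(indel_rate * t * n)
    for _ in range(n_indel):
        length = int(rng.geometric(1.0 / indel_mean))
        if rng.random() < 0.5 and len(seq) > length + 5:  # deletion
            start = int(rng.integers(len(seq) - length))
            del seq[start:start + length]
        else:  # insertion
            start = int(rng.integers(len(seq) + 1))
            fresh = [(new_uid(), AMINO_ACIDS[int(rng.integers(20))]) for _ in range(length)]
            anchor_uid = seq[start - 1][0] if start > 0 else None
            if anchor_uid is None:
                at = 0
            else:
                at = column_order.index(anchor_uid) + 1
            column_order[at:at] = [u for u, _ in fresh]
            seq[start:start] = fresh
    return seq


@dataclass
class FamilySim:
    """One simulated gene family: per-species sequences plus true alignment."""

    sequences: dict[str, str]
    alignment: MSA


def simulate_family(taxonomy: Taxonomy, root_len: int, rng,
                    indel_rate: float = 0.02, indel_mean: float = 3.0,
                    rate_scale: float = 1.0) -> FamilySim:
    """Evolve one protein family along the taxonomy by a Poisson process.

    Branch length x ``rate_scale`` is the expected number of substitutions
    per site.  Indels follow a geometric length law; the true alignment is
    reconstructed from a global site registry.
    """
    rng = _rng(rng)
    counter = itertools.count()

    def new_uid():
        return next(counter)

    root = [(new_uid(), AMINO_ACIDS[int(rng.integers(20))]) for _ in range(root_len)]
    root[0] = (root[0][0], "M")
    column_order = [u for u, _ in root]
    node_seqs: dict[int, list[tuple[int, str]]] = {}
    leaf_seqs: dict[str, list[tuple[int, str]]] = {}
    for node in taxonomy.tree.preorder_node_iter():
        if node.parent_node is None:
            node_seqs[id(node)] = root
        else:
            t = (node.edge.length or 0.0) * rate_scale
            if t < 0:
                raise ValueError("negative branch length in taxonomy")
            child = _mutate_protein(node_seqs[id(node.parent_node)], t, rng,
                                    indel_rate, indel_mean, column_order, new_uid)
            node_seqs[id(node)] = child
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = node_seqs[id(node)]
    col_pos = {u: i for i, u in enumerate(column_order)}
    rows = []
    for sp, seq in leaf_seqs.items():
        row = ["-"] * len(column_order)
        for uid, aa in seq:
            row[col_pos[uid]] = aa
        rows.append(SeqRecord(sp, "".join(row), moltype="protein"))
    keep = [j for j in range(len(column_order))
            if any(r.seq[j] != "-" for r in rows)]
    rows = [SeqRecord(r.id, "".join(r.seq[j] for j in keep), moltype="protein")
            for r in rows]
    seqs = {r.id: r.seq.replace("-", "") for r in rows}
    return FamilySim(seqs, MSA(rows))


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDB:
    proteins: list[SeqRecord]
    lineage_map: dict[str, list[str]]
    families: list[FamilySim]
    taxonomy: Taxonomy


def simulate_reference_db(taxonomy: Taxonomy | None = None, n_families: int = 28,
                          root_len: int = 160, seed=0,
                          indel_rate: float = 0.02) -> ReferenceDB:
    """A taxonomy-labelled protein reference set, one family per gene.

    Every species except the recipient is emitted (the recipient is the
    query organism); subject ids are ``<species>|fam<i>`` and each carries
    the species' lineage in the map.
    """
    taxonomy = taxonomy or default_taxonomy()
    rng = _rng(seed)
    families = [simulate_family(taxonomy, root_len, rng, indel_rate=indel_rate)
                for _ in range(n_families)]
    proteins: list[SeqRecord] = []
    lineage_map: dict[str, list[str]] = {}
    for i, fam in enumerate(families):
        for sp in taxonomy.reference_species():
            sid = f"{sp}|fam{i}"
            proteins.append(SeqRecord(sid, fam.sequences[sp], moltype="protein"))
            lineage_map[sid] = list(taxonomy.lineages[sp])
    return ReferenceDB(proteins, lineage_map, families, taxonomy)


# ---------------------------------------------------------------------------
# Recipient transcriptome
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-transcript labels and planted structure for acceptance checks."""

    labels: dict[str, str]                      # id -> native | hgt | contaminant
    origin: dict[str, str]                      # id -> source species
    cds_span: dict[str, tuple[int, int]]        # id -> CDS interval in transcript
    proteins: dict[str, str]
    intron_positions: dict[str, list[tuple[int, int]]]  # gene -> genomic intervals
    retention: dict[str, tuple[str, str, int, int]] = field(default_factory=dict)
    # gene -> (spliced_isoform_id, retained_isoform_id, insert_pos_in_cdna, length)


@dataclass
class Transcriptome:
    transcripts: list[SeqRecord]
    genomic: dict[str, SeqRecord]
    truth: GroundTruth


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_AA_CODONS[aa][int(rng.integers(len(_AA_CODONS[aa])))]
                   for aa in protein)


def _random_dna(n: int, rng: np.random.Generator, avoid_atg: bool = False) -> str:
    s = "".join(_BASES[i] for i in rng.integers(0, 4, size=n))
    if avoid_atg:
        s = s.replace("ATG", "ATC")
    return s


def _diverge_protein(protein: str, t: float, rng: np.random.Generator) -> str:
    seq = list(protein)
    n_sub = rng.poisson(t * len(seq))
    for _ in range(n_sub):
        pos = int(rng.integers(len(seq)))
        if pos == 0:
            continue  # keep the initiator Met
        seq[pos] = AMINO_ACIDS[int(rng.integers(20))]
    return "".join(seq)


def _make_intron(length: int, rng: np.random.Generator,
                 safe_prefix_codons: int = 7) -> str:
    """GT...AG intron whose first codons are stop-free in phase 0.

    A frame-preserving partial retention of the intron's 5' end must not
    interrupt the reading frame with a stop, so the leading
    ``safe_prefix_codons`` codons are drawn from sense codons (the first is
    forced to GT+N, a valine codon).
    """
    prefix = "GT" + _random_dna(1, rng)
    for _ in range(safe_prefix_codons - 1):
        prefix += sel.CODONS[int(rng.integers(sel.N_CODONS))]
    rest = length - len(prefix) - 2
    if rest < 0:
        raise ValueError("intron too short for the safe prefix")
    return prefix + _random_dna(rest, rng) + "AG"


def simulate_recipient_transcriptome(
        reference: ReferenceDB, n_native: int = 20, n_hgt: int = 3,
        n_contaminants: int = 5, hgt_divergence: float = 0.1,
        utr5: int = 60, utr3: int = 90,
        intron_lengths: tuple[int, int] = (60, 140),
        introns_per_gene: int = 2,
        retention_length: int = 21,
        emit_retention_isoform: bool = True,
        seed=1) -> Transcriptome:
    """Native, planted-foreign and host-contaminant transcripts with genomic copies.

    Native transcripts are the recipient's own family members; HGT
    transcripts are donor-clade copies with ``hgt_divergence`` further
    substitutions/site; contaminants are exact host (donor-clade) copies.
    Genomic versions carry introns at recorded positions — donor-matching
    positions for HGT genes.  One HGT gene is emitted as two isoforms
    differing by partial retention of intron 2 (default 21 nt, preserving
    frame), emulating an intron-retention splice variant.
    """
    if n_native + n_hgt + n_contaminants > len(reference.families):
        raise ValueError("not enough simulated families")
    tax = reference.taxonomy
    if set(tax.donor_species) & {tax.recipient, tax.sister}:
        raise ValueError("donor clade overlaps recipient lineage: no HGT signal")
    if retention_length % 3 != 0:
        raise ValueError("retention length must preserve frame (multiple of 3)")
    rng = _rng(seed)
    labels: dict[str, str] = {}
    origin: dict[str, str] = {}
    cds_span: dict[str, tuple[int, int]] = {}
    proteins: dict[str, str] = {}
    intron_pos: dict[str, list[tuple[int, int]]] = {}
    retention: dict[str, tuple[str, str, int, int]] = {}
    transcripts: list[SeqRecord] = []
    genomic: dict[str, SeqRecord] = {}

    def emit(tid: str, protein: str, label: str, src: str,
             with_introns: bool, intron_codons: list[int] | None = None,
             retained: bool = False):
        cds = "ATG" + _reverse_translate(protein[1:], rng) + "TAA"
        u5 = _random_dna(utr5, rng, avoid_atg=True)
        u3 = _random_dna(utr3, rng)
        cdna = u5 + cds + u3
        transcripts.append(SeqRecord(tid, cdna))
        labels[tid] = label
        origin[tid] = src
        cds_span[tid] = (utr5, utr5 + len(cds))
        proteins[tid] = "M" + protein[1:]
        if with_introns:
            positions = intron_codons or sorted(
                rng.choice(np.arange(10, len(protein) - 10), size=introns_per_gene,
                           replace=False).tolist())
            g = cdna
            offset = 0
            intervals = []
            for ci in positions:
                at = utr5 + 3 * ci + offset
                ilen = int(rng.integers(intron_lengths[0], intron_lengths[1] + 1))
                intron = _make_intron(ilen, rng)
                g = g[:at] + intron + g[at:]
                intervals.append((at, at + ilen))
                offset += ilen
            genomic[tid] = SeqRecord(tid + "_genomic", g)
            intron_pos[tid] = intervals
            if retained:
                # second isoform keeps the first retention_length nt of intron 2
                i2_start, _ = intervals[1]
                # position of intron 2 in the spliced cDNA
                prior = sum(e - s for s, e in intervals[:1])
                pos_in_cdna = i2_start - prior
                retained_seq = (cdna[:pos_in_cdna]
                                + genomic[tid].seq[i2_start:i2_start + retention_length]
                                + cdna[pos_in_cdna:])
                rid = tid + "_iso1"
                transcripts.append(SeqRecord(rid, retained_seq))
                labels[rid] = label
                origin[rid] = src
                cds_span[rid] = (utr5, utr5 + len(cds) + retention_length)
                proteins[rid] = proteins[tid]
                retention[tid] = (tid, rid, pos_in_cdna, retention_length)
        return positions if with_introns and intron_codons is None else intron_codons

    fam_iter = iter(range(len(reference.families)))
    for i in range(n_native):
        fi = next(fam_iter)
        fam = reference.families[fi]
        prot = fam.sequences[tax.recipient]
        emit(f"native_{i}", prot, "native", tax.recipient, with_introns=(i < 3))
    donor = tax.donor_species[0]
    for i in range(n_hgt):
        fi = next(fam_iter)
        fam = reference.families[fi]
        prot = _diverge_protein(fam.sequences[donor], hgt_divergence, rng)
        # donor-matching intron positions: fixed per family
        fam_rng = np.random.default_rng(100000 + fi)
        donor_positions = sorted(fam_rng.choice(
            np.arange(10, len(prot) - 10), size=max(introns_per_gene, 2),
            replace=False).tolist())
        emit(f"hgt_{i}", prot, "hgt", donor, with_introns=True,
             intron_codons=donor_positions,
             retained=(i == 0 and emit_retention_isoform))
    host = tax.donor_species[min(1, len(tax.donor_species) - 1)]
    for i in range(n_contaminants):
        fi = next(fam_iter)
        fam = reference.families[fi]
        emit(f"contam_{i}", fam.sequences[host], "contaminant", host, with_introns=False)

    truth = GroundTruth(labels, origin, cds_span, proteins, intron_pos, retention)
    return Transcriptome(transcripts, genomic, truth)


# ---------------------------------------------------------------------------
# Staged read simulation
# ---------------------------------------------------------------------------

@dataclass
class Stage:
    name: str
    host_free: bool


DEFAULT_STAGES = (Stage("attached", False), Stage("seedling", True), Stage("shoot", True))


def simulate_reads(transcriptome: Transcriptome,
                   stages=DEFAULT_STAGES, depth: float = 8.0,
                   read_length: int = 50, error_rate: float = 0.0,
                   seed=2) -> dict[str, list[SeqRecord]]:
    """Paired-end reads per stage; contaminants get zero host-free coverage.

    Fragment count per transcript is Poisson with mean depth*len/(2*read_len)
    (i.e. ``depth``-fold base coverage); starts are uniform; a per-base error
    substitutes a random different base.  Two records per fragment with
    ``/1`` and ``/2`` suffixes; mate 2 is the reverse complement.
    """
    rng = _rng(seed)
    insert = 2 * read_length
    out: dict[str, list[SeqRecord]] = {}
    for stage in stages:
        reads: list[SeqRecord] = []
        for rec in transcriptome.transcripts:
            if len(rec.seq) < insert:
                continue
            if stage.host_free and transcriptome.truth.labels[rec.id] == "contaminant":
                continue
            mean_frags = depth * len(rec.seq) / insert
            n_frags = int(rng.poisson(mean_frags))
            if not stage.host_free and transcriptome.truth.labels[rec.id] == "contaminant":
                n_frags = max(n_frags, 1)
            starts = rng.integers(0, len(rec.seq) - insert + 1, size=n_frags)
            for f, s in enumerate(starts):
                frag = rec.seq[s:s + insert]
                r1 = frag[:read_length]
                r2 = revcomp(frag[read_length:])
                if error_rate > 0:
                    r1 = _apply_errors(r1, error_rate, rng)
                    r2 = _apply_errors(r2, error_rate, rng)
                q = [35] * read_length
                base = f"{stage.name}:{rec.id}:{f}"
                reads.append(SeqRecord(f"{base}/1", r1, quality=list(q)))
                reads.append(SeqRecord(f"{base}/2", r2, quality=list(q)))
        out[stage.name] = reads
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alt = [b for b in _BASES if b != chars[i]]
        chars[i] = alt[int(rng.integers(3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Homology hit table from the synthetic reference (alignment-score based)
# ---------------------------------------------------------------------------

def build_hit_table(queries: list[SeqRecord], reference: ReferenceDB,
                    min_score: float = 50.0) -> dict[str, list]:
    """Score every query protein against the reference set by local alignment.

    Stands in for an external homology search over the synthetic database:
    the alien-ratio statistic only needs a common score scale, so BLOSUM62
    Smith-Waterman scores serve as the bit-score column.  Returns hits
    grouped by query, sorted by descending score.
    """
    from .comparative import pairwise_align
    from .io import Hit
    grouped: dict[str, list] = {}
    for q in queries:
        hits = []
        for subj in reference.proteins:
            aln = pairwise_align(q.seq, subj.seq, mode="local", moltype="protein")
            if aln.score < min_score:
                continue
            hits.append(Hit(q.id, subj.id, aln.percent_identity, aln.n_columns,
                            float(aln.score), 1e-10,
                            list(reference.lineage_map[subj.id])))
        hits.sort(key=lambda h: -h.bit_score)
        grouped[q.id] = hits
    return grouped


def build_cdna_hit_table(transcripts: list[SeqRecord], truth: GroundTruth,
                         taxonomy: Taxonomy) -> dict[str, list]:
    """Nucleotide-level hit table for the sister-taxon exclusion step.

    In the synthetic regime HGT cDNAs have no significant nucleotide-level
    similarity to the sister taxon (the screen's premise), so only native
    transcripts receive a sister-taxon cDNA hit.
    """
    from .io import Hit
    grouped: dict[str, list] = {}
    for rec in transcripts:
        hits = []
        if truth.labels[rec.id] == "native":
            hits.append(Hit(rec.id, f"{taxonomy.sister}|cdna", 95.0, len(rec.seq),
                            500.0, 1e-50, list(taxonomy.lineages[taxonomy.sister])))
        grouped[rec.id] = hits
    return grouped


# ---------------------------------------------------------------------------
# Codon alignment simulation (GY94)
# ---------------------------------------------------------------------------

def simulate_codon_alignment(tree: dendropy.Tree, kappa: float,
                             site_classes: list[tuple[float, float]],
                             n_sites: int = 300,
                             freqs: np.ndarray | None = None,
                             foreground_leaves=None,
                             foreground_clade: bool = False,
                             fg_omegas: list[float] | None = None,
                             seed=0) -> tuple[MSA, np.ndarray]:
    """Evolve codons along ``tree`` under a GY94 process.

    ``site_classes`` is a list of (omega, proportion) pairs; with
    ``foreground_leaves`` and ``fg_omegas`` the designated branches use the
    per-class foreground omega instead (branch-site regime).  Returns the
    leaf alignment (nucleotide MSA in frame) and the true class per site.
    """
    from .trees import tree_to_arrays
    rng = _rng(seed)
    omegas = np.array([w for w, _ in site_classes])
    props = np.array([p for _, p in site_classes])
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must sum to 1")
    if (omegas < 0).any() or kappa <= 0:
        raise ValueError("omega must be >= 0 and kappa > 0")
    freqs = sel.equal_codon_freqs() if freqs is None else np.asarray(freqs)
    tarr = tree_to_arrays(tree)
    fg_edges = set()
    if foreground_leaves:
        fg_edges = sel.foreground_edges_for(tree, tarr, foreground_leaves,
                                            clade=foreground_clade)
    mats = {}

    def P_for(omega, t):
        key = round(float(omega), 12)
        if key not in mats:
            mats[key] = sel.CodonRateMatrix(sel.build_Q(kappa, float(omega), freqs), freqs)
        return mats[key].transition(t)

    classes = rng.choice(len(omegas), size=n_sites, p=props)
    states = np.empty((tarr.n_nodes, n_sites), dtype=np.int64)
    # preorder = reversed postorder
    parent = np.full(tarr.n_nodes, -1)
    for node in range(tarr.n_nodes):
        for ch in tarr.children[node]:
            parent[ch] = node
    states[tarr.root] = rng.choice(sel.N_CODONS, size=n_sites, p=freqs / freqs.sum())
    for node in range(tarr.n_nodes - 2, -1, -1):
        t = max(tarr.branch_lengths[node], 0.0)
        par_states = states[parent[node]]
        for c in range(len(omegas)):
            mask = classes == c
            if not mask.any():
                continue
            omega = omegas[c]
            if node in fg_edges and fg_omegas is not None:
                omega = fg_omegas[c]
            if t == 0:
                states[node][mask] = par_states[mask]
                continue
            P = P_for(omega, t)
            cum = np.cumsum(P, axis=1)
            u = rng.random(mask.sum())
            rows = cum[par_states[mask]]
            states[node][mask] = (u[:, None] > rows).sum(axis=1)
    records = []
    for idx, label in sorted(tarr.labels.items(), key=lambda kv: kv[1]):
        seq = "".join(sel.CODONS[s] for s in states[idx])
        records.append(SeqRecord(label, seq))
    return MSA(records), classes


# ---------------------------------------------------------------------------
# Two-cluster divergence alignment
# ---------------------------------------------------------------------------

def simulate_divergence_alignment(tree1: dendropy.Tree, tree2: dendropy.Tree,
                                  theta_true: float, alpha: float,
                                  n_sites: int = 500, seed=0
                                  ) -> tuple[MSA, np.ndarray]:
    """Protein alignment of two duplicate clusters with rate-shifted sites.

    A fraction ``theta_true`` of sites draw independent Gamma(alpha) rates in
    the two clusters (type-I functional divergence); the rest share one rate.
    Substitutions are placed by a Poisson process along each cluster tree
    from a common ancestral residue.  Returns the combined MSA (groups
    ``cluster1``/``cluster2``) and the true per-site divergence state.
    """
    if not 0 <= theta_true <= 1:
        raise ValueError("theta_true must be in [0,1]")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    rng = _rng(seed)
    divergent = rng.random(n_sites) < theta_true
    shared = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    r1 = np.where(divergent, rng.gamma(alpha, 1.0 / alpha, size=n_sites), shared)
    r2 = np.where(divergent, rng.gamma(alpha, 1.0 / alpha, size=n_sites), shared)
    root = rng.integers(0, 20, size=n_sites)

    def evolve(tree, rates):
        from .trees import tree_to_arrays
        tarr = tree_to_arrays(tree)
        parent = np.full(tarr.n_nodes, -1)
        for node in range(tarr.n_nodes):
            for ch in tarr.children[node]:
                parent[ch] = node
        states = np.empty((tarr.n_nodes, n_sites), dtype=np.int64)
        states[tarr.root] = root
        for node in range(tarr.n_nodes - 2, -1, -1):
            t = max(tarr.branch_lengths[node], 0.0)
            st = states[parent[node]].copy()
            n_events = rng.poisson(rates * t)
            for s in np.nonzero(n_events > 0)[0]:
                for _ in range(n_events[s]):
                    new = int(rng.integers(19))
                    st[s] = new if new < st[s] else new + 1
            states[node] = st
        return {lab: states[i] for i, lab in tarr.labels.items()}

    leaves1 = evolve(tree1, r1)
    leaves2 = evolve(tree2, r2)
    if set(leaves1) & set(leaves2):
        raise ValueError("cluster trees must have disjoint leaf names")
    records, groups = [], {"cluster1": [], "cluster2": []}
    for name, leaves in (("cluster1", leaves1), ("cluster2", leaves2)):
        for lab in sorted(leaves):
            records.append(SeqRecord(lab, "".join(AMINO_ACIDS[s] for s in leaves[lab]),
                                     moltype="protein"))
            groups[name].append(lab)
    return MSA(records, groups), divergent


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

@dataclass
class QpcrDesign:
    """Conditions, replicate count and candidate reference genes.

    The default sampling mirrors a study design of nine developmental
    stages/organs plus a wounding time course (0-24 h), five biological
    replicates each.  ``reference_drift`` maps each candidate reference
    gene to the SD of its per-condition baseline drift (0 = perfectly
    condition-independent) and ``reference_noise`` to its per-replicate Ct
    noise; the panel mirrors EF-1a / actin / EF-Tu / PP2A with EF-1a the
    planted stable gene (no drift, least noise).
    """

    conditions: tuple[str, ...] = (
        "seed", "germ2mm", "germ3cm", "prehaustoria", "stem", "shoot_tip",
        "floral_bud", "flower", "capsule", "0h", "1h", "3h", "9h", "24h")
    n_replicates: int = 5
    target: str = "target"
    target_baseline: float = 26.0
    reference_baselines: dict = field(default_factory=lambda: {
        "EF1a": 20.0, "actin": 21.0, "EFTU": 22.5, "PP2A": 24.0})
    reference_drift: dict = field(default_factory=lambda: {
        "EF1a": 0.0, "actin": 0.35, "EFTU": 0.5, "PP2A": 0.7})
    reference_noise: dict = field(default_factory=lambda: {
        "EF1a": 0.02, "actin": 0.15, "EFTU": 0.2, "PP2A": 0.3})


def simulate_qpcr(design: QpcrDesign, fold_changes: dict[str, float],
                  noise_sd: float = 0.1, reference_noise_sd: float = 0.0,
                  seed=0) -> CtTable:
    """Ct tables with planted fold changes.

    Target Ct = baseline - log2(fold(condition)) + N(0, noise_sd) per
    replicate.  Reference genes get condition-independent baselines plus a
    per-condition drift drawn with their configured drift SD (and optional
    per-replicate noise ``reference_noise_sd``, default none).
    """
    if noise_sd < 0 or reference_noise_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = _rng(seed)
    rows = []
    drift: dict[tuple[str, str], float] = {}
    for gene, dsd in design.reference_drift.items():
        for cond in design.conditions:
            drift[(gene, cond)] = rng.normal(0, dsd) if dsd > 0 else 0.0
    for cond in design.conditions:
        fold = fold_changes.get(cond, 1.0)
        for rep in range(1, design.n_replicates + 1):
            sample = f"{cond}_r{rep}"
            ct = design.target_baseline - math.log2(fold) + (
                rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((design.target, sample, cond, rep, ct))
            for gene, base in design.reference_baselines.items():
                nsd = design.reference_noise.get(gene, reference_noise_sd)
                ct = base + drift[(gene, cond)] + (
                    rng.normal(0, nsd) if nsd > 0 else 0.0)
                rows.append((gene, sample, cond, rep, ct))
    df = pd.DataFrame(rows, columns=["gene", "sample", "condition", "replicate", "ct"])
    return CtTable(df)


# ---------------------------------------------------------------------------
# Synthetic accession stand-ins
# ---------------------------------------------------------------------------

@dataclass
class SslStandin:
    """Synthetic stand-in for the deposited SSL records (no real accessions).

    Deterministically generated sequences reproducing the structural
    scenario of the deposited gene set: a 1597-bp cDNA whose longest ORF
    encodes 369 amino acids, a genomic copy carrying 2 introns, two mRNA
    isoforms differing by a single in-frame 21-nt partial intron retention
    at an intron boundary, and a donor-clade homolog at ~88% amino-acid
    identity.  All sequences are synthetic; none is downloaded data.
    """

    cdna: SeqRecord
    protein: SeqRecord
    genomic: SeqRecord
    intron_intervals: list[tuple[int, int]]
    isoform_spliced: SeqRecord
    isoform_retained: SeqRecord
    donor_protein: SeqRecord
    retention_length: int
    cds_start: int


def ssl_standins(seed: int = 1594) -> SslStandin:
    """Build the synthetic SSL stand-in gene set (byte-stable for a seed)."""
    rng = _rng(seed)
    n_aa = 369
    protein = "M" + "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n_aa - 1))
    cds = "ATG" + _reverse_translate(protein[1:], rng) + "TAA"   # 1110 nt
    utr5 = _random_dna(200, rng, avoid_atg=True)
    utr3 = _random_dna(1597 - 200 - len(cds), rng)
    cdna_seq = utr5 + cds + utr3
    assert len(cdna_seq) == 1597
    cdna = SeqRecord("sslA_cdna_synthetic", cdna_seq)
    # two introns at phase-0 codon boundaries (by convention introns 2 and 3
    # of the donor family's architecture)
    intron_codons = [118, 247]
    g = cdna_seq
    offset = 0
    intervals = []
    for ci, ilen in zip(intron_codons, (94, 133)):
        at = 200 + 3 * ci + offset
        intron = _make_intron(ilen, rng)
        g = g[:at] + intron + g[at:]
        intervals.append((at, at + ilen))
        offset += ilen
    genomic = SeqRecord("sslA_genomic_synthetic", g)
    # isoform pair: 21-nt partial retention of the first intron
    retention = 21
    i1s, _ = intervals[0]
    pos_in_cdna = i1s   # first intron: no upstream intron offset
    retained_seq = (cdna_seq[:pos_in_cdna]
                    + g[i1s:i1s + retention]
                    + cdna_seq[pos_in_cdna:])
    iso2 = SeqRecord("sslB_seq2_synthetic", cdna_seq)
    iso1 = SeqRecord("sslB_seq1_synthetic", retained_seq)
    # donor homolog at ~88% amino-acid identity (44 of 369 residues changed)
    donor = list(protein)
    sites = rng.choice(np.arange(1, n_aa), size=44, replace=False)
    for s in sites:
        idx = int(rng.integers(19))
        if idx >= _AA_INDEX[donor[s]]:
            idx += 1
        donor[s] = AMINO_ACIDS[idx]
    donor_protein = SeqRecord("donor_ssl_protein_synthetic", "".join(donor),
                              moltype="protein")
    return SslStandin(cdna, SeqRecord("sslA_protein_synthetic", protein, moltype="protein"),
                      genomic, intervals, iso2, iso1, donor_protein, retention, 200)
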