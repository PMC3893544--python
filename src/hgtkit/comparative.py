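"""Pairwise alignment, identity, codon back-translation, group-diagnostic
sites/indels and intron-structure comparison.

Intron positions are compared across genes in protein-alignment codon
coordinates plus phase (0/1/2): two genes share an intron when it
interrupts the same alignment codon column in the same phase, which is the
classical evidence that a foreign gene arrived as DNA carrying the donor's
exon-intron architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io import MSA, SeqRecord

logger = logging.getLogger(__name__)

AMBIGUOUS_PROTEIN = set("BZJXUO")
AMBIGUOUS_DNA = set("NRYSWKMBDHV")


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    mode: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x == y and x != "-")

    @property
    def percent_identity(self) -> float:
        """100 * matches / aligned columns, gap columns excluded; 1 decimal."""
        cols = sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x != "-" and y != "-")
        if cols == 0:
            return 0.0
        return round(100.0 * self.matches / cols, 1)


def _aligner(mode: str, moltype: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if moltype == "protein":
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    else:
        al.match_score = 2.0
        al.mismatch_score = -3.0
        al.open_gap_score = -5.0
        al.extend_gap_score = -2.0
    return al


def pairwise_align(a: str | SeqRecord, b: str | SeqRecord, mode: str = "global",
                   moltype: str = "dna") -> PairwiseAlignment:
    """Optimal pairwise alignment by dynamic programming.

    Protein scoring: BLOSUM62 with affine gaps (open 11, extend 1);
    nucleotide: match 2 / mismatch -3, gap open 5 / extend 2.  The first
    optimal alignment in Biopython's deterministic traversal order is
    returned, so results are reproducible.
    """
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    al = _aligner(mode, moltype)
    aln = al.align(sa.upper(), sb.upper())[0]
    ra, rb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ra, rb, float(aln.score), mode)


def percent_identity(a: str | SeqRecord, b: str | SeqRecord, mode: str = "global",
                     moltype: str = "dna") -> float:
    return pairwise_align(a, b, mode=mode, moltype=moltype).percent_identity


# ---------------------------------------------------------------------------
# Back-translation
# ---------------------------------------------------------------------------

def back_translate_alignment(protein_msa: MSA, cdna: dict[str, str | SeqRecord]) -> MSA:
    """Expand a protein alignment to its codon alignment.

    Each cDNA (frame 0, stop trimmed) must translate exactly to its protein
    row; every residue column becomes the source codon and every gap
    becomes ``---``.
    """
    out = []
    for rec in protein_msa.records:
        if rec.id not in cdna:
            raise ValueError(f"no cDNA provided for {rec.id}")
        cds = cdna[rec.id].seq if isinstance(cdna[rec.id], SeqRecord) else cdna[rec.id]
        cds = cds.upper()
        if len(cds) % 3 == 0 and str(Seq(cds[-3:]).translate()) == "*":
            cds = cds[:-3]
        prot = rec.seq.replace("-", "")
        trans = str(Seq(cds).translate())
        if trans != prot:
            mismatch = next((i for i, (x, y) in enumerate(zip(trans, prot)) if x != y),
                            min(len(trans), len(prot)))
            raise ValueError(f"{rec.id}: cDNA does not translate to protein row "
                             f"(first mismatch at residue {mismatch})")
        codons = iter(cds[i:i + 3] for i in range(0, len(cds), 3))
        row = "".join("---" if aa == "-" else next(codons) for aa in rec.seq)
        out.append(SeqRecord(rec.id, row))
    return MSA(out, dict(protein_msa.groups))


# ---------------------------------------------------------------------------
# Alignment trimming
# ---------------------------------------------------------------------------

@dataclass
class TrimResult:
    msa: MSA
    removed_columns: list[int]
    old_to_new: dict[int, int]


def trim_alignment(msa: MSA, max_gap_fraction: float = 0.0,
                   drop_ambiguous: bool = True) -> TrimResult:
    """Remove gapped and ambiguous columns.

    Strict default (``max_gap_fraction=0``): any gap removes the column, as
    is usual before distance and likelihood analyses.  The old->new column
    map is returned for coordinate bookkeeping.
    """
    if not msa.records:
        raise ValueError("empty alignment")
    ambig = AMBIGUOUS_PROTEIN if msa.records[0].moltype == "protein" else AMBIGUOUS_DNA
    n_rows = len(msa.records)
    removed, kept = [], []
    for j in range(msa.n_cols):
        col = msa.column(j)
        gap_frac = col.count("-") / n_rows
        bad = gap_frac > max_gap_fraction or (drop_ambiguous and any(c in ambig for c in col))
        (removed if bad else kept).append(j)
    if not kept:
        raise ValueError("trimming removed every column")
    records = [SeqRecord(r.id, "".join(r.seq[j] for j in kept), moltype=r.moltype)
               for r in msa.records]
    return TrimResult(MSA(records, dict(msa.groups)), removed,
                      {old: new for new, old in enumerate(kept)})


# ---------------------------------------------------------------------------
# Group-diagnostic sites
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticSite:
    column: int                  # MSA column (start column for deletions)
    kind: str                    # 'residue' | 'deletion'
    group_state: str
    outside_states: str
    purity: float
    length: int = 1              # run length for deletions


def diagnostic_sites(msa: MSA, group_name: str,
                     min_purity: float = 1.0) -> list[DiagnosticSite]:
    """Columns uniquely conserved in one group.

    Residue sites: all group members share one residue and no outside
    member carries it (strict mode; ``min_purity`` < 1 relaxes the
    within-group requirement).  Deletion sites: maximal runs of columns
    gapped in every group member and in no outside member — the
    shared-deletion diagnostic of a common origin.
    """
    if group_name not in msa.groups:
        raise ValueError(f"group {group_name!r} not defined")
    members = set(msa.groups[group_name])
    if len(members) < 2:
        raise ValueError("group needs >= 2 members")
    others = [r for r in msa.records if r.id not in members]
    if not others:
        raise ValueError("group covers all rows; nothing to contrast")
    grp = [r for r in msa.records if r.id in members]
    sites: list[DiagnosticSite] = []
    del_run: list[int] = []

    def flush_run():
        nonlocal del_run
        if del_run:
            sites.append(DiagnosticSite(del_run[0], "deletion", "-",
                                        "".join(sorted({o.seq[del_run[0]] for o in others})),
                                        1.0, len(del_run)))
            del_run = []

    for j in range(msa.n_cols):
        gcol = [r.seq[j] for r in grp]
        ocol = [r.seq[j] for r in others]
        if all(c == "-" for c in gcol) and all(c != "-" for c in ocol):
            del_run.append(j)
            continue
        flush_run()
        counts = {c: gcol.count(c) for c in set(gcol) if c != "-"}
        if not counts:
            continue
        state, cnt = max(counts.items(), key=lambda kv: kv[1])
        purity = cnt / len(gcol)
        if purity >= min_purity and state not in ocol:
            sites.append(DiagnosticSite(j, "residue", state,
                                        "".join(sorted(set(ocol))), purity))
    flush_run()
    return sites


# ---------------------------------------------------------------------------
# Intron mapping (spliced alignment)
# ---------------------------------------------------------------------------

@dataclass
class GeneStructure:
    gene_id: str
    exons: list[tuple[int, int]]         # genomic coordinates, 0-based half-open
    introns: list[tuple[int, int]]
    strand: str = "+"
    gt_ag: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b > c:
                raise ValueError("exons overlap or are unordered")
        expected = [(b, c) for (_, b), (c, _) in zip(self.exons, self.exons[1:])]
        if self.introns != expected:
            raise ValueError("introns must be exactly the gaps between exons")

    def intron_positions_in_cdna(self) -> list[int]:
        """Spliced-coordinate position of each intron (nt offset in cDNA)."""
        out, acc = [], 0
        for (a, b) in self.exons[:-1]:
            acc += b - a
            out.append(acc)
        return out


def map_introns(cdna: SeqRecord, genomic: SeqRecord, min_intron: int = 40,
                min_exon_identity: float = 0.90) -> GeneStructure:
    """Spliced alignment of a cDNA onto its genomic sequence.

    A global affine-gap alignment with cheap long cDNA-side gaps (so that
    skipped introns coalesce into contiguous genomic-only blocks) and
    expensive genomic-side gaps.  Genomic-only runs of at least
    ``min_intron`` are introns; boundaries are left-justified (junction
    repeats make the exact cut ambiguous) and GT...AG conformity is
    reported, not enforced.  Fails if exonic identity falls below
    ``min_exon_identity``.
    """
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -3.0
    # gaps in the cDNA row correspond to genomic-only (intronic) bases:
    # cheap to extend so introns coalesce; genomic-side gaps expensive
    try:
        al.open_internal_insertion_score = -6.0
        al.extend_internal_insertion_score = -0.05
        al.end_insertion_score = 0.0
        al.open_internal_deletion_score = -12.0
        al.extend_internal_deletion_score = -3.0
        al.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        al.target_internal_open_gap_score = -6.0
        al.target_internal_extend_gap_score = -0.05
        al.target_end_gap_score = 0.0
        al.query_internal_open_gap_score = -12.0
        al.query_internal_extend_gap_score = -3.0
        al.query_end_gap_score = 0.0
    aln = al.align(cdna.seq, genomic.seq)[0]
    row_c, row_g = str(aln[0]), str(aln[1])
    introns_raw: list[tuple[int, int]] = []
    g = 0
    matches = aligned = 0
    run = 0
    run_start = 0
    for cc, gc in zip(row_c, row_g):
        if cc == "-" and gc != "-":      # genomic-only column
            if run == 0:
                run_start = g
            run += 1
            g += 1
            continue
        if run:
            if run >= min_intron:
                introns_raw.append((run_start, run_start + run))
            else:
                aligned += run
            run = 0
        if gc != "-":
            aligned += 1
            if cc == gc:
                matches += 1
            g += 1
        else:                            # cDNA-only column
            aligned += 1
    if run:
        if run >= min_intron:
            introns_raw.append((run_start, run_start + run))
        else:
            aligned += run
    if aligned and matches / aligned < min_exon_identity:
        raise ValueError(f"{cdna.id}: exonic identity {matches/aligned:.2%} below "
                         f"{min_exon_identity:.0%}; not a spliced product of {genomic.id}")
    gseq = genomic.seq
    introns: list[tuple[int, int]] = []
    for (s, e) in introns_raw:
        # junction repeats make the cut ambiguous: slide while the flanking
        # bases repeat, prefer a GT...AG-conformant position, else leftmost
        lo = s
        while lo > 0 and gseq[lo - 1] == gseq[lo + (e - s) - 1]:
            lo -= 1
        hi = s
        while hi + (e - s) < len(gseq) and gseq[hi] == gseq[hi + (e - s)]:
            hi += 1
        chosen = lo
        for cand in range(lo, hi + 1):
            ce = cand + (e - s)
            if gseq[cand:cand + 2] == "GT" and gseq[ce - 2:ce] == "AG":
                chosen = cand
                break
        introns.append((chosen, chosen + (e - s)))
    bounds = [0] + [x for se in introns for x in se] + [len(gseq)]
    exons = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
    gt_ag = [gseq[s:s + 2] == "GT" and gseq[e - 2:e] == "AG" for (s, e) in introns]
    return GeneStructure(cdna.id, exons, introns, gt_ag=gt_ag)


# ---------------------------------------------------------------------------
# Intron-position homology across a protein alignment
# ---------------------------------------------------------------------------

def _cdna_pos_to_msa_codon(pos_in_cdna: int, cds_start: int, msa_row: str
                           ) -> tuple[int, int] | None:
    """(codon column in MSA coordinates, phase) for a cDNA nt position."""
    rel = pos_in_cdna - cds_start
    if rel < 0:
        return None
    codon_idx, phase = divmod(rel, 3)
    seen = 0
    for col, ch in enumerate(msa_row):
        if ch != "-":
            if seen == codon_idx:
                return col, phase
            seen += 1
    return None


def compare_structures(structures: dict[str, GeneStructure],
                       msa: MSA, cds_starts: dict[str, int],
                       reference: str) -> pd.DataFrame:
    """Which of the reference gene's introns each gene shares.

    Positions are compared as (protein-MSA codon column, phase).  Cells are
    'shared', 'absent', or the gene's own (column, phase) when an intron
    sits elsewhere.
    """
    pos_by_gene: dict[str, dict[tuple[int, int], int]] = {}
    for gene, st in structures.items():
        if gene not in msa.ids:
            raise ValueError(f"gene {gene!r} absent from alignment")
        row = msa.row(gene)
        mapped = {}
        for k, p in enumerate(st.intron_positions_in_cdna()):
            key = _cdna_pos_to_msa_codon(p, cds_starts[gene], row)
            if key is not None:
                mapped[key] = k
        pos_by_gene[gene] = mapped
    if reference not in pos_by_gene:
        raise ValueError(f"reference {reference!r} has no structure")
    ref_positions = sorted(pos_by_gene[reference], key=lambda kp: kp)
    rows = {}
    for gene, mapped in pos_by_gene.items():
        rows[gene] = ["shared" if key in mapped else "absent" for key in ref_positions]
    cols = [f"intron{i+1}@col{c}.{ph}" for i, (c, ph) in enumerate(ref_positions)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


# ---------------------------------------------------------------------------
# Intron retention between isoforms
# ---------------------------------------------------------------------------

@dataclass
class RetentionReport:
    insert_length: int | None
    insert_position: int | None      # nt offset in the shorter (spliced) isoform
    partial_retention: bool
    matched_intron: int | None       # index into the supplied intron positions
    n_differences: int = 0


def detect_intron_retention(isoform_a: SeqRecord, isoform_b: SeqRecord,
                            intron_positions_in_cdna: list[int] | None = None
                            ) -> RetentionReport:
    """Compare two isoforms of one gene for a single retained block.

    Identifies the inserted block by longest common prefix/suffix of the
    two sequences; with known intron positions (spliced coordinates) the
    call is 'partial retention' when the block sits exactly at an intron
    boundary.  More than one differing block yields no call.
    """
    a, b = isoform_a.seq, isoform_b.seq
    if a == b:
        return RetentionReport(None, None, False, None, 0)
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    diff = len(long_) - len(short)
    if diff == 0:
        n_mismatch = sum(1 for x, y in zip(a, b) if x != y)
        return RetentionReport(None, None, False, None, n_mismatch)
    pre = 0
    while pre < len(short) and short[pre] == long_[pre]:
        pre += 1
    suf = 0
    while suf < len(short) and short[-1 - suf] == long_[-1 - suf]:
        suf += 1
    if pre + suf < len(short):   # leftover mismatches: more than one block
        return RetentionReport(diff, None, False, None,
                               len(short) - pre - suf)
    # single inserted block; junction repeats allow positions in
    # [len(short)-suf, pre] — report the left-justified one
    p_min, p_max = len(short) - suf, pre
    pos = p_min
    matched = None
    if intron_positions_in_cdna:
        for k, ip in enumerate(intron_positions_in_cdna):
            if p_min <= ip <= p_max:
                matched = k
                pos = ip
                break
    return RetentionReport(diff, pos, matched is not None, matched, 0)
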