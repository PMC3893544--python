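"""Transcriptome HGT screening: trimming, contamination filtering, ORF
prediction, length gates, alien score-ratio classification and sister-taxon
exclusion.

The alien ratio is the screen's decision statistic: for each query the
homology hits are partitioned by whether the recipient's taxonomic rank
(e.g. Lamiales) appears in the subject lineage, and

    ratio = best outgroup score / best ingroup score.

A gene is called a horizontal-transfer candidate when the ratio exceeds a
threshold (default 1.2, strict inequality).  Queries with no ingroup hit at
all are candidates-with-flag: the ratio is undefined and downstream
phylogenetic confirmation is mandatory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import CountTable, Hit, SeqRecord

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Constants of the screening stage.

    Defaults follow the screen this package re-implements: Phred floor 25,
    transcripts >= 300 nt, ORFs >= 100 aa, alien ratio > 1.2, with the
    ingroup at order rank and a designated sister taxon for the
    nucleotide-level exclusion step.
    """

    quality_floor: int = 25
    min_transcript_nt: int = 300
    min_orf_aa: int = 100
    ratio_threshold: float = 1.2
    ingroup_rank_name: str = "Lamiales"
    sister_taxon_name: str = "Mimulus guttatus"
    kmer_length: int = 21
    adapters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")
        if min(self.quality_floor, self.min_transcript_nt, self.min_orf_aa,
               self.kmer_length) <= 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# Read trimming
# ---------------------------------------------------------------------------

def trim_reads(records: Iterable[SeqRecord], quality_floor: int = 25,
               adapters: Sequence[str] = ()) -> list[SeqRecord]:
    """Adapter-clip then quality-truncate each read.

    The adapter's first exact occurrence and everything 3' of it are
    removed; then the read is truncated at the first base whose quality is
    below the floor (keeping the longest all-above-floor prefix).  Empty
    reads are dropped.  Adapters longer than the read leave it unchanged.
    """
    out = []
    for rec in records:
        if rec.quality is None:
            raise ValueError(f"{rec.id}: quality values required for trimming")
        seq, qual = rec.seq, list(rec.quality)
        for ad in adapters:
            if not ad or len(ad) > len(seq):
                continue
            pos = seq.find(ad.upper())
            if pos >= 0:
                seq, qual = seq[:pos], qual[:pos]
        cut = len(seq)
        for i, q in enumerate(qual):
            if q < quality_floor:
                cut = i
                break
        seq, qual = seq[:cut], qual[:cut]
        if seq:
            out.append(SeqRecord(rec.id, seq, quality=qual))
    return out


# ---------------------------------------------------------------------------
# k-mer read assignment
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _kmers(seq: str, k: int):
    return (seq[i:i + k] for i in range(len(seq) - k + 1))


@dataclass
class AssignmentReport:
    unassigned_fragments: int = 0
    total_fragments: int = 0


def assign_reads(transcripts: Sequence[SeqRecord],
                 reads_by_stage: Mapping[str, Sequence[SeqRecord]],
                 k: int = 21) -> tuple[CountTable, AssignmentReport]:
    """Fragment counts per transcript per stage by shared-k-mer voting.

    A fragment (read pair, mates identified by ``/1``/``/2`` suffixes, or a
    single read otherwise) is assigned to every transcript sharing its
    maximal number of matching k-mers, with fractional 1/t credit on ties.
    Both read orientations are considered.  Fragments sharing no k-mer with
    any transcript are counted in the report.
    """
    index: dict[str, set[str]] = {}
    for tr in transcripts:
        for km in set(_kmers(tr.seq, k)):
            index.setdefault(km, set()).add(tr.id)
    report = AssignmentReport()
    stage_counts: dict[str, dict[str, float]] = {}
    for stage, reads in reads_by_stage.items():
        frags: dict[str, list[SeqRecord]] = {}
        for rec in reads:
            base = rec.id[:-2] if rec.id.endswith(("/1", "/2")) else rec.id
            frags.setdefault(base, []).append(rec)
        counts: dict[str, float] = {tr.id: 0.0 for tr in transcripts}
        for base, mates in frags.items():
            report.total_fragments += 1
            votes: dict[str, int] = {}
            for mate in mates:
                if len(mate.seq) < k:
                    continue
                fwd: dict[str, int] = {}
                rev: dict[str, int] = {}
                for km in _kmers(mate.seq, k):
                    for tid in index.get(km, ()):
                        fwd[tid] = fwd.get(tid, 0) + 1
                for km in _kmers(_revcomp(mate.seq), k):
                    for tid in index.get(km, ()):
                        rev[tid] = rev.get(tid, 0) + 1
                for tid in set(fwd) | set(rev):
                    votes[tid] = votes.get(tid, 0) + max(fwd.get(tid, 0), rev.get(tid, 0))
            if not votes:
                report.unassigned_fragments += 1
                continue
            best = max(votes.values())
            winners = [tid for tid, v in votes.items() if v == best]
            for tid in winners:
                counts[tid] += 1.0 / len(winners)
        stage_counts[stage] = counts
    df = pd.DataFrame(stage_counts)
    df = df.reindex([tr.id for tr in transcripts])
    lengths = pd.Series({tr.id: float(len(tr.seq)) for tr in transcripts})
    return CountTable(df, lengths), report


# ---------------------------------------------------------------------------
# Contamination filter
# ---------------------------------------------------------------------------

def contamination_filter(transcripts: Sequence[SeqRecord], counts: CountTable,
                         host_free_stages: Sequence[str]
                         ) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Keep transcripts with >= 1 fragment summed over host-free stages.

    Transcripts expressed only when the parasite is attached to a host are
    presumed host contamination and removed.  The rule pools the host-free
    stages (union, not per-stage intersection).
    """
    if not host_free_stages:
        raise ValueError("need at least one host-free stage")
    missing = set(host_free_stages) - set(counts.counts.columns)
    if missing:
        raise ValueError(f"stages absent from count table: {sorted(missing)}")
    total = counts.counts[list(host_free_stages)].sum(axis=1)
    kept, removed = [], []
    for tr in transcripts:
        (kept if total.get(tr.id, 0.0) >= 1.0 else removed).append(tr)
    return kept, removed


# ---------------------------------------------------------------------------
# ORF prediction
# ---------------------------------------------------------------------------

@dataclass
class OrfResult:
    protein: SeqRecord
    strand: str                 # '+' or '-'
    frame: int                  # 0..2 within the strand
    start: int                  # 0-based half-open on the *given* transcript
    end: int
    no_atg: bool = False


def _translate(seq: str) -> str:
    pad = (-len(seq)) % 3
    return str(Seq(seq + "N" * pad).translate()).rstrip("X" if pad else "")


def predict_orf(transcript: SeqRecord) -> OrfResult:
    """Longest ATG-to-stop open reading frame across all six frames.

    The stop codon is excluded from the protein.  Ties break forward strand
    before reverse, then leftmost start.  If no ATG-initiated ORF exists the
    longest stop-free stretch is returned with ``no_atg`` set.  Ambiguity
    codes translate to X.
    """
    if len(transcript.seq) < 3:
        raise ValueError("transcript shorter than one codon")
    best = None          # (length, strand_rank, start) for ATG orfs
    best_open = None     # fallback: longest stop-free stretch
    n = len(transcript.seq)
    for strand, seq in (("+", transcript.seq), ("-", _revcomp(transcript.seq))):
        strand_rank = 0 if strand == "+" else 1
        for frame in range(3):
            aa = _translate(seq[frame:])
            # scan segments between stops
            seg_start = 0
            for seg in aa.split("*"):
                if seg:
                    m = seg.find("M")
                    if m >= 0:
                        orf_aa = seg[m:]
                        start_nt = frame + 3 * (seg_start + m)
                        cand = (-len(orf_aa), strand_rank, start_nt)
                        if best is None or cand < best[0]:
                            best = (cand, strand, frame, start_nt, orf_aa)
                    cand_open = (-len(seg), strand_rank, frame + 3 * seg_start)
                    if best_open is None or cand_open < best_open[0]:
                        best_open = (cand_open, strand, frame, frame + 3 * seg_start, seg)
                seg_start += len(seg) + 1
    chosen, no_atg = (best, False) if best is not None else (best_open, True)
    if chosen is None:
        raise ValueError(f"{transcript.id}: no open reading frame")
    _, strand, frame, start_nt, orf_aa = chosen
    nt_len = 3 * len(orf_aa)
    if strand == "+":
        start, end = start_nt, start_nt + nt_len
    else:
        start, end = n - (start_nt + nt_len), n - start_nt
    prot = SeqRecord(transcript.id + "_orf", orf_aa, moltype="protein")
    return OrfResult(prot, strand, frame, start, end, no_atg)


# ---------------------------------------------------------------------------
# Length gates
# ---------------------------------------------------------------------------

@dataclass
class GateResult:
    passed: bool
    reason: str = ""


def length_gates(transcript: SeqRecord, orf: OrfResult,
                 config: ScreenConfig) -> GateResult:
    """Pass iff transcript >= min nt AND ORF >= min aa (inclusive bounds)."""
    if len(transcript.seq) < config.min_transcript_nt:
        return GateResult(False, "transcript_too_short")
    if len(orf.protein.seq) < config.min_orf_aa:
        return GateResult(False, "orf_too_short")
    return GateResult(True)


# ---------------------------------------------------------------------------
# Alien score ratio
# ---------------------------------------------------------------------------

@dataclass
class AlienVerdict:
    query_id: str
    best_ingroup_hit: Hit | None
    best_outgroup_hit: Hit | None
    ratio: float                 # +inf when no ingroup hit
    is_candidate: bool
    flags: set[str] = field(default_factory=set)


def _is_self_hit(query_id: str, hit: Hit) -> bool:
    return hit.subject_id == query_id or (
        hit.percent_identity >= 100.0 and hit.aln_length >= hit.qend - hit.qstart > 0)


def alien_score(hits: Sequence[Hit], config: ScreenConfig,
                query_id: str | None = None) -> AlienVerdict:
    """Classify one query by the taxon-partitioned score ratio.

    "First hit" means highest bit score after removing self-hits.  With no
    ingroup hit the ratio is +inf and the query is a candidate flagged
    ``no_ingroup_hit``; with no outgroup hit it cannot be a candidate.
    """
    qid = query_id or (hits[0].query_id if hits else "?")
    flags: set[str] = set()
    usable = [h for h in hits if not _is_self_hit(qid, h)]
    ingroup = [h for h in usable if config.ingroup_rank_name in h.lineage]
    outgroup = [h for h in usable if config.ingroup_rank_name not in h.lineage]
    best_in = max(ingroup, key=lambda h: h.bit_score, default=None)
    best_out = max(outgroup, key=lambda h: h.bit_score, default=None)
    if best_in is None:
        flags.add("no_ingroup_hit")
    if best_out is None:
        flags.add("no_outgroup_hit")
    if best_out is None:
        ratio, cand = 0.0, False
    elif best_in is None:
        ratio, cand = math.inf, True
    else:
        ratio = best_out.bit_score / best_in.bit_score
        cand = ratio > config.ratio_threshold
    return AlienVerdict(qid, best_in, best_out, ratio, cand, flags)


def sister_taxon_filter(verdicts: Sequence[AlienVerdict],
                        cdna_hits: Mapping[str, Sequence[Hit]],
                        config: ScreenConfig) -> list[AlienVerdict]:
    """Remove candidates whose best cDNA-level hit is the sister taxon.

    Guards against non-coding sequence rigidly translated into spurious
    protein hits: real recipient-lineage genes show nucleotide-level
    affinity to the sister taxon.  Candidates without cDNA hits are retained
    (logged).
    """
    out = []
    for v in verdicts:
        if v.is_candidate:
            hits = sorted(cdna_hits.get(v.query_id, []), key=lambda h: -h.bit_score)
            if not hits:
                logger.info("%s: no cDNA-level hits; retained", v.query_id)
            elif config.sister_taxon_name in hits[0].lineage:
                v = AlienVerdict(v.query_id, v.best_ingroup_hit, v.best_outgroup_hit,
                                 v.ratio, False, v.flags | {"sister_taxon_cdna_hit"})
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# Full screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    verdicts: list[AlienVerdict]
    report: pd.DataFrame          # one row per surviving transcript
    removed_contaminants: list[str]
    failed_gates: dict[str, str]
    counts: CountTable

    @property
    def candidates(self) -> list[str]:
        return [v.query_id for v in self.verdicts if v.is_candidate]


def run_screen(transcripts: Sequence[SeqRecord],
               reads_by_stage: Mapping[str, Sequence[SeqRecord]],
               host_free_stages: Sequence[str],
               protein_hits: Mapping[str, Sequence[Hit]],
               cdna_hits: Mapping[str, Sequence[Hit]] | None = None,
               config: ScreenConfig | None = None,
               trim: bool = True) -> ScreenResult:
    """The full screening cascade.

    trim -> k-mer read assignment -> contamination filter -> ORF prediction
    -> length gates -> alien score ratio -> sister-taxon exclusion.  The
    report lists one row per surviving transcript sorted by descending
    ratio (ties by id).
    """
    config = config or ScreenConfig()
    reads = {stage: (trim_reads(rs, config.quality_floor, config.adapters) if trim else list(rs))
             for stage, rs in reads_by_stage.items()}
    counts, _ = assign_reads(transcripts, reads, k=config.kmer_length)
    kept, removed = contamination_filter(transcripts, counts, host_free_stages)
    failed: dict[str, str] = {}
    verdicts: list[AlienVerdict] = []
    for tr in kept:
        if len(tr.seq) < max(3, config.min_transcript_nt):
            failed[tr.id] = "transcript_too_short"
            continue
        orf = predict_orf(tr)
        gate = length_gates(tr, orf, config)
        if not gate.passed:
            failed[tr.id] = gate.reason
            continue
        verdicts.append(alien_score(list(protein_hits.get(tr.id, [])), config,
                                    query_id=tr.id))
    if cdna_hits is not None:
        verdicts = sister_taxon_filter(verdicts, cdna_hits, config)
    verdicts.sort(key=lambda v: (-v.ratio, v.query_id))
    rows = [{
        "query_id": v.query_id,
        "ratio": v.ratio,
        "is_candidate": v.is_candidate,
        "best_ingroup": v.best_ingroup_hit.subject_id if v.best_ingroup_hit else "",
        "best_ingroup_score": v.best_ingroup_hit.bit_score if v.best_ingroup_hit else np.nan,
        "best_outgroup": v.best_outgroup_hit.subject_id if v.best_outgroup_hit else "",
        "best_outgroup_score": v.best_outgroup_hit.bit_score if v.best_outgroup_hit else np.nan,
        "flags": ",".join(sorted(v.flags)),
    } for v in verdicts]
    report = pd.DataFrame(rows, columns=["query_id", "ratio", "is_candidate",
                                         "best_ingroup", "best_ingroup_score",
                                         "best_outgroup", "best_outgroup_score", "flags"])
    return ScreenResult(verdicts, report, [t.id for t in removed], failed, counts)
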