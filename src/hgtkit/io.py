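"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* All internal coordinates are 0-based half-open.  Tabular homology hits
  arrive in the 12-column BLAST dialect (1-based inclusive coordinates) and
  are converted on ingest.
* Lineages are ordered name lists (kingdom -> species); clade membership is
  a plain ``name in lineage`` test, matching rank-level screening
  (e.g. "Lamiales", "Brassicales").
* FASTQ qualities are Phred+33 unless another offset is given.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

DNA_CHARS = set("ACGTUNRYSWKMBDHV-")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")


class FormatError(ValueError):
    """Malformed input; message carries file and line context."""


@dataclass
class SeqRecord:
    """A nucleotide or amino-acid sequence with optional Phred qualities."""

    id: str
    seq: str
    quality: list[int] | None = None
    moltype: str = "dna"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        allowed = DNA_CHARS if self.moltype == "dna" else PROTEIN_CHARS
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(f"{self.id}: characters {sorted(bad)} not valid for {self.moltype}")
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ValueError(f"{self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Hit:
    """One homology-search hit with its subject's taxonomic lineage."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    bit_score: float
    e_value: float
    lineage: list[str] = field(default_factory=list)
    # query coordinates, 0-based half-open (converted from BLAST 1-based inclusive)
    qstart: int = 0
    qend: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.bit_score) or self.bit_score < 0:
            raise ValueError(f"{self.query_id}->{self.subject_id}: bit score must be finite and >= 0")
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class MSA:
    """Aligned sequences ('-' gaps) with optional named, disjoint groups."""

    records: list[SeqRecord]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records:
            n = len(self.records[0].seq)
            for r in self.records:
                if len(r.seq) != n:
                    raise ValueError(f"row {r.id} has length {len(r.seq)} != {n}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        seen: set[str] = set()
        for name, members in self.groups.items():
            extra = set(members) - set(ids)
            if extra:
                raise ValueError(f"group {name}: members {sorted(extra)} not rows of the alignment")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"group {name}: members {sorted(overlap)} already in another group")
            seen |= set(members)

    @property
    def n_cols(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, rid: str) -> str:
        for r in self.records:
            if r.id == rid:
                return r.seq
        raise KeyError(rid)

    def column(self, j: int) -> str:
        return "".join(r.seq[j] for r in self.records)

    def subset(self, ids: Sequence[str]) -> "MSA":
        wanted = set(ids)
        return MSA([r for r in self.records if r.id in wanted])


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, moltype: str = "dna") -> list[SeqRecord]:
    """Read a FASTA file; IDs are the first whitespace token of each header.

    Duplicate IDs raise :class:`FormatError` listing the offenders; an empty
    file returns an empty list with a warning.  Lowercase sequence is
    uppercased (logged).
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: dict[str, int] = {}
    had_lower = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if raw != raw.upper():
            had_lower.append(rec.id)
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(SeqRecord(rec.id, raw.upper(), moltype=moltype))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise FormatError(f"{path}: duplicate sequence ids: {dupes}")
    if not records:
        logger.warning("%s: empty FASTA file", path)
    if had_lower:
        logger.info("%s: uppercased %d lowercase/mixed-case records (%s...)",
                    path, len(had_lower), had_lower[0])
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path: str | Path, offset: int = 33) -> list[SeqRecord]:
    """Read FASTQ with the given Phred offset (default Phred+33)."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if offset != 33:
            quals = [q + 33 - offset for q in quals]
        records.append(SeqRecord(rec.id, str(rec.seq).upper(), quality=list(quals)))
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path, offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.quality is None:
                raise ValueError(f"{r.id}: FASTQ output requires qualities")
            qual = "".join(chr(q + offset) for q in r.quality)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "aln_length", "mismatches",
    "gap_opens", "qstart", "qend", "sstart", "send", "e_value", "bit_score",
]


def read_lineage_map(path: str | Path) -> dict[str, list[str]]:
    """TSV ``subject_id <tab> semicolon-joined lineage`` -> ordered name lists."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{i}: expected 2 tab-separated fields, got {len(parts)}")
            out[parts[0]] = [t.strip() for t in parts[1].split(";") if t.strip()]
    return out


@dataclass
class HitTableReport:
    """Subjects that could not be joined to the lineage map."""

    unmapped_subjects: list[str] = field(default_factory=list)
    dropped_rows: int = 0


def read_hit_table(
    path: str | Path,
    lineage_map_path: str | Path | None = None,
    lineage_map: Mapping[str, list[str]] | None = None,
    on_unmapped: str = "drop",
) -> tuple[dict[str, list[Hit]], HitTableReport]:
    """Parse a 12-column tab-separated homology hit table.

    Returns hits grouped by query, each group sorted by descending bit score,
    plus a report of subjects missing from the lineage map.  ``on_unmapped``
    is ``drop`` (default, with warning) or ``error``.
    """
    if lineage_map is None:
        lineage_map = read_lineage_map(lineage_map_path) if lineage_map_path else {}
    report = HitTableReport()
    grouped: dict[str, list[Hit]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{i}: expected 12 columns, got {len(parts)}")
            try:
                bit = float(parts[11])
                evalue = float(parts[10])
                pid = float(parts[2])
                alen = int(parts[3])
                qstart = int(parts[6])
                qend = int(parts[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: non-numeric field ({exc})") from None
            subject = parts[1]
            lineage = lineage_map.get(subject)
            if lineage is None:
                report.unmapped_subjects.append(subject)
                if on_unmapped == "error":
                    raise FormatError(f"{path}:{i}: subject {subject!r} missing from lineage map")
                report.dropped_rows += 1
                continue
            hit = Hit(parts[0], subject, pid, alen, bit, evalue, list(lineage),
                      qstart=qstart - 1, qend=qend)
            grouped.setdefault(hit.query_id, []).append(hit)
    if report.unmapped_subjects:
        logger.warning("%s: %d rows dropped (subjects missing from lineage map)",
                       path, report.dropped_rows)
    for hits in grouped.values():
        hits.sort(key=lambda h: -h.bit_score)
    return grouped, report


def write_hit_table(grouped: Mapping[str, list[Hit]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for query in grouped:
            for h in grouped[query]:
                fh.write("\t".join(map(str, [
                    h.query_id, h.subject_id, h.percent_identity, h.aln_length,
                    0, 0, h.qstart + 1, h.qend, 0, 0, h.e_value, h.bit_score,
                ])) + "\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree; internal node labels are read as support values."""
    try:
        is_file = Path(str(source)).exists()
    except OSError:
        is_file = False
    text = Path(source).read_text() if is_file else str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from None
    leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaf_names)) != len(leaf_names):
        raise FormatError("duplicate leaf names in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Count and Ct tables (pandas-backed)
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Fragment counts per transcript per stage plus effective lengths (nt)."""

    counts: pd.DataFrame          # index transcript_id, columns stage labels
    lengths: pd.Series            # index transcript_id -> effective length nt

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative fragment counts")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise ValueError(f"lengths missing for transcripts: {sorted(missing)[:5]}")


def read_count_table(path: str | Path) -> CountTable:
    """TSV with columns ``transcript_id, length`` then one column per stage."""
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns or "length" not in df.columns:
        raise FormatError(f"{path}: need 'transcript_id' and 'length' columns")
    df = df.set_index("transcript_id")
    lengths = df.pop("length")
    return CountTable(df, lengths)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "length", table.lengths)
    df.to_csv(path, sep="\t", index_label="transcript_id")


@dataclass
class CtTable:
    """qPCR cycle-threshold replicates in long form.

    Columns: gene, sample, condition, replicate, ct.  Conditions label the
    biological contrast (e.g. hours after wounding); samples are individual
    RNA preparations.
    """

    data: pd.DataFrame

    REQUIRED = ("gene", "sample", "condition", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))


def read_ct_table(path: str | Path) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment FASTA
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, moltype: str = "protein",
                   groups: Mapping[str, Sequence[str]] | None = None) -> MSA:
    records = read_fasta(path, moltype=moltype)
    return MSA(records, {k: list(v) for k, v in (groups or {}).items()})


def write_alignment(msa: MSA, path: str | Path) -> None:
    write_fasta(msa.records, path)
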