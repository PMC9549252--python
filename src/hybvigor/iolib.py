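"""Readers and writers for the formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals on the
forward genomic axis. Conversions happen only at the file boundary: GFF3 is
1-based closed (start shifts by one on read/write), BED is already 0-based
half-open and passes through unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VARIETIES = ("maternal", "hybrid", "paternal")

_VALID_DNA = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Inconsistent configuration or metadata."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """An in-memory genome: ordered chromosome names and uppercase DNA."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) == 0:
            raise FormatError("genome has no sequences")
        for name, seq in self.sequences.items():
            if len(seq) == 0:
                raise FormatError(f"chromosome {name!r} has empty sequence")
            if not set(seq) <= _VALID_DNA:
                raise FormatError(f"chromosome {name!r} holds non-ACGTN characters")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _check_interval(name: str, chrom: str, start: int, end: int,
                    exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    if start < 0 or end <= start:
        raise FormatError(f"{name}: invalid interval {chrom}:{start}-{end}")
    exons = sorted((int(a), int(b)) for a, b in exons)
    prev_end = None
    for a, b in exons:
        if a >= b:
            raise FormatError(f"{name}: empty exon ({a},{b})")
        if a < start or b > end:
            raise FormatError(f"{name}: exon ({a},{b}) outside [{start},{end})")
        if prev_end is not None and a < prev_end:
            raise FormatError(f"{name}: overlapping exons near {a}")
        prev_end = b
    return exons


@dataclass
class GeneModel:
    """A stranded gene with sorted, disjoint exons (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = _check_interval(self.gene_id, self.chrom, self.start,
                                     self.end, self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TranscriptRecord:
    """A transcript interval with an RNA class label."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    rna_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.rna_class not in {"mRNA", "lncRNA", "circRNA", "miRNA", "unknown"}:
            raise FormatError(f"{self.transcript_id}: bad rna_class {self.rna_class!r}")
        self.exons = _check_interval(self.transcript_id, self.chrom, self.start,
                                     self.end, self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome: GenomeSequence) -> str:
        """Genomic (sense-strand) sequence of the transcript span."""
        seq = genome[self.chrom][self.start:self.end]
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


@dataclass
class CountTable:
    """Integer counts (features x samples) plus the trio sample design."""

    counts: pd.DataFrame                       # index: feature, columns: sample
    design: pd.DataFrame                       # index: sample; variety, replicate

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicated feature id(s): {dupes}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("negative counts present")
        if not (vals == vals.astype(int)).all():
            raise FormatError("non-integer counts present")
        self.counts = self.counts.astype(int)
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ConfigError(f"samples missing from design: {sorted(missing)}")
        bad = set(self.design["variety"]) - set(VARIETIES)
        if bad:
            raise ConfigError(f"unknown varieties in design: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, variety: str) -> list[str]:
        sel = self.design.loc[self.design["variety"] == variety].index
        return [s for s in self.sample_ids if s in set(sel)]

    def is_full_design(self) -> bool:
        """True when every variety has exactly three replicates."""
        per = self.design.loc[self.sample_ids, "variety"].value_counts()
        return all(per.get(v, 0) == 3 for v in VARIETIES)

    def subset(self, feature_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(feature_ids)].copy(), self.design)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def circ_id(chrom: str, donor: int, acceptor: int) -> str:
    """Joinable circRNA key, ``chrom:acceptor|donor`` (genomic low|high)."""
    lo, hi = sorted((donor, acceptor))
    return f"{chrom}:{lo}|{hi}"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; characters outside ACGTN become N with a
    logged warning. Duplicate headers and empty files are format errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        cleaned = _NON_ACGTN.sub("N", seq)
        if cleaned != seq:
            n_bad = sum(a != b for a, b in zip(seq, cleaned))
            logger.warning("%s: %d non-ACGTN character(s) in %r mapped to N",
                           path, n_bad, rec.id)
        records[rec.id] = cleaned
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence | Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    seqs = genome.sequences if isinstance(genome, GenomeSequence) else genome
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_reads_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA read set as ``{read_id: sequence}`` (uppercased)."""
    reads: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in reads:
            raise FormatError(f"duplicate read id {rec.id!r} in {path}")
        reads[rec.id] = _NON_ACGTN.sub("N", str(rec.seq).upper())
    return reads


# ---------------------------------------------------------------------------
# GFF3 (1-based closed on disk; gene/mRNA-like records with exon children)
# ---------------------------------------------------------------------------

_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")

_TRANSCRIPT_TYPES = {"mRNA", "lncRNA", "circRNA", "miRNA", "transcript"}


def _parse_attrs(text: str) -> dict[str, str]:
    return dict(_GFF_ATTR.findall(text))


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, converting to 0-based half-open.

    Recognized feature types: ``gene`` and ``exon`` (grouped under a gene
    via the ``Parent`` attribute). Exons whose parent is unknown, and
    records with end < start, are format errors.
    """
    genes: dict[str, GeneModel] = {}
    pending_exons: list[tuple[str, int, int, str]] = []
    for ln, line in enumerate(_gff_lines(path), start=1):
        chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = line
        start0, end0 = int(start1) - 1, int(end1)
        if end0 <= start0:
            raise FormatError(f"{path}:{ln}: end < start")
        a = _parse_attrs(attrs)
        if ftype == "gene":
            gid = a.get("ID") or a.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{ln}: gene without ID")
            genes[gid] = GeneModel(gid, chrom, start0, end0, strand, [])
        elif ftype == "exon":
            parent = a.get("Parent")
            if parent is None:
                raise FormatError(f"{path}:{ln}: exon without Parent")
            pending_exons.append((parent, start0, end0, chrom))
    for parent, s, e, chrom in pending_exons:
        if parent not in genes:
            raise FormatError(f"exon Parent {parent!r} not a known gene")
        genes[parent].exons.append((s, e))
    out = []
    for g in genes.values():
        # re-validate now that exons are attached
        out.append(GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand, g.exons))
    return out


def _gff_lines(path: str | Path):
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns, got {len(parts)}")
            yield parts


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([g.chrom, "hybvigor", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", f"ID={g.gene_id}"]) + "\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write("\t".join([g.chrom, "hybvigor", "exon", str(s + 1), str(e),
                                    ".", g.strand, ".",
                                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]) + "\n")


def read_transcripts_gff3(path: str | Path) -> list[TranscriptRecord]:
    """Read transcript records (transcript-typed rows + exon children)."""
    txs: dict[str, TranscriptRecord] = {}
    pending: list[tuple[str, int, int]] = []
    for ln, line in enumerate(_gff_lines(path), start=1):
        chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = line
        start0, end0 = int(start1) - 1, int(end1)
        if end0 <= start0:
            raise FormatError(f"{path}:{ln}: end < start")
        a = _parse_attrs(attrs)
        if ftype in _TRANSCRIPT_TYPES:
            tid = a.get("ID") or a.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}:{ln}: transcript without ID")
            rna_class = ftype if ftype != "transcript" else a.get("rna_class", "unknown")
            txs[tid] = TranscriptRecord(tid, chrom, start0, end0, strand, [], rna_class)
        elif ftype == "exon":
            parent = a.get("Parent")
            if parent is None:
                raise FormatError(f"{path}:{ln}: exon without Parent")
            pending.append((parent, start0, end0))
    for parent, s, e in pending:
        if parent not in txs:
            raise FormatError(f"exon Parent {parent!r} not a known transcript")
        txs[parent].exons.append((s, e))
    return [TranscriptRecord(t.transcript_id, t.chrom, t.start, t.end, t.strand,
                             t.exons, t.rna_class) for t in txs.values()]


def write_transcripts_gff3(txs: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in txs:
            ftype = t.rna_class if t.rna_class != "unknown" else "transcript"
            fh.write("\t".join([t.chrom, "hybvigor", ftype, str(t.start + 1),
                                str(t.end), ".", t.strand, ".",
                                f"ID={t.transcript_id}"]) + "\n")
            for i, (s, e) in enumerate(t.exons, start=1):
                fh.write("\t".join([t.chrom, "hybvigor", "exon", str(s + 1), str(e),
                                    ".", t.strand, ".",
                                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]) + "\n")


# ---------------------------------------------------------------------------
# BED6 (0-based half-open on disk; passes through unchanged)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            p = raw.split("\t")
            if len(p) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = p[0], int(p[1]), int(p[2])
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            name = p[3] if len(p) > 3 else "."
            score = int(float(p[4])) if len(p) > 4 and p[4] != "." else 0
            strand = p[5] if len(p) > 5 else "+"
            rows.append((chrom, start, end, name, score, strand))
    return rows


def write_bed(rows: Iterable[tuple[str, int, int, str, int, str]],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Count tables and designs (TSV)
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "variety", "replicate"}
    if not required <= set(design.columns):
        raise FormatError(f"design file must have columns {sorted(required)}")
    if design["sample_id"].duplicated().any():
        raise FormatError("duplicated sample_id in design")
    return design.set_index("sample_id")


def read_counts(path: str | Path, design_path: str | Path) -> CountTable:
    """Read a feature x sample TSV and join the sample design."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated feature id(s): {dupes}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric counts in sample {col!r}")
    design = read_design(design_path)
    return CountTable(df, design)


def write_counts(table: CountTable, counts_path: str | Path,
                 design_path: str | Path | None = None) -> None:
    out = table.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(counts_path, sep="\t")
    if design_path is not None:
        d = table.design.copy()
        d.index.name = "sample_id"
        d.to_csv(design_path, sep="\t")


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)
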