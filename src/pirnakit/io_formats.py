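"""Readers and writers for the formats the pipeline exchanges.

Conventions enforced throughout the package:

* all coordinates are 0-based, half-open (``start`` inclusive, ``end``
  exclusive);
* the 5' end of a plus-strand record is ``start``; of a minus-strand record
  it is ``end - 1``;
* BED6 is the canonical exchange format, with the read copy number carried
  in the score column; SAM is accepted as input only;
* reading is gzip-transparent (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

VALID_STRANDS = frozenset({"+", "-", "."})

_COLLAPSED_NAME_RE = re.compile(r"_x(\d+)$")


class FormatError(ValueError):
    """Raised for malformed records; carries the offending line number."""


@dataclass
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5' end position: plus strand -> start, minus strand -> end - 1."""
        if self.strand == "-":
            return self.end - 1
        return self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AlignedPiRNA:
    """One collapsed, uniquely mapped small-RNA read with its copy number."""

    interval: GenomicInterval
    copies: int = 1
    sample: str = ""

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"copies must be >= 1, got {self.copies}")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("aligned reads must be stranded (+ or -)")

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime(self) -> int:
        return self.interval.five_prime

    @property
    def name(self) -> str:
        return self.interval.name


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED6 (or BED3+) file into :class:`GenomicInterval` records."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                iv = GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3] if len(fields) > 3 else ".",
                    score=float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            score = iv.score
            score_str = str(int(score)) if float(score).is_integer() else repr(score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score_str}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Aligned reads (BED6 or SAM)
# ---------------------------------------------------------------------------

def _copies_from_bed(iv: GenomicInterval) -> int:
    """Copy number from the score column, falling back to a name_xN suffix."""
    if iv.score and iv.score > 0:
        if not float(iv.score).is_integer():
            raise ValueError(f"non-integer copy number {iv.score}")
        return int(iv.score)
    m = _COLLAPSED_NAME_RE.search(iv.name)
    if m:
        return int(m.group(1))
    return 1


def _read_alignments_sam(
    path: str | Path, unique_only: bool
) -> Iterator[tuple[GenomicInterval, int]]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if unique_only:
                try:
                    if rec.get_tag("NH") > 1:
                        continue
                except KeyError:
                    if rec.mapping_quality == 0:
                        continue
            iv = GenomicInterval(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                name=rec.query_name or ".",
                strand="-" if rec.is_reverse else "+",
            )
            m = _COLLAPSED_NAME_RE.search(iv.name)
            yield iv, int(m.group(1)) if m else 1


def read_alignments(
    path: str | Path,
    min_len: int = 1,
    max_len: int = 50,
    unique_only: bool = True,
    sample: str = "",
) -> list[AlignedPiRNA]:
    """Read aligned small-RNA records from BED6 or SAM.

    Records with length outside ``[min_len, max_len]`` are dropped.  For SAM
    input, ``unique_only`` drops multimappers (``NH`` tag > 1, or MAPQ 0 when
    no ``NH`` tag is present).  Copy numbers come from the BED score column
    or a ``_xN`` name suffix (default 1).
    """
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    if stem.endswith(".sam"):
        pairs = _read_alignments_sam(path, unique_only)
    else:
        pairs = ((iv, _copies_from_bed(iv)) for iv in read_bed(path))
    out: list[AlignedPiRNA] = []
    for iv, copies in pairs:
        if not (min_len <= len(iv) <= max_len):
            continue
        out.append(AlignedPiRNA(interval=iv, copies=copies, sample=sample))
    return out


def write_alignments(reads: Iterable[AlignedPiRNA], path: str | Path) -> None:
    """Write reads as BED6 with the copy number in the score column."""
    write_bed(
        (
            GenomicInterval(
                chrom=r.chrom,
                start=r.interval.start,
                end=r.interval.end,
                name=r.name,
                score=r.copies,
                strand=r.strand,
            )
            for r in reads
        ),
        path,
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: sequence}`` dict.

    Duplicate headers are an error.  Sequence names are the first
    whitespace-delimited token of the header.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise FormatError(f"duplicate sequence name {rec.id!r} in {path}")
            out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Count tables and generic TSV
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample count table (TSV, first column = feature id).

    Counts must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_numeric_dtype(vals):
            raise FormatError(f"non-numeric counts in column {col!r}")
        if (vals < 0).any():
            raise FormatError(f"negative count in column {col!r}")
        if not (vals == vals.round()).all():
            raise FormatError(f"non-integer count in column {col!r}")
    return df.astype(int)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_tsv(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write records (DataFrame or list of dicts) as TSV with a header row."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    records.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
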