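"""Read-length summaries, 3'-trimming comparison and genomic origin.

The 3'-end comparison groups reads by their exact 5' end (chromosome,
strand, 5' position), takes the copy-weighted median length per group and
compares medians between two libraries; systematic 3' trimming shows up as
a shifted mode of the per-group median differences.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignedPiRNA, GenomicInterval, reverse_complement

# length window used by the 3'-end comparison
MIN_COMPARE_LENGTH = 24
MAX_COMPARE_LENGTH = 40

FivePrimeKey = tuple[str, str, int]  # (chrom, strand, 5' position)


@dataclass
class FivePrimeGroup:
    key: FivePrimeKey
    lengths: dict[int, int]  # length -> total copies
    median_length: float


def weighted_median(
    lengths: Mapping[int, int], rule: str = "lower"
) -> float:
    """Copy-weighted median of an integer multiset.

    ``lower`` returns the element at 1-based rank ``(W + 1) // 2`` (the lower
    median for even total weight, hence always an observed integer);
    ``midpoint`` averages the two central elements, which can yield
    half-integers.
    """
    if not lengths:
        raise ValueError("empty length multiset")
    items = sorted(lengths.items())
    total = sum(w for _, w in items)
    if rule == "lower":
        target = (total + 1) // 2
        acc = 0
        for val, w in items:
            acc += w
            if acc >= target:
                return float(val)
    elif rule == "midpoint":
        lo_rank = (total + 1) // 2
        hi_rank = total // 2 + 1
        acc = 0
        lo = hi = None
        for val, w in items:
            acc += w
            if lo is None and acc >= lo_rank:
                lo = val
            if hi is None and acc >= hi_rank:
                hi = val
                break
        return (lo + hi) / 2.0
    else:
        raise ValueError(f"unknown median rule {rule!r}")
    raise AssertionError("unreachable")


def median_length_by_5prime(
    reads: Iterable[AlignedPiRNA],
    min_len: int = MIN_COMPARE_LENGTH,
    max_len: int = MAX_COMPARE_LENGTH,
    rule: str = "lower",
) -> dict[FivePrimeKey, FivePrimeGroup]:
    """Group reads by (chrom, strand, 5' position); copy-weighted median each.

    Reads outside ``[min_len, max_len]`` are excluded before grouping.
    """
    groups: dict[FivePrimeKey, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for r in reads:
        if not (min_len <= r.length <= max_len):
            continue
        groups[(r.chrom, r.strand, r.five_prime)][r.length] += r.copies
    return {
        key: FivePrimeGroup(
            key=key, lengths=dict(lengths), median_length=weighted_median(lengths, rule)
        )
        for key, lengths in groups.items()
    }


@dataclass
class DeltaMedianResult:
    deltas: dict[FivePrimeKey, float]  # median_b - median_a per shared key
    histogram: dict[float, int]
    no_shared_keys: bool = False

    @property
    def modal_delta(self) -> float | None:
        if not self.histogram:
            return None
        return max(sorted(self.histogram), key=lambda d: self.histogram[d])


def delta_median(
    groups_a: Mapping[FivePrimeKey, FivePrimeGroup],
    groups_b: Mapping[FivePrimeKey, FivePrimeGroup],
) -> DeltaMedianResult:
    """Per-5'-end median length differences, ``median_b - median_a``.

    Only keys present in both collections contribute.  A negative modal
    delta of ``-k`` indicates a systematic k-nt 3' truncation in b.
    """
    shared = groups_a.keys() & groups_b.keys()
    deltas = {k: groups_b[k].median_length - groups_a[k].median_length for k in shared}
    hist = Counter(deltas.values())
    return DeltaMedianResult(
        deltas=deltas, histogram=dict(hist), no_shared_keys=not shared
    )


def length_histogram(
    reads: Iterable[AlignedPiRNA],
    min_len: int = MIN_COMPARE_LENGTH,
    max_len: int = MAX_COMPARE_LENGTH,
) -> dict[int, int]:
    """Copy-weighted read counts per length over ``min_len..max_len``."""
    hist = {L: 0 for L in range(min_len, max_len + 1)}
    for r in reads:
        if min_len <= r.length <= max_len:
            hist[r.length] += r.copies
    return hist


_BASES = "ACGU"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def read_sequence(read: AlignedPiRNA, genome: Mapping[str, str]) -> str:
    """Genome-derived read sequence, 5'->3' (reverse complement on minus)."""
    chrom_seq = genome[read.chrom]
    if read.interval.end > len(chrom_seq) or read.interval.start < 0:
        raise ValueError(
            f"read {read.name} at {read.chrom}:{read.interval.start}-"
            f"{read.interval.end} exceeds genome bounds"
        )
    seq = chrom_seq[read.interval.start : read.interval.end]
    if read.strand == "-":
        seq = reverse_complement(seq)
    return seq.upper().replace("T", "U")


def nucleotide_composition(
    reads: Sequence[AlignedPiRNA],
    genome: Mapping[str, str],
    n_positions: int = 10,
) -> np.ndarray:
    """Copy-weighted base frequencies per read position.

    Returns an ``(n_positions, 4)`` matrix over A/C/G/U; row ``i`` covers
    read position ``i + 1`` and sums to 1 over the reads long enough to
    have that position.  T is reported as U; the first row's U column is
    the 1U-bias fraction.
    """
    counts = np.zeros((n_positions, 4), dtype=float)
    for r in reads:
        seq = read_sequence(r, genome)
        for i in range(min(n_positions, len(seq))):
            j = _BASE_INDEX.get(seq[i])
            if j is not None:
                counts[i, j] += r.copies
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return freqs


def first_position_u_fraction(
    reads: Sequence[AlignedPiRNA], genome: Mapping[str, str]
) -> float:
    comp = nucleotide_composition(reads, genome, n_positions=1)
    return float(comp[0, _BASE_INDEX["U"]])


DEFAULT_PRECEDENCE = ("cluster", "gene", "repeat")


def genomic_feature_assignment(
    reads: Sequence[AlignedPiRNA],
    annotations: Mapping[str, Sequence[GenomicInterval]],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    min_overlap_fraction: float = 0.5,
) -> dict[str, int]:
    """Assign each read to exactly one genomic category.

    A read is assigned to the first category in ``precedence`` whose
    intervals cover at least ``min_overlap_fraction`` of the read's span
    (full interval, strand-agnostic); otherwise it is ``intergenic``.
    Counts are copy-weighted and always sum to the copy-weighted total.
    """
    by_chrom: dict[str, dict[str, list[GenomicInterval]]] = {}
    for cat in precedence:
        for iv in annotations.get(cat, ()):  # tolerate absent categories
            by_chrom.setdefault(cat, {}).setdefault(iv.chrom, []).append(iv)

    counts = {cat: 0 for cat in precedence}
    counts["intergenic"] = 0
    for r in reads:
        assigned = "intergenic"
        need = min_overlap_fraction * r.length
        for cat in precedence:
            ivs = by_chrom.get(cat, {}).get(r.chrom, ())
            if any(iv.overlap(r.interval) >= need for iv in ivs):
                assigned = cat
                break
        counts[assigned] += r.copies
    return counts
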