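"""Ping-pong amplification analysis.

Opposite-strand read pairs are scored by the distance between their 5' ends:
for a plus-strand read with 5' end ``p`` and a minus-strand read with 5' end
``m`` on the same chromosome, the overlap distance is ``d = m - p + 1``, so
two reads whose 5' ends overlap by exactly 10 nt score ``d = 10``.  Distances
are accumulated over a 30-nt window (``d`` in 1..30) into a weight histogram,
and the amplification signature is the z-score of the weight at ``d = 10``
against the sample mean and unbiased sample variance of the 29 other bins:

    z = (w(10) - mean(w(d != 10))) / sqrt(var(w(d != 10)) / n),   n = 29
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import AlignedPiRNA

DEFAULT_WINDOW = 30
PING_PONG_DISTANCE = 10

WEIGHTING_MODES = ("product", "unique")


@dataclass
class DistanceHistogram:
    """Weights of opposite-strand 5'-5' overlap distances over 1..window."""

    w: dict[int, float]
    weighting_mode: str = "product"
    window: int = DEFAULT_WINDOW
    empty_input: bool = False

    def __post_init__(self) -> None:
        full = {d: float(self.w.get(d, 0.0)) for d in range(1, self.window + 1)}
        if any(v < 0 for v in full.values()):
            raise ValueError("histogram weights must be non-negative")
        self.w = full

    @property
    def n_background(self) -> int:
        return self.window - 1

    def background(self, peak: int = PING_PONG_DISTANCE) -> list[float]:
        return [self.w[d] for d in sorted(self.w) if d != peak]


@dataclass
class PingPongStat:
    z: float
    w10: float
    background_mean: float
    background_var: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not math.isfinite(self.z):
            raise ValueError("non-degenerate z-score must be finite")


def _index_by_five_prime(
    reads: Iterable[AlignedPiRNA], strand: str
) -> dict[str, dict[int, tuple[float, int]]]:
    """chrom -> 5' position -> (total copies, number of reads) on `strand`."""
    idx: dict[str, dict[int, list]] = defaultdict(lambda: defaultdict(lambda: [0.0, 0]))
    for r in reads:
        if r.strand != strand:
            continue
        cell = idx[r.chrom][r.five_prime]
        cell[0] += r.copies
        cell[1] += 1
    return {c: {p: (v[0], v[1]) for p, v in d.items()} for c, d in idx.items()}


def _accumulate(
    plus_reads: Sequence[AlignedPiRNA],
    minus_index: dict[str, dict[int, tuple[float, int]]],
    window: int,
    weighting: str,
    w: dict[int, float],
) -> None:
    for r in plus_reads:
        if r.strand != "+":
            continue
        chrom_idx = minus_index.get(r.chrom)
        if not chrom_idx:
            continue
        p = r.five_prime
        for d in range(1, window + 1):
            hit = chrom_idx.get(p + d - 1)
            if hit is None:
                continue
            copies_sum, n_reads = hit
            if weighting == "product":
                w[d] += r.copies * copies_sum
            else:
                w[d] += n_reads


def five_prime_distance_histogram(
    reads_a: Sequence[AlignedPiRNA],
    reads_b: Sequence[AlignedPiRNA] | None = None,
    window: int = DEFAULT_WINDOW,
    weighting: str = "product",
) -> DistanceHistogram:
    """Histogram of opposite-strand 5'-5' overlap distances.

    ``reads_b=None`` (or passing the same object) runs homotypic mode, where
    each unordered opposite-strand pair is counted once.  Heterotypic mode
    accumulates plus(a) x minus(b) and plus(b) x minus(a), which makes the
    result symmetric in its two arguments.

    In ``product`` weighting each pair contributes the product of the two
    copy numbers; in ``unique`` weighting each pair contributes 1.
    """
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {WEIGHTING_MODES}")
    homotypic = reads_b is None or reads_b is reads_a
    if reads_b is None:
        reads_b = reads_a

    w: dict[int, float] = {d: 0.0 for d in range(1, window + 1)}
    _accumulate(reads_a, _index_by_five_prime(reads_b, "-"), window, weighting, w)
    if not homotypic:
        _accumulate(reads_b, _index_by_five_prime(reads_a, "-"), window, weighting, w)
    empty = len(reads_a) == 0 and len(reads_b) == 0
    return DistanceHistogram(w=w, weighting_mode=weighting, window=window, empty_input=empty)


def pingpong_zscore(
    hist: DistanceHistogram, peak: int = PING_PONG_DISTANCE
) -> PingPongStat:
    """z-score of the peak-bin weight against the other bins of the window.

    Background mean is the sample mean and background variance the unbiased
    (n-1) sample variance of the ``window - 1`` off-peak weights.  A zero
    background variance yields a flagged degenerate result rather than a
    silent infinity.
    """
    bg = hist.background(peak)
    n = len(bg)
    mean = sum(bg) / n
    var = sum((x - mean) ** 2 for x in bg) / (n - 1)
    w10 = hist.w[peak]
    if var == 0.0:
        # perfectly flat background: zero excess is a well-defined z of 0,
        # any other excess is undefined
        if w10 == mean:
            return PingPongStat(z=0.0, w10=w10, background_mean=mean, background_var=var)
        return PingPongStat(
            z=math.nan, w10=w10, background_mean=mean, background_var=var, degenerate=True
        )
    z = (w10 - mean) / math.sqrt(var / n)
    return PingPongStat(z=z, w10=w10, background_mean=mean, background_var=var)


@dataclass
class PairFraction:
    """Copy-weighted fraction of reads with a partner at exactly d = 10."""

    fraction: float
    fraction_a: float
    fraction_b: float
    empty_input: bool = False


def _paired_weight(
    reads: Sequence[AlignedPiRNA],
    partner_index_minus: dict[str, dict[int, tuple[float, int]]],
    partner_index_plus: dict[str, dict[int, tuple[float, int]]],
    distance: int,
) -> tuple[float, float]:
    """(copy weight of reads with a d=10 partner in the partner set, total)."""
    paired = 0.0
    total = 0.0
    for r in reads:
        total += r.copies
        if r.strand == "+":
            hit = partner_index_minus.get(r.chrom, {}).get(r.five_prime + distance - 1)
        else:
            hit = partner_index_plus.get(r.chrom, {}).get(r.five_prime - distance + 1)
        if hit is not None:
            paired += r.copies
    return paired, total


def pingpong_pair_fraction(
    reads_a: Sequence[AlignedPiRNA],
    reads_b: Sequence[AlignedPiRNA] | None = None,
    distance: int = PING_PONG_DISTANCE,
) -> PairFraction:
    """Fraction of reads participating in a 10-nt 5' overlap pair.

    Homotypic mode reports the fraction over the single read set; heterotypic
    mode reports each set's fraction against the other set, plus the pooled
    fraction.
    """
    homotypic = reads_b is None or reads_b is reads_a
    if reads_b is None:
        reads_b = reads_a
    idx_minus_b = _index_by_five_prime(reads_b, "-")
    idx_plus_b = _index_by_five_prime(reads_b, "+")
    paired_a, total_a = _paired_weight(reads_a, idx_minus_b, idx_plus_b, distance)
    if homotypic:
        frac = paired_a / total_a if total_a else 0.0
        return PairFraction(
            fraction=frac, fraction_a=frac, fraction_b=frac, empty_input=total_a == 0
        )
    idx_minus_a = _index_by_five_prime(reads_a, "-")
    idx_plus_a = _index_by_five_prime(reads_a, "+")
    paired_b, total_b = _paired_weight(reads_b, idx_minus_a, idx_plus_a, distance)
    total = total_a + total_b
    return PairFraction(
        fraction=(paired_a + paired_b) / total if total else 0.0,
        fraction_a=paired_a / total_a if total_a else 0.0,
        fraction_b=paired_b / total_b if total_b else 0.0,
        empty_input=total == 0,
    )
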