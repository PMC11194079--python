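"""piRNA representatives, target-site scanning and cleavage validation.

A piRNA identity is the 25 genomic nucleotides downstream of the mapped 5'
end (read in the read's orientation); identical 25-mers are collapsed and
their abundances summed per sample.

Target scanning slides the 25-mer antisense along the transcript (mRNA
sense strand, 5'->3', ungapped).  With the piRNA's nt 1 opposite transcript
position ``j`` (0-based), piRNA nt ``i`` pairs with transcript position
``j - (i - 1)``.  A register is a candidate site when:

* piRNA positions 2-6 are perfectly Watson-Crick complementary,
* positions 7-25 contain at least ``min_matches`` (default 14) complementary
  pairs,
* position 1 is unconstrained (mismatch allowed).

G:U wobble counts as a mismatch; non-ACGT characters never pair.  The
predicted cleavage position is the transcript base paired with piRNA nt 10
(``j - 9``): the 5' end of the downstream decay fragment, i.e. cleavage of
the bond between the bases opposite piRNA nt 10 and nt 11.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignedPiRNA, GenomicInterval, reverse_complement

REPRESENTATIVE_LENGTH = 25
DEFAULT_MIN_MATCHES = 14
CUT_GUIDE_POSITION = 10  # cleavage across the nt 10-11 junction of the guide


@dataclass
class PiRNARepresentative:
    """A 25-nt genome-derived piRNA identity with per-sample abundance."""

    sequence: str
    origin: tuple[str, str, int]  # (chrom, strand, 5' position)
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) != REPRESENTATIVE_LENGTH:
            raise ValueError(
                f"representative must be {REPRESENTATIVE_LENGTH} nt, "
                f"got {len(self.sequence)}"
            )
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("abundance must be non-negative")

    @property
    def total_abundance(self) -> float:
        return sum(self.abundance.values())


@dataclass
class TargetSite:
    """One predicted piRNA cleavage site on a transcript."""

    pirna: str  # representative sequence (identity)
    transcript: str
    pairing_start: int  # transcript position opposite piRNA nt 1
    cut: int  # 5' base of the downstream cleavage fragment
    matches_7_25: int
    mismatch_positions: frozenset[int]
    region: str = "unassigned"  # 5UTR / CDS / 3UTR / noncoding
    meta_position: float = float("nan")
    repeat_class: str = "none"  # sense / antisense / none
    degradome_support: dict[str, bool] = field(default_factory=dict)
    supported: bool = False


class CollapseResult(dict):
    """sequence -> PiRNARepresentative; carries the skipped-record count."""

    n_skipped: int = 0


def collapse_representatives(
    reads: Iterable[AlignedPiRNA],
    genome: Mapping[str, str],
) -> CollapseResult:
    """Collapse reads to 25-nt representatives, summing copies per sample.

    The representative is the 25 genomic nt starting at the read's 5' end in
    the read's orientation.  Reads whose 5' end lies within 25 nt of the
    contig edge on their 3' side are skipped (counted in ``n_skipped``).
    Identical sequences merge; the recorded origin is the lexicographically
    smallest (chrom, strand, 5') among the merged reads, for determinism.
    """
    out = CollapseResult()
    skipped = 0
    for r in reads:
        chrom_seq = genome[r.chrom]
        p = r.five_prime
        if r.strand == "+":
            if p + REPRESENTATIVE_LENGTH > len(chrom_seq):
                skipped += 1
                continue
            seq = chrom_seq[p : p + REPRESENTATIVE_LENGTH].upper()
        else:
            if p - REPRESENTATIVE_LENGTH + 1 < 0:
                skipped += 1
                continue
            seq = reverse_complement(
                chrom_seq[p - REPRESENTATIVE_LENGTH + 1 : p + 1]
            ).upper()
        rep = out.get(seq)
        origin = (r.chrom, r.strand, p)
        if rep is None:
            out[seq] = PiRNARepresentative(sequence=seq, origin=origin, abundance={})
            rep = out[seq]
        elif origin < rep.origin:
            rep.origin = origin
        rep.abundance[r.sample] = rep.abundance.get(r.sample, 0.0) + r.copies
    out.n_skipped = skipped
    return out


# ---------------------------------------------------------------------------
# Target scanning
# ---------------------------------------------------------------------------

# byte-level pairing: transcript base (sense) that pairs each guide base.
# Unknown guide characters map to 0x00, which matches no transcript byte.
_PAIR = np.zeros(256, dtype=np.uint8)
for _g, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A"), ("U", "A")):
    _PAIR[ord(_g)] = ord(_t)

# window index k (0..24, transcript 5'->3') of guide position i: k = 25 - i
_K_OF_POS = {i: REPRESENTATIVE_LENGTH - i for i in range(1, REPRESENTATIVE_LENGTH + 1)}
_SEED_SLICE = slice(_K_OF_POS[6], _K_OF_POS[2] + 1)  # positions 2..6
_TAIL_SLICE = slice(_K_OF_POS[25], _K_OF_POS[7] + 1)  # positions 7..25


def _required_window(pirna: str) -> np.ndarray:
    """Transcript window bytes that would pair the guide perfectly.

    Index ``k`` of the window (transcript 5'->3') opposes guide position
    ``25 - k``.
    """
    guide = np.frombuffer(pirna.upper().encode(), dtype=np.uint8)
    return _PAIR[guide][::-1]


def scan_targets(
    pirna: PiRNARepresentative | str,
    transcript: str,
    transcript_id: str = "",
    min_matches: int = DEFAULT_MIN_MATCHES,
    allow_pos1_mismatch: bool = True,
    require_2_6_exact: bool = True,
) -> list[TargetSite]:
    """All antisense registers of the 25-mer guide that satisfy the rules.

    Transcripts shorter than 25 nt yield no candidates.  Every passing
    register is reported unmerged, one :class:`TargetSite` each.
    """
    seq = pirna.sequence if isinstance(pirna, PiRNARepresentative) else pirna
    t = transcript.upper().replace("U", "T")
    L = len(t)
    if L < REPRESENTATIVE_LENGTH:
        return []
    t_arr = np.frombuffer(t.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t_arr, REPRESENTATIVE_LENGTH)
    eq = windows == _required_window(seq)[None, :]

    ok = np.ones(eq.shape[0], dtype=bool)
    if require_2_6_exact:
        ok &= eq[:, _SEED_SLICE].all(axis=1)
    tail_matches = eq[:, _TAIL_SLICE].sum(axis=1)
    ok &= tail_matches >= min_matches
    if not allow_pos1_mismatch:
        ok &= eq[:, _K_OF_POS[1]]

    sites: list[TargetSite] = []
    for s in np.flatnonzero(ok):
        j = int(s) + REPRESENTATIVE_LENGTH - 1  # transcript pos opposite nt 1
        mismatches = frozenset(
            REPRESENTATIVE_LENGTH - k for k in np.flatnonzero(~eq[s])
        )
        sites.append(
            TargetSite(
                pirna=seq,
                transcript=transcript_id,
                pairing_start=j,
                cut=j - (CUT_GUIDE_POSITION - 1),
                matches_7_25=int(tail_matches[s]),
                mismatch_positions=mismatches,
            )
        )
    return sites


def scan_all_targets(
    representatives: Mapping[str, PiRNARepresentative] | Iterable[str],
    transcripts: Mapping[str, str],
    min_matches: int = DEFAULT_MIN_MATCHES,
    allow_pos1_mismatch: bool = True,
) -> list[TargetSite]:
    """Scan every representative against every transcript.

    Equivalent to calling :func:`scan_targets` for each (guide, transcript)
    pair, but candidate registers are prefiltered through a 5-mer index on
    the exact-match region (guide positions 2-6), which makes scanning large
    guide collections practical.
    """
    if isinstance(representatives, Mapping):
        guides: list[str] = list(representatives.keys())
    else:
        guides = list(representatives)

    # index guides by the transcript 5-mer their positions 2..6 must equal
    reqs = [_required_window(g).tobytes().decode("latin1") for g in guides]
    by_seed: dict[str, list[int]] = defaultdict(list)
    for gi, req in enumerate(reqs):
        by_seed[req[_SEED_SLICE]].append(gi)

    k1 = _K_OF_POS[1]
    sites: list[TargetSite] = []
    for tid, tseq in transcripts.items():
        t = tseq.upper().replace("U", "T")
        L = len(t)
        for s in range(L - REPRESENTATIVE_LENGTH + 1):
            candidates = by_seed.get(t[s + _SEED_SLICE.start : s + _SEED_SLICE.stop])
            if not candidates:
                continue
            window = t[s : s + REPRESENTATIVE_LENGTH]
            for gi in candidates:
                req = reqs[gi]
                tail = sum(
                    window[k] == req[k]
                    for k in range(_TAIL_SLICE.start, _TAIL_SLICE.stop)
                )
                if tail < min_matches:
                    continue
                if not allow_pos1_mismatch and window[k1] != req[k1]:
                    continue
                j = s + REPRESENTATIVE_LENGTH - 1
                mismatches = frozenset(
                    REPRESENTATIVE_LENGTH - k
                    for k in range(REPRESENTATIVE_LENGTH)
                    if window[k] != req[k]
                )
                sites.append(
                    TargetSite(
                        pirna=guides[gi],
                        transcript=tid,
                        pairing_start=j,
                        cut=j - (CUT_GUIDE_POSITION - 1),
                        matches_7_25=int(tail),
                        mismatch_positions=mismatches,
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# Degradome support
# ---------------------------------------------------------------------------

def degradome_support(
    sites: Sequence[TargetSite],
    degradome: Mapping[str, Sequence[tuple[str, int]]],
    tolerance: int = 0,
    require_all_replicates: bool = True,
) -> list[TargetSite]:
    """Flag each site with per-replicate degradome support and a verdict.

    ``degradome`` maps replicate id -> records of (transcript id, 5'-end
    transcript coordinate).  A replicate supports a site when some record on
    the site's transcript lies within ``tolerance`` nt of the cut (default
    exact).  The verdict requires support in all replicates; with fewer than
    two replicates the verdict is never "supported".
    """
    indexed: dict[str, dict[str, set[int]]] = {}
    for rep_id, records in degradome.items():
        idx: dict[str, set[int]] = defaultdict(set)
        for tid, pos in records:
            idx[tid].add(pos)
        indexed[rep_id] = idx

    enough_replicates = len(degradome) >= 2
    for site in sites:
        flags = {}
        for rep_id, idx in indexed.items():
            positions = idx.get(site.transcript, ())
            flags[rep_id] = any(
                abs(p - site.cut) <= tolerance for p in positions
            )
        site.degradome_support = flags
        if require_all_replicates:
            site.supported = (
                enough_replicates and bool(flags) and all(flags.values())
            )
        else:
            site.supported = any(flags.values())
    return list(sites)


# ---------------------------------------------------------------------------
# Metatranscript distribution
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Region structure of one transcript in transcript coordinates."""

    transcript: str
    length: int
    cds_start: int | None = None  # None -> noncoding
    cds_end: int | None = None

    def region_of(self, pos: int) -> tuple[str, float]:
        """(region, meta position within region) of a transcript coordinate."""
        if not 0 <= pos < self.length:
            raise ValueError(
                f"position {pos} outside transcript {self.transcript} "
                f"(length {self.length})"
            )
        if self.cds_start is None or self.cds_end is None:
            return "noncoding", pos / self.length if self.length else 0.0
        if pos < self.cds_start:
            start, end, name = 0, self.cds_start, "5UTR"
        elif pos < self.cds_end:
            start, end, name = self.cds_start, self.cds_end, "CDS"
        else:
            start, end, name = self.cds_end, self.length, "3UTR"
        return name, (pos - start) / (end - start)


def metatranscript_distribution(
    sites: Sequence[TargetSite],
    models: Mapping[str, TranscriptModel],
) -> dict[str, int]:
    """Assign each site's cut to a region; return region counts.

    Sites are annotated in place (``region``, ``meta_position``).  Counts
    over 5UTR/CDS/3UTR/noncoding sum to the number of sites whose transcript
    has a model.
    """
    counts = {"5UTR": 0, "CDS": 0, "3UTR": 0, "noncoding": 0}
    for site in sites:
        model = models.get(site.transcript)
        if model is None:
            continue
        region, meta = model.region_of(site.cut)
        site.region = region
        site.meta_position = meta
        counts[region] += 1
    return counts


# ---------------------------------------------------------------------------
# Repeat overlap
# ---------------------------------------------------------------------------

def classify_repeat_overlap(
    feature: GenomicInterval,
    repeats: Sequence[GenomicInterval],
) -> str:
    """sense / antisense / none by strand agreement with the best repeat.

    Ties between overlapping repeats are broken by the largest overlap.
    """
    best_len = 0
    best_class = "none"
    for rep in repeats:
        ov = rep.overlap(feature)
        if ov > best_len:
            best_len = ov
            best_class = "sense" if rep.strand == feature.strand else "antisense"
    return best_class


def pirna_footprint(origin: tuple[str, str, int]) -> GenomicInterval:
    """Genomic interval of the 25-nt representative starting at ``origin``."""
    chrom, strand, p = origin
    if strand == "+":
        return GenomicInterval(chrom=chrom, start=p, end=p + REPRESENTATIVE_LENGTH, strand=strand)
    return GenomicInterval(
        chrom=chrom, start=p - REPRESENTATIVE_LENGTH + 1, end=p + 1, strand=strand
    )


def repeat_overlap(
    sites: Sequence[TargetSite],
    origins: Mapping[str, tuple[str, str, int]],
    repeats: Sequence[GenomicInterval],
) -> dict[str, str]:
    """Repeat class of each targeting piRNA by its genomic origin.

    Sites are annotated in place with their piRNA's class; the returned map
    is per unique piRNA sequence.
    """
    classes: dict[str, str] = {}
    for seq, origin in origins.items():
        classes[seq] = classify_repeat_overlap(pirna_footprint(origin), repeats)
    for site in sites:
        site.repeat_class = classes.get(site.pirna, "none")
    return classes
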