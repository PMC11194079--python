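from collections import defaultdict

import numpy as np
import pytest

from pirnakit.io_formats import GenomicInterval, reverse_complement
from pirnakit.targeting import (
    TranscriptModel,
    classify_repeat_overlap,
    collapse_representatives,
    degradome_support,
    metatranscript_distribution,
    pirna_footprint,
    repeat_overlap,
    scan_all_targets,
    scan_targets,
)
from tests.conftest import make_read, random_genome, random_reads

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def scan_oracle(guide, transcript, min_matches=14, allow_pos1_mismatch=True):
    """Exhaustive per-register check of all pairing rules, string-based."""
    t = transcript.upper().replace("U", "T")
    g = guide.upper()
    hits = []
    for s in range(len(t) - 24):
        window = t[s : s + 25]
        # guide position i pairs window[25 - i]
        matches = [COMP.get(g[i - 1]) == window[25 - i] for i in range(1, 26)]
        if not all(matches[1:6]):  # positions 2..6 exact
            continue
        n_tail = sum(matches[6:25])
        if n_tail < min_matches:
            continue
        if not allow_pos1_mismatch and not matches[0]:
            continue
        j = s + 24
        hits.append((j, j - 9, n_tail))
    return hits


class TestCollapse:
    def test_merges_same_five_prime(self, rng):
        genome = {"chr1": random_genome(rng, 500)}
        r1 = make_read(start=100, length=28, strand="+", copies=2)
        r2 = make_read(start=100, length=31, strand="+", copies=3)
        reps = collapse_representatives([r1, r2], genome)
        assert len(reps) == 1
        (rep,) = reps.values()
        assert rep.sequence == genome["chr1"][100:125]
        assert rep.abundance == {"s": 5}
        assert rep.origin == ("chr1", "+", 100)

    def test_opposite_strands_distinct(self, rng):
        genome = {"chr1": random_genome(rng, 500)}
        plus = make_read(start=100, length=30, strand="+")
        minus = make_read(start=71, length=30, strand="-")  # 5' = 100
        reps = collapse_representatives([plus, minus], genome)
        assert len(reps) == 2
        seqs = set(reps)
        assert genome["chr1"][100:125] in seqs
        assert reverse_complement(genome["chr1"][76:101]) in seqs

    def test_contig_edge_skipped(self, rng):
        genome = {"chr1": random_genome(rng, 120)}
        ok = make_read(start=50, length=30, strand="+")
        edge = make_read(start=110, length=9, strand="+")  # 5' too close to end
        reps = collapse_representatives([ok, edge], genome)
        assert len(reps) == 1
        assert reps.n_skipped == 1

    def test_minus_edge_skipped(self, rng):
        genome = {"chr1": random_genome(rng, 120)}
        edge = make_read(start=0, length=10, strand="-")  # 5' = 9 < 24
        reps = collapse_representatives([edge], genome)
        assert reps.n_skipped == 1

    def test_matches_brute_force_tally(self, rng):
        genome = {
            "chr1": random_genome(rng, 3000),
            "chr2": random_genome(rng, 3000),
        }
        reads = random_reads(rng, 1000, chrom_len=2900)
        reps = collapse_representatives(reads, genome)
        expected = defaultdict(float)
        for r in reads:
            p = r.five_prime
            if r.strand == "+":
                if p + 25 > len(genome[r.chrom]):
                    continue
                seq = genome[r.chrom][p : p + 25]
            else:
                if p - 24 < 0:
                    continue
                seq = reverse_complement(genome[r.chrom][p - 24 : p + 1])
            expected[seq] += r.copies
        assert {s: r.total_abundance for s, r in reps.items()} == dict(expected)


class TestScanTargets:
    def _setup(self, rng, transcript_len=300):
        transcript = random_genome(rng, transcript_len)
        j = 150  # transcript position opposite guide nt 1
        window = transcript[j - 24 : j + 1]
        guide = reverse_complement(window)
        return transcript, guide, j

    def test_perfect_complement(self, rng):
        transcript, guide, j = self._setup(rng)
        sites = scan_targets(guide, transcript, transcript_id="t")
        exact = [s for s in sites if s.pairing_start == j]
        assert len(exact) == 1
        s = exact[0]
        assert s.matches_7_25 == 19
        assert s.mismatch_positions == frozenset()
        assert s.cut == j - 9

    def test_position1_mismatch_allowed(self, rng):
        transcript, guide, j = self._setup(rng)
        # mutate the transcript base opposite guide nt 1 (position j)
        mutated = list(transcript)
        mutated[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[transcript[j]]
        sites = scan_targets(guide, "".join(mutated), transcript_id="t")
        exact = [s for s in sites if s.pairing_start == j]
        assert len(exact) == 1
        assert exact[0].mismatch_positions == frozenset({1})
        assert exact[0].matches_7_25 == 19

    def test_six_tail_mismatches_reject(self, rng):
        transcript, guide, j = self._setup(rng)
        mutated = list(transcript)
        for pos in (7, 10, 14, 18, 21, 25):  # guide positions, all in 7..25
            t_pos = j - (pos - 1)
            mutated[t_pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[transcript[t_pos]]
        sites = scan_targets(guide, "".join(mutated), transcript_id="t")
        assert not any(s.pairing_start == j for s in sites)
        # the oracle agrees the register fails (13 matches < 14)
        assert (j, j - 9, 13) not in scan_oracle(guide, "".join(mutated))

    def test_seed_mismatch_rejects(self, rng):
        transcript, guide, j = self._setup(rng)
        mutated = list(transcript)
        t_pos = j - 3  # opposite guide position 4 (within 2..6)
        mutated[t_pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[transcript[t_pos]]
        sites = scan_targets(guide, "".join(mutated), transcript_id="t")
        assert not any(s.pairing_start == j for s in sites)

    def test_gu_wobble_is_mismatch(self):
        # guide all-U pairs an all-A window; an all-G window would be G:U
        guide = "T" * 25
        assert scan_targets(guide, "A" * 60, transcript_id="t")
        assert scan_targets(guide, "G" * 60, transcript_id="t") == []

    def test_short_transcript_no_candidates(self):
        assert scan_targets("A" * 25, "ACGT" * 6) == []

    def test_non_acgt_counts_as_mismatch(self, rng):
        transcript, guide, j = self._setup(rng)
        mutated = list(transcript)
        t_pos = j - 3  # seed region
        mutated[t_pos] = "N"
        sites = scan_targets(guide, "".join(mutated), transcript_id="t")
        assert not any(s.pairing_start == j for s in sites)

    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(300):
            transcript = random_genome(rng, 200)
            if rng.random() < 0.5:
                guide = random_genome(rng, 25)
            else:  # planted complements so positives exist too
                j = int(rng.integers(24, 200))
                guide = reverse_complement(transcript[j - 24 : j + 1])
            got = [
                (s.pairing_start, s.cut, s.matches_7_25)
                for s in scan_targets(guide, transcript)
            ]
            assert got == scan_oracle(guide, transcript)

    def test_relaxing_min_matches_is_monotone(self, rng):
        for _ in range(50):
            transcript = random_genome(rng, 300)
            j = int(rng.integers(24, 300))
            guide = list(reverse_complement(transcript[j - 24 : j + 1]))
            # degrade some tail pairings so the threshold actually bites
            for pos in rng.choice(range(7, 26), size=5, replace=False):
                guide[pos - 1] = "N"
            guide = "".join(guide)
            n14 = len(scan_targets(guide, transcript, min_matches=14))
            n13 = len(scan_targets(guide, transcript, min_matches=13))
            assert n13 >= n14

    @pytest.mark.parametrize("allow_pos1", [True, False])
    @pytest.mark.parametrize("min_matches", [13, 14])
    def test_scan_all_matches_per_pair_scan(self, rng, allow_pos1, min_matches):
        """The indexed bulk scanner agrees with the per-pair scanner."""
        transcripts = {f"t{i}": random_genome(rng, 300) for i in range(5)}
        guides = []
        for _ in range(30):
            tid = f"t{int(rng.integers(0, 5))}"
            j = int(rng.integers(24, 300))
            g = list(reverse_complement(transcripts[tid][j - 24 : j + 1]))
            for pos in rng.choice(range(1, 26), size=int(rng.integers(0, 6)), replace=False):
                g[pos - 1] = "ACGT"[int(rng.integers(0, 4))]
            guides.append("".join(g))
        guides += [random_genome(rng, 25) for _ in range(20)]
        bulk = scan_all_targets(
            guides, transcripts, min_matches=min_matches, allow_pos1_mismatch=allow_pos1
        )
        expected = set()
        for tid, tseq in transcripts.items():
            for g in guides:
                for s in scan_targets(
                    g, tseq, transcript_id=tid,
                    min_matches=min_matches, allow_pos1_mismatch=allow_pos1,
                ):
                    expected.add(
                        (s.pirna, s.transcript, s.pairing_start, s.cut,
                         s.matches_7_25, s.mismatch_positions)
                    )
        got = {
            (s.pirna, s.transcript, s.pairing_start, s.cut,
             s.matches_7_25, s.mismatch_positions)
            for s in bulk
        }
        assert got == expected

    def test_mismatches_confined_to_allowed_positions(self, rng):
        for _ in range(100):
            transcript = random_genome(rng, 400)
            j = int(rng.integers(24, 400))
            guide = reverse_complement(transcript[j - 24 : j + 1])
            for s in scan_targets(guide, transcript):
                assert s.mismatch_positions <= ({1} | set(range(7, 26)))
                assert s.matches_7_25 >= 14


class TestDegradomeSupport:
    def _site(self, cut=50):
        (s,) = scan_targets("T" * 25, "A" * 100, transcript_id="t1")[:1] or [None]
        s.cut = cut
        s.transcript = "t1"
        return s

    def test_both_replicates_supported(self):
        site = self._site(cut=50)
        degradome_support([site], {"r1": [("t1", 50)], "r2": [("t1", 50)]})
        assert site.supported
        assert site.degradome_support == {"r1": True, "r2": True}

    def test_single_replicate_not_supported(self):
        site = self._site(cut=50)
        degradome_support([site], {"r1": [("t1", 50)], "r2": [("t1", 99)]})
        assert not site.supported

    def test_tolerance_semantics(self):
        site = self._site(cut=50)
        records = {"r1": [("t1", 51)], "r2": [("t1", 51)]}
        degradome_support([site], records, tolerance=0)
        assert not site.supported
        degradome_support([site], records, tolerance=1)
        assert site.supported

    def test_fewer_than_two_replicates_never_supported(self):
        site = self._site(cut=50)
        degradome_support([site], {"r1": [("t1", 50)]})
        assert not site.supported

    def test_any_replicate_mode(self):
        site = self._site(cut=50)
        degradome_support(
            [site],
            {"r1": [("t1", 50)], "r2": []},
            require_all_replicates=False,
        )
        assert site.supported


class TestMetatranscript:
    @pytest.fixture
    def model(self):
        # 50 nt 5'UTR, 200 nt CDS, 100 nt 3'UTR
        return TranscriptModel(transcript="t1", length=350, cds_start=50, cds_end=250)

    def _site_at(self, cut):
        s = scan_targets("T" * 25, "A" * 400, transcript_id="t1")[0]
        s.cut = cut
        return s

    def test_first_base_of_3utr(self, model):
        s = self._site_at(250)
        counts = metatranscript_distribution([s], {"t1": model})
        assert s.region == "3UTR"
        assert s.meta_position == 0.0
        assert counts["3UTR"] == 1

    def test_cds_midpoint(self, model):
        s = self._site_at(150)
        metatranscript_distribution([s], {"t1": model})
        assert s.region == "CDS"
        assert s.meta_position == pytest.approx(0.5)

    def test_noncoding_transcript(self):
        model = TranscriptModel(transcript="t1", length=350)
        s = self._site_at(100)
        counts = metatranscript_distribution([s], {"t1": model})
        assert s.region == "noncoding"
        assert counts["noncoding"] == 1

    def test_counts_conserve_sites(self, rng, model):
        sites = [self._site_at(int(rng.integers(0, 350))) for _ in range(50)]
        counts = metatranscript_distribution(sites, {"t1": model})
        assert sum(counts.values()) == 50

    def test_out_of_bounds_cut_raises(self, model):
        with pytest.raises(ValueError):
            model.region_of(350)


class TestRepeatOverlap:
    def test_sense(self):
        rep = GenomicInterval(chrom="c", start=100, end=300, strand="+")
        feat = GenomicInterval(chrom="c", start=150, end=175, strand="+")
        assert classify_repeat_overlap(feat, [rep]) == "sense"

    def test_antisense(self):
        rep = GenomicInterval(chrom="c", start=100, end=300, strand="+")
        feat = GenomicInterval(chrom="c", start=150, end=175, strand="-")
        assert classify_repeat_overlap(feat, [rep]) == "antisense"

    def test_none(self):
        rep = GenomicInterval(chrom="c", start=100, end=300, strand="+")
        feat = GenomicInterval(chrom="c", start=500, end=525, strand="+")
        assert classify_repeat_overlap(feat, [rep]) == "none"

    def test_tie_broken_by_largest_overlap(self):
        plus = GenomicInterval(chrom="c", start=100, end=160, strand="+")
        minus = GenomicInterval(chrom="c", start=140, end=300, strand="-")
        feat = GenomicInterval(chrom="c", start=145, end=170, strand="+")
        # overlap with plus = 15, with minus = 25 -> antisense wins
        assert classify_repeat_overlap(feat, [plus, minus]) == "antisense"

    def test_footprint_orientation(self):
        assert pirna_footprint(("c", "+", 100)).start == 100
        assert pirna_footprint(("c", "+", 100)).end == 125
        assert pirna_footprint(("c", "-", 100)).start == 76
        assert pirna_footprint(("c", "-", 100)).end == 101

    def test_sites_annotated_via_origin(self):
        sites = scan_targets("T" * 25, "A" * 60, transcript_id="t1")
        repeats = [GenomicInterval(chrom="c", start=0, end=200, strand="-")]
        classes = repeat_overlap(sites, {"T" * 25: ("c", "+", 50)}, repeats)
        assert classes["T" * 25] == "antisense"
        assert all(s.repeat_class == "antisense" for s in sites)
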