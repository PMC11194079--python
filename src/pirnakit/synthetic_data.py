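"""Seeded synthetic data with a machine-readable ground-truth ledger.

Generates, deterministically from a single seed:

* a toy genome with piRNA clusters, genes (5'UTR/CDS/3'UTR) and repeats,
  some repeats embedded inside 3'UTRs;
* per-(protein, genotype, replicate) piRNA libraries with a controllable
  fraction of opposite-strand read pairs at exactly 10-nt 5' overlap, a 1U
  bias and protein-specific length models;
* planted cleavage targets: piRNAs whose 25-nt representative is the exact
  antisense complement of a transcript window (3'UTR-embedded, usually
  inside a repeat), so every planted site passes the target scan by
  construction;
* degradome 5'-end records marking each planted cut in every replicate,
  plus an optional uniform background;
* negative-binomial gene and piRNA count matrices with planted up/down
  regulation across two genotypes.

Every planted signal is recorded in :class:`GroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignedPiRNA,
    GenomicInterval,
    reverse_complement,
    write_alignments,
    write_bed,
    write_counts,
    write_fasta,
    write_tsv,
)
from .targeting import REPRESENTATIVE_LENGTH, TranscriptModel

CHROM = "chrS"
PROTEINS = ("MIWI", "MILI")
GENOTYPES = ("het", "mut")

# stage constants mixed into the seed so each operation has its own stream
_STREAM_GENOME = 1
_STREAM_LIBRARIES = 2
_STREAM_DEGRADOME = 3
_STREAM_COUNTS = 4

DEFAULT_LENGTH_MODELS: dict[str, dict[int, float]] = {
    # MIWI-like peak at 30 nt, MILI-like at 26-27 nt
    "MIWI": {29: 0.25, 30: 0.50, 31: 0.25},
    "MILI": {26: 0.5, 27: 0.5},
}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    genome_length: int = 200_000
    n_clusters: int = 4
    cluster_length: int = 8_000
    pingpong_fraction: float = 0.5
    n_reads: int = 2_000
    length_model: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LENGTH_MODELS.items()}
    )
    abundance_model: tuple[float, float] = (1.0, 1.2)  # log-normal mu, sigma
    u_bias: float = 0.85
    n_transcripts: int = 30
    utr5_length: int = 100
    cds_length: int = 600
    utr3_length: int = 400
    repeat_length: int = 80
    n_planted_targets: int = 5
    target_effect: float = 4.0
    pirna_effect: float = 4.0
    planted_pirna_copies: int = 20
    count_mean: float = 200.0
    degradome_depth: int = 5
    degradome_background_rate: float = 0.0
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    n_degradome_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pingpong_fraction <= 1.0:
            raise SimulationError("pingpong_fraction must be in [0, 1]")
        if not 0.0 <= self.u_bias <= 1.0:
            raise SimulationError("u_bias must be in [0, 1]")
        for protein, dist in self.length_model.items():
            if not dist:
                raise SimulationError(f"empty length model for {protein}")
            if any(not 24 <= L <= 40 for L in dist):
                raise SimulationError("length model values must lie in 24..40")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SimulationError(f"length model for {protein} must sum to 1")
        for name in (
            "genome_length", "cluster_length", "n_reads", "count_mean",
            "degradome_depth", "repeat_length",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.degradome_background_rate < 0 or self.nb_dispersion < 0:
            raise SimulationError("rates must be >= 0")
        if self.n_replicates < 2:
            raise SimulationError("need at least 2 replicates per genotype")
        if self.target_effect <= 0 or self.pirna_effect <= 0:
            raise SimulationError("effects must be positive multipliers")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class GroundTruth:
    """Ledger of every planted signal."""

    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_sites: list[tuple[str, str, int]] = field(default_factory=list)
    regulated_genes: list[str] = field(default_factory=list)
    down_pirnas: list[str] = field(default_factory=list)


@dataclass
class GeneModel:
    """A gene with transcript-structure sub-intervals, in genome coordinates."""

    name: str
    interval: GenomicInterval
    utr5_length: int
    cds_length: int
    utr3_length: int

    @property
    def transcript_length(self) -> int:
        return self.utr5_length + self.cds_length + self.utr3_length

    def transcript_model(self) -> TranscriptModel:
        return TranscriptModel(
            transcript=self.name,
            length=self.transcript_length,
            cds_start=self.utr5_length,
            cds_end=self.utr5_length + self.cds_length,
        )

    def genome_position(self, t_pos: int) -> int:
        """Genome coordinate of transcript position ``t_pos``."""
        if self.interval.strand == "-":
            return self.interval.end - 1 - t_pos
        return self.interval.start + t_pos

    def transcript_sequence(self, genome: Mapping[str, bytearray | str]) -> str:
        seq = genome[self.interval.chrom][self.interval.start : self.interval.end]
        if isinstance(seq, (bytes, bytearray)):
            seq = seq.decode()
        if self.interval.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class SyntheticGenome:
    sequences: dict[str, bytearray]  # mutable so targets can be planted
    clusters: list[GenomicInterval]
    genes: list[GeneModel]
    repeats: list[GenomicInterval]

    def fasta(self) -> dict[str, str]:
        return {name: seq.decode() for name, seq in self.sequences.items()}

    def transcripts(self) -> dict[str, str]:
        return {g.name: g.transcript_sequence(self.sequences) for g in self.genes}

    def transcript_models(self) -> dict[str, TranscriptModel]:
        return {g.name: g.transcript_model() for g in self.genes}


LibraryKey = tuple[str, str, int]  # (protein, genotype, replicate)


@dataclass
class PlantedTarget:
    """Full provenance of one planted piRNA -> transcript cleavage site."""

    pirna_id: str
    sequence: str  # 25-nt representative (guide, 5'->3')
    origin: tuple[str, str, int]
    gene: str
    pairing_start: int  # transcript pos opposite guide nt 1
    cut: int


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: SyntheticGenome
    libraries: dict[LibraryKey, list[AlignedPiRNA]]
    truth: GroundTruth
    planted_targets: list[PlantedTarget]
    degradome: dict[str, dict[str, list[tuple[str, int]]]]  # genotype -> rep -> records
    gene_counts: pd.DataFrame
    pirna_counts: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write all outputs as plain-text files (FASTA/BED6/TSV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.fasta(), outdir / "genome.fa")
        write_fasta(self.genome.transcripts(), outdir / "transcripts.fa")
        write_bed(self.genome.clusters, outdir / "clusters.bed")
        write_bed([g.interval for g in self.genome.genes], outdir / "genes.bed")
        write_bed(self.genome.repeats, outdir / "repeats.bed")
        write_tsv(
            [
                {
                    "transcript": g.name,
                    "length": g.transcript_length,
                    "cds_start": g.utr5_length,
                    "cds_end": g.utr5_length + g.cds_length,
                }
                for g in self.genome.genes
            ],
            outdir / "transcript_models.tsv",
        )
        for (protein, genotype, rep), reads in sorted(self.libraries.items()):
            write_alignments(reads, outdir / f"reads_{protein}_{genotype}_{rep}.bed")
        for genotype, reps in sorted(self.degradome.items()):
            for rep_id, records in sorted(reps.items()):
                write_bed(
                    [
                        GenomicInterval(
                            chrom=tid, start=pos, end=pos + 1, name=".", score=1, strand="+"
                        )
                        for tid, pos in records
                    ],
                    outdir / f"degradome_{genotype}_{rep_id}.bed",
                )
        write_counts(self.gene_counts, outdir / "gene_counts.tsv")
        write_counts(self.pirna_counts, outdir / "pirna_counts.tsv")
        write_tsv(
            [
                {
                    "pirna_id": t.pirna_id,
                    "sequence": t.sequence,
                    "origin_chrom": t.origin[0],
                    "origin_strand": t.origin[1],
                    "origin_5p": t.origin[2],
                    "gene": t.gene,
                    "pairing_start": t.pairing_start,
                    "cut": t.cut,
                }
                for t in self.planted_targets
            ],
            outdir / "truth_planted_targets.tsv",
        )
        write_tsv(
            [{"plus_read": a, "minus_read": b} for a, b in self.truth.planted_pairs],
            outdir / "truth_planted_pairs.tsv",
        )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n).tobytes())


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Random genome with non-overlapping clusters, genes and repeats."""
    config.validate()
    rng = config.rng(_STREAM_GENOME)
    seq = _random_dna(rng, config.genome_length)

    gene_length = config.utr5_length + config.cds_length + config.utr3_length
    features = config.n_clusters + config.n_transcripts
    total_needed = (
        config.n_clusters * config.cluster_length + config.n_transcripts * gene_length
    )
    slack = config.genome_length - total_needed
    if slack < features + 1:
        raise SimulationError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_clusters} clusters and {config.n_transcripts} genes"
        )
    # random gaps between consecutive features (at least 1 nt each)
    gaps = rng.multinomial(slack - (features + 1), np.full(features + 1, 1.0 / (features + 1)))
    gaps = gaps + 1

    kinds = ["cluster"] * config.n_clusters + ["gene"] * config.n_transcripts
    rng.shuffle(kinds)

    clusters: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    repeats: list[GenomicInterval] = []
    pos = int(gaps[0])
    ci = gi = 0
    for k, kind in enumerate(kinds):
        if kind == "cluster":
            iv = GenomicInterval(
                chrom=CHROM,
                start=pos,
                end=pos + config.cluster_length,
                name=f"cluster{ci}",
                strand="+" if rng.random() < 0.5 else "-",
            )
            clusters.append(iv)
            pos = iv.end
            ci += 1
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(
                chrom=CHROM,
                start=pos,
                end=pos + gene_length,
                name=f"gene{gi:03d}",
                strand=strand,
            )
            gene = GeneModel(
                name=iv.name,
                interval=iv,
                utr5_length=config.utr5_length,
                cds_length=config.cds_length,
                utr3_length=config.utr3_length,
            )
            genes.append(gene)
            # embed one repeat inside the 3'UTR of every other gene
            if gi % 2 == 0 and config.repeat_length + 2 < config.utr3_length:
                t0 = gene.utr5_length + gene.cds_length + 1
                t0 += int(rng.integers(0, config.utr3_length - config.repeat_length - 1))
                g0 = gene.genome_position(t0)
                g1 = gene.genome_position(t0 + config.repeat_length - 1)
                start, end = min(g0, g1), max(g0, g1) + 1
                repeats.append(
                    GenomicInterval(
                        chrom=CHROM,
                        start=start,
                        end=end,
                        name=f"repeat_utr{gi}",
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
            pos = iv.end
            gi += 1
        pos += int(gaps[k + 1])
    if pos > config.genome_length:
        raise SimulationError("annotation intervals exceed genome bounds")

    # a few free-standing repeats overlapping clusters (piRNA-origin repeats)
    for i, cluster in enumerate(clusters):
        if len(cluster) <= config.repeat_length + 2:
            continue
        start = cluster.start + int(
            rng.integers(0, len(cluster) - config.repeat_length - 1)
        )
        repeats.append(
            GenomicInterval(
                chrom=CHROM,
                start=start,
                end=start + config.repeat_length,
                name=f"repeat_cl{i}",
                strand="+" if rng.random() < 0.5 else "-",
            )
        )

    return SyntheticGenome(
        sequences={CHROM: seq}, clusters=clusters, genes=genes, repeats=repeats
    )


# ---------------------------------------------------------------------------
# piRNA libraries with planted ping-pong and planted targets
# ---------------------------------------------------------------------------

def _sample_lengths(
    rng: np.random.Generator, model: Mapping[int, float], n: int
) -> np.ndarray:
    lengths = np.array(sorted(model), dtype=int)
    probs = np.array([model[int(L)] for L in lengths], dtype=float)
    return rng.choice(lengths, size=n, p=probs)


def _sample_copies(rng: np.random.Generator, model: tuple[float, float], n: int) -> np.ndarray:
    mu, sigma = model
    return np.ceil(rng.lognormal(mu, sigma, size=n)).astype(int)


def _u_start_positions(
    seq: bytearray, clusters: Sequence[GenomicInterval], margin: int
) -> dict[str, np.ndarray]:
    """Cluster positions where a read 5' end yields a first-position U.

    Plus-strand reads need genome base T at the 5' end; minus-strand reads
    need genome base A.  ``margin`` keeps the read body inside the cluster.
    """
    arr = np.frombuffer(bytes(seq), dtype=np.uint8)
    out = {"+": [], "-": []}
    for cl in clusters:
        lo, hi = cl.start, cl.end - margin
        if hi <= lo:
            continue
        window = arr[lo:hi]
        out["+"].append(lo + np.flatnonzero(window == ord("T")))
        lo2, hi2 = cl.start + margin, cl.end
        window2 = arr[lo2:hi2]
        out["-"].append(lo2 + np.flatnonzero(window2 == ord("A")))
    return {
        s: (np.concatenate(v) if v else np.empty(0, dtype=int)) for s, v in out.items()
    }


def _uniform_positions(
    rng: np.random.Generator, clusters: Sequence[GenomicInterval], margin: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(cluster index, offset) pairs for n uniform read placements."""
    sizes = np.array([len(c) - margin for c in clusters])
    probs = sizes / sizes.sum()
    idx = rng.choice(len(clusters), size=n, p=probs)
    offsets = rng.integers(0, sizes[idx])
    return idx, offsets


def _plant_targets(
    config: SimulationConfig, genome: SyntheticGenome, rng: np.random.Generator
) -> list[PlantedTarget]:
    """Choose target sites in 3'UTRs and write matching guides into clusters.

    The guide 25-mer is the reverse complement of the transcript target
    window, so the planted piRNA is perfectly antisense-complementary by
    construction.  The guide sequence is written into the genome at the
    chosen cluster origin so that reads mapped there collapse to it.
    """
    if config.n_planted_targets == 0:
        return []
    if config.n_planted_targets > len(genome.genes):
        raise SimulationError("more planted targets than genes")
    if not genome.clusters:
        raise SimulationError("planting targets requires at least one cluster")

    # prefer genes with a 3'UTR repeat so planted sites are repeat-embedded
    repeat_gene_idx = {
        int(r.name.removeprefix("repeat_utr"))
        for r in genome.repeats
        if r.name.startswith("repeat_utr")
    }
    ordered = sorted(
        genome.genes,
        key=lambda g: (int(g.name.removeprefix("gene")) not in repeat_gene_idx, g.name),
    )
    chosen = ordered[: config.n_planted_targets]

    seq = genome.sequences[CHROM]
    used: list[tuple[int, int]] = []
    targets: list[PlantedTarget] = []
    for k, gene in enumerate(sorted(chosen, key=lambda g: g.name)):
        model = gene.transcript_model()
        # target window [j - 24, j] anywhere in the 3'UTR
        utr_start = model.cds_end
        utr_end = model.length
        lo = utr_start + REPRESENTATIVE_LENGTH - 1
        j = int(rng.integers(lo, utr_end))
        window_t = (j - REPRESENTATIVE_LENGTH + 1, j)
        tseq = gene.transcript_sequence(genome.sequences)
        window = tseq[window_t[0] : j + 1]
        guide = reverse_complement(window)

        # pick a guide origin inside a cluster, non-overlapping previous picks
        for _attempt in range(1000):
            cl = genome.clusters[int(rng.integers(0, len(genome.clusters)))]
            if len(cl) < REPRESENTATIVE_LENGTH + 2:
                continue
            start = cl.start + int(
                rng.integers(0, len(cl) - REPRESENTATIVE_LENGTH - 1)
            )
            span = (start, start + REPRESENTATIVE_LENGTH)
            if all(span[1] <= a or span[0] >= b for a, b in used):
                break
        else:  # pragma: no cover - pathological configs only
            raise SimulationError("could not place planted guide origins")
        used.append(span)
        strand = cl.strand if cl.strand in "+-" else "+"
        if strand == "+":
            seq[span[0] : span[1]] = guide.encode()
            origin = (CHROM, "+", span[0])
        else:
            seq[span[0] : span[1]] = reverse_complement(guide).encode()
            origin = (CHROM, "-", span[1] - 1)

        targets.append(
            PlantedTarget(
                pirna_id=f"pi{k:03d}",
                sequence=guide,
                origin=origin,
                gene=gene.name,
                pairing_start=j,
                cut=j - 9,
            )
        )
    return targets


def simulate_pirna_libraries(
    config: SimulationConfig,
    genome: SyntheticGenome,
) -> tuple[dict[LibraryKey, list[AlignedPiRNA]], GroundTruth, list[PlantedTarget]]:
    """Per-(protein, genotype, replicate) read sets plus the ground truth.

    Each library holds ``n_reads`` collapsed reads placed in clusters: half
    are primaries (1U-biased 5' ends), and of the other half a fraction
    ``pingpong_fraction`` are responders placed on the opposite strand at
    exactly 10-nt 5' overlap with a sampled primary.  Planted targeting
    guides (see :func:`_plant_targets`) are added to MIWI libraries with
    genotype-scaled copy numbers.
    """
    config.validate()
    if config.pingpong_fraction > 0:
        if not genome.clusters:
            raise SimulationError("pingpong_fraction > 0 requires clusters")
        if any(len(c) < 40 for c in genome.clusters):
            raise SimulationError("clusters must be at least 40 nt for ping-pong")
    rng = config.rng(_STREAM_LIBRARIES)
    planted = _plant_targets(config, genome, rng)

    margin = max(max(L for m in config.length_model.values() for L in m), 40)
    u_pos = _u_start_positions(genome.sequences[CHROM], genome.clusters, margin)

    truth = GroundTruth(
        planted_sites=[(t.sequence, t.gene, t.cut) for t in planted],
        regulated_genes=sorted({t.gene for t in planted}),
        down_pirnas=[t.sequence for t in planted],
    )

    libraries: dict[LibraryKey, list[AlignedPiRNA]] = {}
    genome_len = len(genome.sequences[CHROM])
    for protein in PROTEINS:
        model = config.length_model.get(protein)
        if model is None:
            model = next(iter(config.length_model.values()))
        for genotype in GENOTYPES:
            for rep in range(1, config.n_replicates + 1):
                sample = f"{protein}_{genotype}_{rep}"
                reads: list[AlignedPiRNA] = []

                if protein == "MIWI":
                    scale = 1.0 / config.pirna_effect if genotype == "mut" else 1.0
                    for t in planted:
                        copies = max(1, int(round(config.planted_pirna_copies * scale)))
                        _, strand, p = t.origin
                        if strand == "+":
                            start, end = p, p + 30
                        else:
                            start, end = p - 29, p + 1
                        reads.append(
                            AlignedPiRNA(
                                interval=GenomicInterval(
                                    chrom=CHROM,
                                    start=start,
                                    end=end,
                                    name=f"{sample}_{t.pirna_id}",
                                    strand=strand,
                                ),
                                copies=copies,
                                sample=sample,
                            )
                        )

                n_rest = max(0, config.n_reads - len(reads))
                n_primary = (n_rest + 1) // 2
                n_responder = n_rest - n_primary
                if n_rest and not genome.clusters:
                    libraries[(protein, genotype, rep)] = reads
                    continue

                lengths = _sample_lengths(rng, model, n_rest)
                copies = _sample_copies(rng, config.abundance_model, n_rest)
                strands = np.where(rng.random(n_rest) < 0.5, "+", "-")
                cl_idx, offsets = _uniform_positions(
                    rng, genome.clusters, margin, n_rest
                )
                from_u = rng.random(n_primary) < config.u_bias
                is_planted_pair = (
                    rng.random(n_responder) < config.pingpong_fraction
                )

                primaries: list[AlignedPiRNA] = []
                for i in range(n_primary):
                    strand = str(strands[i])
                    cl = genome.clusters[cl_idx[i]]
                    if from_u[i] and u_pos[strand].size:
                        pool = u_pos[strand]
                        p5 = int(pool[rng.integers(0, pool.size)])
                    elif strand == "+":
                        p5 = cl.start + int(offsets[i])
                    else:
                        p5 = cl.start + margin + int(offsets[i])
                    L = int(lengths[i])
                    if strand == "+":
                        start, end = p5, p5 + L
                    else:
                        start, end = p5 - L + 1, p5 + 1
                    if start < 0 or end > genome_len:
                        raise SimulationError("read exceeds genome bounds")
                    r = AlignedPiRNA(
                        interval=GenomicInterval(
                            chrom=CHROM, start=start, end=end,
                            name=f"{sample}_p{i}", strand=strand,
                        ),
                        copies=int(copies[i]),
                        sample=sample,
                    )
                    primaries.append(r)
                reads.extend(primaries)

                for k in range(n_responder):
                    i = n_primary + k
                    L = int(lengths[i])
                    if is_planted_pair[k] and primaries:
                        partner = primaries[int(rng.integers(0, len(primaries)))]
                        if partner.strand == "+":
                            m5 = partner.five_prime + 9
                            strand = "-"
                            start, end = m5 - L + 1, m5 + 1
                        else:
                            p5 = partner.five_prime - 9
                            strand = "+"
                            start, end = p5, p5 + L
                        if start < 0 or end > genome_len:
                            # partner too close to an edge; place uniformly
                            is_planted = False
                        else:
                            is_planted = True
                    else:
                        is_planted = False
                    if not is_planted:
                        strand = str(strands[i])
                        cl = genome.clusters[cl_idx[i]]
                        p5 = cl.start + int(offsets[i]) + (margin if strand == "-" else 0)
                        if strand == "+":
                            start, end = p5, p5 + L
                        else:
                            start, end = p5 - L + 1, p5 + 1
                    name = f"{sample}_r{k}"
                    r = AlignedPiRNA(
                        interval=GenomicInterval(
                            chrom=CHROM, start=start, end=end, name=name, strand=strand
                        ),
                        copies=int(copies[i]),
                        sample=sample,
                    )
                    reads.append(r)
                    if is_planted:
                        if r.strand == "-":
                            truth.planted_pairs.append((partner.name, r.name))
                        else:
                            truth.planted_pairs.append((r.name, partner.name))
                libraries[(protein, genotype, rep)] = reads

    return libraries, truth, planted


# ---------------------------------------------------------------------------
# Degradome
# ---------------------------------------------------------------------------

def simulate_degradome(
    config: SimulationConfig,
    planted: Sequence[PlantedTarget],
    transcripts: Mapping[str, str],
    genotype: str = "het",
) -> dict[str, list[tuple[str, int]]]:
    """Per-replicate degradome 5'-end records (transcript coordinates).

    Every planted cut receives exactly ``degradome_depth`` records in every
    replicate; background 5' ends are Poisson over the transcriptome at
    ``degradome_background_rate`` per base.
    """
    config.validate()
    for t in planted:
        if t.gene not in transcripts:
            raise SimulationError(f"planted site on unknown transcript {t.gene!r}")
        if not 0 <= t.cut < len(transcripts[t.gene]):
            raise SimulationError("planted cut outside transcript bounds")
    # stable per-genotype stream offset (string hash is process-dependent)
    offset = sum(genotype.encode())
    rng = config.rng(_STREAM_DEGRADOME * 1000 + offset)
    out: dict[str, list[tuple[str, int]]] = {}
    for rep in range(1, config.n_degradome_replicates + 1):
        records: list[tuple[str, int]] = []
        for t in planted:
            records.extend((t.gene, t.cut) for _ in range(config.degradome_depth))
        if config.degradome_background_rate > 0:
            for tid, tseq in transcripts.items():
                n_bg = rng.poisson(config.degradome_background_rate * len(tseq))
                for pos in rng.integers(0, len(tseq), size=n_bg):
                    records.append((tid, int(pos)))
        out[f"rep{rep}"] = records
    return out


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with var = mu + dispersion * mu^2 (Poisson at dispersion 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    pirna_ids: Sequence[str],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene and piRNA count matrices across genotypes and replicates.

    Planted regulated genes have their mutant mean multiplied by
    ``target_effect``; planted down-piRNAs divided by ``pirna_effect``; all
    other features share equal means across genotypes.
    """
    config.validate()
    rng = config.rng(_STREAM_COUNTS)
    samples = [
        f"{g}_{r}" for g in GENOTYPES for r in range(1, config.n_replicates + 1)
    ]

    def matrix(ids: Sequence[str], up: set[str], up_factor: float) -> pd.DataFrame:
        base = config.count_mean * rng.lognormal(0.0, 0.25, size=len(ids))
        data = {}
        for sample in samples:
            genotype = sample.rsplit("_", 1)[0]
            mean = base.copy()
            if genotype == "mut":
                mask = np.array([i in up for i in ids])
                mean[mask] = mean[mask] * up_factor
            data[sample] = _nb_counts(rng, mean, config.nb_dispersion)
        return pd.DataFrame(data, index=list(ids))

    gene_counts = matrix(gene_ids, set(truth.regulated_genes), config.target_effect)
    pirna_counts = matrix(
        pirna_ids, set(truth.down_pirnas), 1.0 / config.pirna_effect
    )
    return gene_counts, pirna_counts


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all four simulation stages under one seed."""
    genome = simulate_genome(config)
    libraries, truth, planted = simulate_pirna_libraries(config, genome)
    transcripts = genome.transcripts()
    degradome = {
        genotype: simulate_degradome(config, planted, transcripts, genotype)
        for genotype in GENOTYPES
    }
    gene_ids = [g.name for g in genome.genes]
    pirna_ids = sorted({t.sequence for t in planted})
    # piRNA count matrix covers planted guides plus a background of
    # non-regulated pseudo-piRNA features for realistic multiple testing
    n_background = max(0, 200 - len(pirna_ids))
    pirna_ids = pirna_ids + [f"bg_pirna_{i:04d}" for i in range(n_background)]
    gene_counts, pirna_counts = simulate_counts(config, gene_ids, pirna_ids, truth)
    return SyntheticDataset(
        config=config,
        genome=genome,
        libraries=libraries,
        truth=truth,
        planted_targets=planted,
        degradome=degradome,
        gene_counts=gene_counts,
        pirna_counts=pirna_counts,
    )
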