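"""End-to-end orchestration with a JSON report.

Stage order mirrors the analysis flow: simulate (optional) -> ping-pong ->
length profiles -> representatives -> expression filter -> target scan ->
degradome support -> metatranscript / repeat annotation -> differential
expression -> integration.  Each stage writes its outputs before dependents
run; a stage whose output files already exist is skipped on rerun, so
deleting an intermediate regenerates only the downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import expression_de, length_profiles, pingpong, synthetic_data, targeting
from .io_formats import read_alignments, read_bed, read_counts, read_fasta, write_tsv

log = logging.getLogger("pirnakit")


class PipelineError(RuntimeError):
    """A stage failed; dependents are aborted."""


@dataclass
class PipelineConfig:
    outdir: str = "pirnakit_out"
    seed: int = 0
    simulate: dict[str, Any] = field(default_factory=dict)
    window: int = 30
    weighting: str = "product"
    min_matches: int = 14
    allow_pos1_mismatch: bool = True
    degradome_tolerance: int = 0
    expression_threshold: int = 100
    gene_max_adj_p: float = 0.1
    pirna_max_adj_p: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.window < 10:
            raise ValueError("window must cover the 10-nt overlap bin")
        if self.weighting not in pingpong.WEIGHTING_MODES:
            raise ValueError(f"weighting must be one of {pingpong.WEIGHTING_MODES}")
        if self.min_matches < 0 or self.min_matches > 19:
            raise ValueError("min_matches must lie in 0..19")
        if self.degradome_tolerance < 0:
            raise ValueError("degradome_tolerance must be >= 0")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages on a simulated dataset; return (and write) the report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = outdir / "data"
    report: dict[str, Any] = {"seed": config.seed}

    # --- stage: simulate -------------------------------------------------
    sim_cfg = synthetic_data.SimulationConfig(
        seed=config.seed, **config.simulate
    )
    marker = data_dir / "gene_counts.tsv"
    if not marker.exists():
        log.info("stage simulate: generating dataset")
        try:
            dataset = synthetic_data.simulate_dataset(sim_cfg)
            dataset.write(data_dir)
        except synthetic_data.SimulationError as exc:
            raise PipelineError(f"simulate failed: {exc}") from exc
    else:
        log.info("stage simulate: outputs present, skipping")
        dataset = synthetic_data.simulate_dataset(sim_cfg)
    report["inputs"] = {
        p.name: _checksum(p) for p in sorted(data_dir.glob("*.tsv"))
    }

    genome = dataset.genome.fasta()
    transcripts = dataset.genome.transcripts()
    models = dataset.genome.transcript_models()

    # --- stage: ping-pong -------------------------------------------------
    pp_rows = []
    for protein in synthetic_data.PROTEINS:
        for genotype in synthetic_data.GENOTYPES:
            reads = dataset.libraries[(protein, genotype, 1)]
            hist = pingpong.five_prime_distance_histogram(
                reads, window=config.window, weighting=config.weighting
            )
            stat = pingpong.pingpong_zscore(hist)
            frac = pingpong.pingpong_pair_fraction(reads)
            pp_rows.append(
                {
                    "protein": protein,
                    "genotype": genotype,
                    "z": stat.z,
                    "w10": stat.w10,
                    "degenerate": stat.degenerate,
                    "pair_fraction": frac.fraction,
                }
            )
    write_tsv(pp_rows, outdir / "pingpong.tsv")
    report["pingpong"] = pp_rows

    # --- stage: length profiles ------------------------------------------
    het = dataset.libraries[("MIWI", "het", 1)]
    mut = dataset.libraries[("MIWI", "mut", 1)]
    dm = length_profiles.delta_median(
        length_profiles.median_length_by_5prime(het),
        length_profiles.median_length_by_5prime(mut),
    )
    report["delta_median"] = {
        "n_shared_5p_ends": len(dm.deltas),
        "modal_delta": dm.modal_delta,
    }
    origin = length_profiles.genomic_feature_assignment(
        het,
        {
            "cluster": dataset.genome.clusters,
            "gene": [g.interval for g in dataset.genome.genes],
            "repeat": dataset.genome.repeats,
        },
    )
    report["genomic_origin"] = origin

    # --- stage: representatives + expression filter ----------------------
    all_miwi = [
        r
        for genotype in synthetic_data.GENOTYPES
        for rep in range(1, sim_cfg.n_replicates + 1)
        for r in dataset.libraries[("MIWI", genotype, rep)]
    ]
    reps = targeting.collapse_representatives(all_miwi, genome)
    report["n_representatives"] = len(reps)
    expressed = expression_de.expressed_transcript_filter(
        dataset.gene_counts, config.expression_threshold
    )
    report["n_expressed_transcripts"] = len(expressed)

    # --- stage: targeting -------------------------------------------------
    # scanning every representative is quadratic; restrict to the abundant
    # ones plus all planted guides, which is what the report cares about
    abundant = sorted(
        reps, key=lambda s: -reps[s].total_abundance
    )[:200]
    guides = set(abundant) | {t.sequence for t in dataset.planted_targets}
    scan_transcripts = {
        tid: seq for tid, seq in transcripts.items() if tid in expressed
    }
    sites = targeting.scan_all_targets(
        sorted(guides),
        scan_transcripts,
        min_matches=config.min_matches,
        allow_pos1_mismatch=config.allow_pos1_mismatch,
    )
    report["n_theoretical_sites"] = len(sites)

    degradome = dataset.degradome["het"]
    targeting.degradome_support(sites, degradome, tolerance=config.degradome_tolerance)
    supported = [s for s in sites if s.supported]
    report["n_supported_sites"] = len(supported)

    report["region_counts"] = targeting.metatranscript_distribution(supported, models)
    origins = {s: reps[s].origin for s in reps if s in guides}
    for t in dataset.planted_targets:
        origins.setdefault(t.sequence, t.origin)
    classes = targeting.repeat_overlap(sites, origins, dataset.genome.repeats)
    report["repeat_classes"] = {
        c: sum(1 for v in classes.values() if v == c)
        for c in ("sense", "antisense", "none")
    }
    write_tsv(
        [
            {
                "pirna": s.pirna,
                "transcript": s.transcript,
                "cut": s.cut,
                "matches_7_25": s.matches_7_25,
                "region": s.region,
                "repeat_class": s.repeat_class,
                "supported": s.supported,
            }
            for s in sites
        ],
        outdir / "sites.tsv",
    )

    # --- stage: differential expression ----------------------------------
    groups = {
        c: c.rsplit("_", 1)[0] for c in dataset.gene_counts.columns
    }
    try:
        gene_de_df = expression_de.differential_expression(
            dataset.gene_counts, groups, control="het", treatment="mut"
        )
        pirna_groups = {c: c.rsplit("_", 1)[0] for c in dataset.pirna_counts.columns}
        pirna_de_df = expression_de.differential_expression(
            dataset.pirna_counts, pirna_groups, control="het", treatment="mut"
        )
    except ValueError as exc:
        raise PipelineError(f"differential expression failed: {exc}") from exc
    gene_de_df.rename_axis("feature").to_csv(outdir / "gene_de.tsv", sep="\t")
    pirna_de_df.rename_axis("feature").to_csv(outdir / "pirna_de.tsv", sep="\t")

    # --- stage: integration ----------------------------------------------
    gene_de = expression_de.de_results_from_table(gene_de_df)
    pirna_de = expression_de.de_results_from_table(pirna_de_df)
    # piRNAs outside the count matrix are untested: treat as unchanged
    for s in supported:
        if s.pirna not in pirna_de:
            pirna_de[s.pirna] = expression_de.DEResult(s.pirna, 0.0, 1.0, 1.0)
    pairs = expression_de.integrate_regulated_targets(
        supported,
        gene_de,
        pirna_de,
        gene_max_adj_p=config.gene_max_adj_p,
        pirna_max_adj_p=config.pirna_max_adj_p,
    )
    report["integration"] = expression_de.summarize_pairs(pairs)
    report["regulated_genes"] = sorted({p.gene for p in pairs})
    write_tsv(
        [
            {
                "gene": p.gene,
                "pirna": p.pirna,
                "cut": p.site.cut,
                "gene_log2fc": p.gene_de.log2fc,
                "gene_adj_p": p.gene_de.adj_p,
                "pirna_log2fc": p.pirna_de.log2fc,
                "pirna_adj_p": p.pirna_de.adj_p,
            }
            for p in pairs
        ],
        outdir / "regulated_pairs.tsv",
    )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
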