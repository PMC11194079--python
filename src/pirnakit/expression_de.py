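"""Expression filtering, a stand-in DE test and the regulated-gene integration.

The differential-expression test is deliberately simple and self-contained
(the original analyses used off-the-shelf count-model fitters): counts are
library-size normalized, a common negative-binomial dispersion is estimated
by moments, per-group sums are deflated to a Poisson-like scale, and the
two groups are compared with an exact conditional binomial test, followed by
Benjamini-Hochberg adjustment.  Externally computed DE tables can be
supplied instead, so the integration step is fitter-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .targeting import TargetSite

DEFAULT_EXPRESSION_THRESHOLD = 100

# threshold presets, named after the steps that use them
GENE_DE_THRESHOLDS = {"max_adj_p": 0.05, "min_abs_log2fc": 1.0}
PIRNA_DE_THRESHOLDS = {"max_adj_p": 0.05, "min_abs_log2fc": 0.0}
INTEGRATION_GENE_THRESHOLDS = {"max_adj_p": 0.1, "direction": "up"}
INTEGRATION_PIRNA_THRESHOLDS = {"max_adj_p": 0.25, "direction": "down"}


@dataclass
class DEResult:
    feature: str
    log2fc: float
    pvalue: float
    adj_p: float


def expressed_transcript_filter(
    counts: pd.DataFrame, threshold: int = DEFAULT_EXPRESSION_THRESHOLD
) -> set[str]:
    """Features with at least ``threshold`` reads in at least one sample."""
    mask = counts.max(axis=1) >= threshold
    return set(counts.index[mask])


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clamped to [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _normalize(counts: pd.DataFrame, method: str = "total") -> pd.DataFrame:
    """Scale each library to the mean library size.

    ``total``: total-count scaling.  ``median_ratio``: median-of-ratios
    against the geometric-mean pseudo-reference (features with any zero are
    ignored for the factor).
    """
    libsizes = counts.sum(axis=0).astype(float)
    if method == "total":
        factors = libsizes / libsizes.mean()
    elif method == "median_ratio":
        logs = np.log(counts.replace(0, np.nan))
        ref = logs.mean(axis=1)
        ratios = logs.sub(ref, axis=0)
        factors = np.exp(ratios.median(axis=0))
        factors = factors / np.exp(np.log(factors).mean())
    else:
        raise ValueError(f"unknown normalization {method!r}")
    factors = factors.replace(0, 1.0).fillna(1.0)
    return counts / factors


def estimate_common_dispersion(
    normalized: pd.DataFrame, groups: Mapping[str, str]
) -> float:
    """Moment estimate of a common NB dispersion across features.

    Within each group, var = mu + alpha * mu^2; pooling over features and
    groups gives ``alpha = sum(var - mu) / sum(mu^2)``.  May be <= 0 for
    under-dispersed data (callers then fall back to Poisson).
    """
    num = 0.0
    den = 0.0
    labels = pd.Series(groups)
    for g in labels.unique():
        cols = labels.index[labels == g]
        sub = normalized[cols]
        if sub.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        mu = sub.mean(axis=1).to_numpy()
        var = sub.var(axis=1, ddof=1).to_numpy()
        num += float(np.sum(var - mu))
        den += float(np.sum(mu**2))
    return num / den if den > 0 else 0.0


def differential_expression(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    control: str,
    treatment: str,
    normalization: str = "total",
) -> pd.DataFrame:
    """Per-feature log2 fold change and exact-style two-sided p-value.

    Returns a DataFrame indexed by feature with columns ``log2fc``,
    ``pvalue`` and ``adj_p`` (treatment vs control).  All-zero features get
    ``log2fc = 0, pvalue = 1``.  Fold changes use a 0.5-count prior on the
    normalized group means.
    """
    labels = pd.Series(groups)
    ctrl_cols = list(labels.index[labels == control])
    trt_cols = list(labels.index[labels == treatment])
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [c for c in ctrl_cols + trt_cols if c not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from count table: {missing}")

    norm = _normalize(counts[ctrl_cols + trt_cols], normalization)
    alpha = estimate_common_dispersion(norm, {c: groups[c] for c in norm.columns})

    mean_ctrl = norm[ctrl_cols].mean(axis=1).to_numpy()
    mean_trt = norm[trt_cols].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_trt + 0.5) / (mean_ctrl + 0.5))

    sum_ctrl = norm[ctrl_cols].sum(axis=1).to_numpy()
    sum_trt = norm[trt_cols].sum(axis=1).to_numpy()
    # deflate sums so their variance is approximately Poisson, then apply an
    # exact conditional binomial test on the deflated integer pseudo-counts
    mu = (sum_ctrl + sum_trt) / (len(ctrl_cols) + len(trt_cols))
    shrink = 1.0 / (1.0 + max(alpha, 0.0) * mu)
    a = np.rint(sum_trt * shrink).astype(np.int64)
    b = np.rint(sum_ctrl * shrink).astype(np.int64)
    p_null = len(trt_cols) / (len(trt_cols) + len(ctrl_cols))

    pvals = np.ones(len(counts), dtype=float)
    for i, (ai, ti) in enumerate(zip(a, a + b)):
        if ti == 0:
            continue
        pvals[i] = stats.binomtest(int(ai), int(ti), p_null).pvalue
    zero = (sum_ctrl + sum_trt) == 0
    log2fc = np.where(zero, 0.0, log2fc)
    pvals = np.where(zero, 1.0, pvals)

    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "adj_p": benjamini_hochberg(pvals)},
        index=counts.index,
    )


def de_results_from_table(df: pd.DataFrame) -> dict[str, DEResult]:
    """Adapt a (feature, log2fc, pvalue, adj_p) table, external or internal."""
    if "feature" in df.columns:
        df = df.set_index("feature")
    return {
        str(f): DEResult(
            feature=str(f),
            log2fc=float(row["log2fc"]),
            pvalue=float(row["pvalue"]),
            adj_p=float(row["adj_p"]),
        )
        for f, row in df.iterrows()
    }


@dataclass
class RegulatedPair:
    gene: str
    pirna: str
    site: TargetSite
    gene_de: DEResult
    pirna_de: DEResult


def _passes(de: DEResult, max_adj_p: float, direction: str) -> bool:
    if not de.adj_p < max_adj_p:
        return False
    if direction == "up":
        return de.log2fc > 0
    if direction == "down":
        return de.log2fc < 0
    raise ValueError(f"unknown direction {direction!r}")


def integrate_regulated_targets(
    sites: Sequence[TargetSite],
    gene_de: Mapping[str, DEResult],
    pirna_de: Mapping[str, DEResult],
    gene_of_transcript: Mapping[str, str] | None = None,
    gene_max_adj_p: float = 0.1,
    pirna_max_adj_p: float = 0.25,
) -> list[RegulatedPair]:
    """Nominate piRNA-regulated genes from supported sites plus DE results.

    A pair is emitted iff its site's degradome verdict is supported, its
    gene is up-regulated (adj_p < ``gene_max_adj_p``, log2fc > 0) and its
    targeting piRNA is down-regulated (adj_p < ``pirna_max_adj_p``,
    log2fc < 0).  A missing DE entry for a referenced feature is an error.
    Output is sorted by gene, then transcript coordinate.
    """
    pairs: list[RegulatedPair] = []
    for site in sites:
        if not site.supported:
            continue
        gene = (
            gene_of_transcript.get(site.transcript, site.transcript)
            if gene_of_transcript
            else site.transcript
        )
        if gene not in gene_de:
            raise KeyError(f"no gene DE entry for {gene!r}")
        if site.pirna not in pirna_de:
            raise KeyError(f"no piRNA DE entry for {site.pirna!r}")
        g = gene_de[gene]
        p = pirna_de[site.pirna]
        if _passes(g, gene_max_adj_p, "up") and _passes(p, pirna_max_adj_p, "down"):
            pairs.append(
                RegulatedPair(gene=gene, pirna=site.pirna, site=site, gene_de=g, pirna_de=p)
            )
    pairs.sort(key=lambda pr: (pr.gene, pr.site.transcript, pr.site.cut))
    return pairs


def summarize_pairs(pairs: Sequence[RegulatedPair]) -> dict[str, int]:
    return {
        "n_pairs": len(pairs),
        "n_genes": len({p.gene for p in pairs}),
        "n_pirnas": len({p.pirna for p in pairs}),
    }
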