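"""Higher-level statistics over per-gene and per-motif-set results.

Covers the bimodality (dip) test of enrichment-P distributions, the
tail-proportion contingency test comparing RBP motifs with random k-mers,
the global-reduction estimate (density x normalized rate x 100, the
percentage decrease in the region's substitution rate attributable to motif
preservation), expression parameters from a gene x tissue TPM table, and
rank correlations between enrichment and conservation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dip import DipResult, dip_test  # noqa: F401  (re-exported pipeline surface)


@dataclass
class ReductionEstimate:
    density: float
    norm_rate: float
    reduction_pct: float


def global_reduction(density: float, norm_rate: float) -> float:
    """Percentage change in substitution rate due to motif preservation.

    The product of the motif density and the normalized conservation
    statistic, times 100.  Negative values (norm_rate < 0) mean the region
    evolves slower over-all because of the pressure to preserve motifs.
    """
    return density * norm_rate * 100.0


def reduction_estimate(density: float, norm_rate: float) -> ReductionEstimate:
    return ReductionEstimate(density, norm_rate, global_reduction(density, norm_rate))


def tail_proportion_test(
    pvals_a,
    pvals_b,
    lower: float = 0.1,
    upper: float = 0.9,
    mode: str = "both_tails",
) -> tuple[float, float]:
    """Chi-square comparison of extreme-P proportions between two collections.

    ``mode='both_tails'`` classes P values as extreme (< lower or > upper)
    vs middle (between the cutoffs, boundaries included in the middle);
    ``mode='upper_tail'`` classes them as > upper vs <= upper.  Pearson
    chi-square with 1 df, no continuity correction.
    """
    a = np.asarray(pvals_a, dtype=float)
    b = np.asarray(pvals_b, dtype=float)

    def split(p):
        if mode == "both_tails":
            extreme = np.sum((p < lower) | (p > upper))
        elif mode == "upper_tail":
            extreme = np.sum(p > upper)
        else:
            raise ValueError("mode must be 'both_tails' or 'upper_tail'")
        return int(extreme), int(p.size - extreme)

    table = np.array([split(a), split(b)])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def expression_params(table: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Per-gene expression parameters from a gene x sample TPM table.

    Returns breadth (fraction of tissues with TPM strictly above the
    threshold), median, max, and median over expressed tissues (NaN with
    ``expressed_nowhere`` True when the gene clears the threshold in no
    tissue).
    """
    if (table.values < 0).any():
        raise ValueError("TPM values must be non-negative")
    expressed = table.values > threshold
    breadth = expressed.mean(axis=1)
    med_in_expr = np.full(len(table), np.nan)
    for i, row in enumerate(table.values):
        vals = row[expressed[i]]
        if vals.size:
            med_in_expr[i] = float(np.median(vals))
    return pd.DataFrame(
        {
            "breadth": breadth,
            "median": np.median(table.values, axis=1),
            "max": table.values.max(axis=1),
            "median_expressed": med_in_expr,
            "expressed_nowhere": ~expressed.any(axis=1),
        },
        index=table.index,
    )


def correlate_enrichment_conservation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) between per-set statistics.

    Used for (ND, normalized dS), (enrichment P, conservation P) and
    (ND, normalized gain) pairs.  Requires at least 5 sets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need at least 5 sets with both statistics defined")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def bonferroni(pvals, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-corrected P values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    k = n_tests if n_tests is not None else p.size
    return np.minimum(p * k, 1.0)


def expression_correlations(
    nd_by_gene: pd.Series, expr_params: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of ND with each expression parameter.

    Bonferroni correction uses the number of parameters tested (the four
    columns), reproducing the usual multiple-testing treatment of such
    tables.
    """
    cols = ["breadth", "max", "median", "median_expressed"]
    shared = nd_by_gene.index.intersection(expr_params.index)
    rows = []
    for c in cols:
        x = nd_by_gene.loc[shared]
        y = expr_params.loc[shared, c]
        ok = x.notna() & y.notna()
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"parameter": c, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].values, len(cols))
    return out


def mannwhitney_by_label(values, labels, group_a, group_b, alternative="greater"):
    """One-tailed Mann-Whitney U comparing a statistic between two label groups.

    Thin utility for comparing e.g. CDS-binding vs non-CDS-binding RBP
    annotations; the labels are an input column, not derived here.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == group_a]
    b = values[labels == group_b]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(stat), float(p)
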