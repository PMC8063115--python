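"""Percent intron retention (PIR) and its stratified analyses.

PIR treats the mean of the two exon-intron boundary counts as one unspliced
observation per RNA molecule (each retained intron can be sequenced at both
its 5' and 3' splice site):

    retained = (EI5 + EI3) / 2
    PIR      = retained / (retained + EE)

PIR = 0 means fully spliced (cotranscriptionally, for nascent RNA);
PIR = 1 means completely unspliced.  Introns with fewer than ``min_total``
junction-informative reads are reported as NA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import assign_quantile_groups


def compute_pir(counts: pd.DataFrame, min_total: float = 10) -> pd.DataFrame:
    """Add ``retained_reads`` and ``pir`` columns to a junction-count table.

    ``counts`` needs columns ``ei5``, ``ei3``, ``ee``.  PIR is NA where
    retained + EE < ``min_total``.
    """
    for col in ("ei5", "ei3", "ee"):
        if (counts[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    out = counts.copy()
    retained = (out["ei5"] + out["ei3"]) / 2.0
    total = retained + out["ee"]
    pir = np.where(total >= min_total, retained / np.where(total > 0, total, 1), np.nan)
    out["retained_reads"] = retained
    out["pir"] = pir
    return out


def gene_average_pir(pir_table: pd.DataFrame, introns) -> pd.Series:
    """Unweighted per-gene mean of non-NA constitutive-intron PIRs.

    ``introns`` maps intron_id -> gene_id (Series/dict) or is a constitutive
    intron table with those columns.  Genes whose introns are all NA are
    excluded.
    """
    if isinstance(introns, pd.DataFrame):
        mapping = introns.set_index("intron_id")["gene_id"]
    else:
        mapping = pd.Series(dict(introns)) if not isinstance(introns, pd.Series) else introns
    df = pir_table.dropna(subset=["pir"]).copy()
    df["gene_id"] = df["intron_id"].map(mapping)
    df = df.dropna(subset=["gene_id"])
    return df.groupby("gene_id")["pir"].mean()


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value, 1.0 for the fully
    degenerate all-tied case."""
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


@dataclass
class StratifiedPIR:
    """PIR distributions across quantile groups of a covariate."""

    covariate: str
    k: int
    labels: np.ndarray  # group 1..k per observation
    summary: pd.DataFrame  # group, n, median, q1, q3
    adjacent_p: list[float]  # Wilcoxon rank-sum p between groups i, i+1


def stratify_pir(
    pir: np.ndarray | pd.Series,
    covariate: np.ndarray | pd.Series,
    k: int = 5,
    covariate_name: str = "covariate",
) -> StratifiedPIR:
    """Split observations into ``k`` covariate quantile groups and summarize
    the PIR distribution per group, testing adjacent groups with a two-sided
    Wilcoxon rank-sum test."""
    pir = np.asarray(pir, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if pir.shape != covariate.shape:
        raise ValueError("pir and covariate must align")
    mask = np.isfinite(pir) & np.isfinite(covariate)
    pir, covariate = pir[mask], covariate[mask]
    labels = assign_quantile_groups(covariate, k)
    rows, pvals = [], []
    groups = [pir[labels == g] for g in range(1, k + 1)]
    for g, vals in enumerate(groups, 1):
        q1, med, q3 = (
            np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
        )
        rows.append(dict(group=g, n=len(vals), median=med, q1=q1, q3=q3))
    for a, b in zip(groups, groups[1:]):
        pvals.append(_ranksum_p(a, b))
    return StratifiedPIR(covariate_name, k, labels, pd.DataFrame(rows), pvals)


@dataclass
class PairedPIRComparison:
    n: int
    median_a: float
    median_b: float
    p_value: float


def compare_pir_cb_vs_polya(
    pir_a: pd.DataFrame | pd.Series, pir_b: pd.DataFrame | pd.Series
) -> PairedPIRComparison:
    """Paired comparison of PIR between two assays over shared non-NA introns
    (two-sided Wilcoxon signed-rank).  Typically a = nascent/CB, b = mature
    polyA RNA."""

    def _series(x):
        if isinstance(x, pd.DataFrame):
            return x.set_index("intron_id")["pir"]
        return x

    a, b = _series(pir_a), _series(pir_b)
    shared = a.dropna().index.intersection(b.dropna().index)
    if len(shared) == 0:
        raise ValueError("no shared introns with defined PIR")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if np.allclose(x, y):
        p = 1.0
    else:
        p = float(stats.wilcoxon(x, y, zero_method="zsplit").pvalue)
    return PairedPIRComparison(
        n=len(shared),
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        p_value=p,
    )


def plot_stratified_pir(strat: StratifiedPIR, pir, path: str) -> None:
    """Plain boxplot export of a stratified PIR analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pir = np.asarray(pir, dtype=float)
    data = [pir[strat.labels == g] for g in range(1, strat.k + 1)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot(data, showfliers=False)
    ax.set_xlabel(f"{strat.covariate} quantile group")
    ax.set_ylabel("PIR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
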