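"""TPM quantification, nascent-vs-mature stability classification, and
cross-assay fold-change concordance.

Steady-state (polyA) RNA abundance is modeled as a log-log linear function of
nascent (chromatin-bound) abundance:

    log2 TPM_polyA = intercept + slope * log2 TPM_CB + residual

Genes whose actual polyA TPM is at least ``fold`` (default 3) times the value
predicted by this regression are called *stable*; at most 1/``fold`` times,
*unstable*; everything else is *concordant*.  Both boundaries are inclusive.
The polyA assay is always the response and the CB assay the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and effective (union-exon)
    lengths: tpm_g = 1e6 * (count_g/len_g) / sum_j (count_j/len_j)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing effective lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = list(denom.index[denom == 0])
        raise ValueError(f"all-zero samples: {bad}")
    return rate.div(denom, axis=1) * 1e6


@dataclass
class StabilityModel:
    """OLS of log2 polyA TPM on log2 CB TPM over genes active in both."""

    slope: float
    intercept: float
    genes: pd.Index
    r_value: float

    def predict_polya_tpm(self, tpm_cb) -> np.ndarray:
        return 2.0 ** (self.intercept + self.slope * np.log2(np.asarray(tpm_cb)))


def fit_stability_model(
    tpm_cb: pd.Series,
    tpm_polya: pd.Series,
    active_tpm: float = 1.0,
    min_genes: int = 10,
) -> StabilityModel:
    """Fit the log2-log2 regression on genes with TPM > ``active_tpm`` in
    both assays (at least ``min_genes`` of them)."""
    shared = tpm_cb.index.intersection(tpm_polya.index)
    x, y = tpm_cb.loc[shared], tpm_polya.loc[shared]
    mask = (x > active_tpm) & (y > active_tpm)
    if int(mask.sum()) < max(min_genes, 2):
        raise ValueError(f"only {int(mask.sum())} active genes; need >= {min_genes}")
    lx = np.log2(x[mask].to_numpy(dtype=float))
    ly = np.log2(y[mask].to_numpy(dtype=float))
    if np.ptp(lx) == 0:
        raise ValueError("zero-variance predictor")
    fit = stats.linregress(lx, ly)
    return StabilityModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        genes=shared[mask],
        r_value=float(fit.rvalue),
    )


def classify_stability(
    model: StabilityModel,
    tpm_cb: pd.Series,
    tpm_polya: pd.Series,
    fold: float = 3.0,
    active_tpm: float = 1.0,
) -> pd.DataFrame:
    """Label genes stable / unstable / concordant by the ``fold`` rule
    (inclusive boundaries) on actual vs model-predicted polyA TPM.  Genes
    inactive in the CB assay are excluded."""
    shared = tpm_cb.index.intersection(tpm_polya.index)
    cb = tpm_cb.loc[shared]
    keep = cb > active_tpm
    cb = cb[keep]
    actual = tpm_polya.loc[cb.index].to_numpy(dtype=float)
    predicted = model.predict_polya_tpm(cb.to_numpy(dtype=float))
    ratio = actual / predicted
    # inclusive boundaries, robust to float rounding at exactly fold / 1/fold
    tol = 1e-9
    label = np.where(
        ratio >= fold * (1 - tol),
        "stable",
        np.where(ratio <= (1.0 / fold) * (1 + tol), "unstable", "concordant"),
    )
    return pd.DataFrame(
        {
            "gene_id": cb.index,
            "tpm_cb": cb.to_numpy(dtype=float),
            "predicted_tpm": predicted,
            "actual_tpm": actual,
            "ratio": ratio,
            "label": label,
        }
    ).set_index("gene_id")


@dataclass
class FoldChangeConcordance:
    table: pd.DataFrame  # per-gene log2FC in each assay
    rho: float  # Spearman over genes tested in both
    n_a_only: int  # |log2FC| gate passed in assay A only
    n_shared: int  # passed in both with the same direction
    n_b_only: int


def fold_change_concordance(
    tpm_a_cond1: pd.DataFrame | pd.Series,
    tpm_a_cond2: pd.DataFrame | pd.Series,
    tpm_b_cond1: pd.DataFrame | pd.Series,
    tpm_b_cond2: pd.DataFrame | pd.Series,
    pseudocount: float = 1.0,
    min_abs_log2fc: float = 1.0,
) -> FoldChangeConcordance:
    """Between-condition log2 fold changes in two assays and their
    concordance.

    Inputs are genes x replicates TPM frames (or Series of replicate-mean
    TPM) for condition 1 and 2 in assay A (e.g. CB) and assay B (e.g. polyA).
    log2FC = log2((mean1 + c)/(mean2 + c)).  The ``min_abs_log2fc`` gate
    mirrors a |fold change| > 2 magnitude cut-off; statistical DEG testing is
    delegated to dedicated tools.
    """

    def _mean(x) -> pd.Series:
        return x.mean(axis=1) if isinstance(x, pd.DataFrame) else x

    a1, a2, b1, b2 = map(_mean, (tpm_a_cond1, tpm_a_cond2, tpm_b_cond1, tpm_b_cond2))
    genes = a1.index.intersection(a2.index).intersection(b1.index).intersection(b2.index)
    if len(genes) == 0:
        raise ValueError("no genes present in all four tables")
    c = pseudocount
    lfc_a = np.log2((a1.loc[genes] + c) / (a2.loc[genes] + c))
    lfc_b = np.log2((b1.loc[genes] + c) / (b2.loc[genes] + c))
    rho = float(stats.spearmanr(lfc_a, lfc_b).statistic)
    hit_a = lfc_a.abs() > min_abs_log2fc
    hit_b = lfc_b.abs() > min_abs_log2fc
    same_dir = np.sign(lfc_a) == np.sign(lfc_b)
    table = pd.DataFrame({"log2fc_a": lfc_a, "log2fc_b": lfc_b})
    return FoldChangeConcordance(
        table=table,
        rho=rho,
        n_a_only=int((hit_a & ~(hit_b & same_dir)).sum()),
        n_shared=int((hit_a & hit_b & same_dir).sum()),
        n_b_only=int((hit_b & ~(hit_a & same_dir)).sum()),
    )
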