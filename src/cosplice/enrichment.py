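"""Term-enrichment testing: upper-tail hypergeometric p-values with
Benjamini-Hochberg FDR adjustment.

The gene -> term mapping is taken as-is (no propagation up an ontology DAG).
For a universe of N genes of which K are annotated to a term, and a study set
of n genes of which k carry the term, the enrichment p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1
    and order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _term_members(term_map) -> dict[str, set[str]]:
    if isinstance(term_map, pd.DataFrame):
        return {
            t: set(sub["gene_id"]) for t, sub in term_map.groupby("term_id")
        }
    if isinstance(term_map, Mapping):
        return {t: set(g) for t, g in term_map.items()}
    raise TypeError("term_map must be a mapping term->genes or a DataFrame")


def read_term_map(path: str) -> pd.DataFrame:
    """Read a two-column (gene_id, term_id) TSV mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
    return df


def hypergeom_enrich(
    gene_set: Iterable[str],
    universe: Iterable[str],
    term_map,
) -> pd.DataFrame:
    """Test each term for over-representation in ``gene_set`` relative to
    ``universe``.  Returns a frame (term_id, k, K, n, N, p_value, q_value)
    sorted by q then p.  Genes in the set but not the universe raise."""
    genes = set(gene_set)
    uni = set(universe)
    stray = sorted(genes - uni)
    if stray:
        raise ValueError(f"genes in set but not universe: {stray}")
    members = _term_members(term_map)
    N, n = len(uni), len(genes)
    rows = []
    for term, annotated in sorted(members.items()):
        ann = annotated & uni
        K = len(ann)
        if K == 0:
            continue
        k = len(ann & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term_id=term, k=k, K=K, n=n, N=N, p_value=min(p, 1.0)))
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["q_value", "p_value"]).reset_index(drop=True)
    return df
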