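"""Alternative-splicing events, PSI quantification, and differential AS.

Events are enumerated from annotated isoform structures (no novel-junction
discovery).  Four event types are handled, mirroring the standard inventory:

* ES    - exon skipping: an internal exon included in some isoforms and
          exactly skipped (identical flanking splice sites) in others;
* A5SS  - two isoforms share an intron's acceptor but differ at the donor;
* A3SS  - share the donor, differ at the acceptor;
* RI    - an intron spliced in some isoforms lies fully inside an exon of
          another.

PSI for an event is the transcript-abundance fraction of the inclusion form:
PSI = sum TPM(inclusion) / sum TPM(inclusion + exclusion).  For A5SS/A3SS the
inclusion form is the variant with the shorter intron (longer exon).

Differential AS between two conditions uses the replicate-mean difference
dPSI = mean(A) - mean(B) and calls an event significant when |dPSI| > 0.1 and
p < 0.05.  The default significance test is a pooled-variance two-sample
t-test on replicate PSI values (replicate noise is assumed homoscedastic
between conditions); an exact/Monte-Carlo label-permutation test is
available as ``method="permutation"``, but note its resolution floor: with
3 vs 3 replicates the smallest achievable two-sided permutation p is
2/20 = 0.1, which can never clear an alpha of 0.05 (see docs/methods.md).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel

log = logging.getLogger(__name__)

AS_TYPES = ("A3SS", "A5SS", "ES", "RI")


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    etype: str  # one of AS_TYPES
    gene_id: str
    inclusion: frozenset[str]  # transcript ids carrying the inclusion form
    exclusion: frozenset[str]
    coords: tuple[int, ...]  # defining genomic coordinates

    def __post_init__(self) -> None:
        if not self.inclusion or not self.exclusion:
            raise ValueError(f"event {self.event_id}: empty isoform set")
        if self.inclusion & self.exclusion:
            raise ValueError(f"event {self.event_id}: overlapping isoform sets")


def _contains(exons, s: int, e: int, strict: bool = True) -> bool:
    """Is [s,e) inside one exon (strictly, so both junction flanks are exonic)?"""
    for xs, xe in exons:
        if (xs < s and e < xe) if strict else (xs <= s and e <= xe):
            return True
    return False


def enumerate_as_events(genes) -> list[ASEvent]:
    """Enumerate A3SS/A5SS/ES/RI events by exhaustive isoform comparison.

    Single-isoform genes yield no events.  Event ids are stable and carry the
    defining coordinates.
    """
    events: dict[tuple, ASEvent] = {}
    for g in genes:
        if len(g.transcripts) < 2:
            continue
        tx_introns = {t.transcript_id: set(t.introns) for t in g.transcripts}
        tx_exons = {t.transcript_id: t.exons for t in g.transcripts}
        all_introns = sorted(set().union(*tx_introns.values()))

        def with_intron(iv):
            return frozenset(t for t, ivs in tx_introns.items() if iv in ivs)

        # RI: intron (s,e) spliced in some isoforms, fully exonic in others
        for s, e in all_introns:
            incl = frozenset(
                t for t in tx_introns if _contains(tx_exons[t], s, e, strict=True)
            )
            excl = with_intron((s, e))
            if incl and excl:
                key = (g.gene_id, "RI", s, e)
                events[key] = ASEvent(
                    f"{g.gene_id};RI:{g.chrom}:{s}-{e}:{g.strand}",
                    "RI", g.gene_id, incl, excl, (s, e),
                )

        # ES: internal exon with both flanking introns vs the exact skip intron
        for t in g.transcripts:
            exons = tx_exons[t.transcript_id]
            for i in range(1, len(exons) - 1):
                xs, xe = exons[i]
                a = exons[i - 1][1]  # upstream intron start (genomic)
                b = exons[i + 1][0]  # downstream intron end
                skip = (a, b)
                excl = with_intron(skip)
                if not excl:
                    continue
                incl = frozenset(
                    u
                    for u in tx_introns
                    if (a, xs) in tx_introns[u]
                    and (xe, b) in tx_introns[u]
                    and (xs, xe) in tx_exons[u]
                ) - excl
                if not incl:
                    continue
                key = (g.gene_id, "ES", a, xs, xe, b)
                events[key] = ASEvent(
                    f"{g.gene_id};ES:{g.chrom}:{a}-{xs}^{xe}-{b}:{g.strand}",
                    "ES", g.gene_id, incl, excl, (a, xs, xe, b),
                )

        # A5SS / A3SS: intron pairs sharing exactly one boundary, where the
        # alternative region is exonic in the short-intron isoforms (this
        # excludes pairs that are really part of an ES comparison).
        for (s1, e1), (s2, e2) in combinations(all_introns, 2):
            if e1 == e2 and s1 != s2:  # shared genomic end
                lo, hi = sorted((s1, s2))
                short_iv, long_iv = ((hi, e1), (lo, e1))
                ok = [
                    t
                    for t in with_intron(short_iv)
                    if any(xe == hi and xs <= lo for xs, xe in tx_exons[t])
                ]
                etype = "A5SS" if g.strand == "+" else "A3SS"
                coords = (lo, hi, e1)
            elif s1 == s2 and e1 != e2:  # shared genomic start
                lo, hi = sorted((e1, e2))
                short_iv, long_iv = ((s1, lo), (s1, hi))
                ok = [
                    t
                    for t in with_intron(short_iv)
                    if any(xs == lo and xe >= hi for xs, xe in tx_exons[t])
                ]
                etype = "A3SS" if g.strand == "+" else "A5SS"
                coords = (s1, lo, hi)
            else:
                continue
            incl = frozenset(ok)  # shorter intron -> longer exon = inclusion
            excl = with_intron(long_iv) - incl
            if not incl or not excl:
                continue
            key = (g.gene_id, etype) + coords
            events[key] = ASEvent(
                f"{g.gene_id};{etype}:{g.chrom}:" +
                "-".join(map(str, coords)) + f":{g.strand}",
                etype, g.gene_id, incl, excl, coords,
            )
    return list(events.values())


def filter_active_events(
    events, tpm: pd.DataFrame, min_tpm: float = 1.0, min_samples: int = 3
) -> list[ASEvent]:
    """Keep events whose member transcripts all exceed ``min_tpm`` in at
    least ``min_samples`` samples (the transcript activity gate)."""
    active = (tpm > min_tpm).sum(axis=1) >= min_samples
    keep = []
    for ev in events:
        members = ev.inclusion | ev.exclusion
        if all(active.get(t, False) for t in members):
            keep.append(ev)
    return keep


def compute_psi(events, tpm: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """PSI per event per sample from transcript abundances.

    ``tpm`` is a transcripts x samples frame (or a Series for one sample).
    PSI is NA when the event's transcripts have zero total abundance.
    """
    if isinstance(tpm, pd.Series):
        tpm = tpm.to_frame("sample")
    if (tpm < 0).any().any():
        raise ValueError("negative transcript abundances")
    rows = []
    for ev in events:
        for sample in tpm.columns:
            col = tpm[sample]
            inc = float(col.reindex(list(ev.inclusion)).fillna(0.0).sum())
            tot = inc + float(col.reindex(list(ev.exclusion)).fillna(0.0).sum())
            rows.append(
                dict(
                    event_id=ev.event_id,
                    sample_id=sample,
                    psi=inc / tot if tot > 0 else np.nan,
                    inclusion_tpm=inc,
                    total_tpm=tot,
                )
            )
    return pd.DataFrame(rows)


def correlate_psi(
    psi_a: pd.DataFrame, psi_b: pd.DataFrame, events
) -> pd.DataFrame:
    """Spearman correlation of PSI between two assays, per AS type, with
    per-assay medians.  ``psi_a``/``psi_b`` are single-sample PSI tables."""
    etype = {ev.event_id: ev.etype for ev in events}
    a = psi_a.set_index("event_id")["psi"].dropna()
    b = psi_b.set_index("event_id")["psi"].dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared events with defined PSI")
    rows = []
    df = pd.DataFrame({"a": a.loc[shared], "b": b.loc[shared]})
    df["etype"] = [etype.get(e, "?") for e in df.index]
    for t, sub in df.groupby("etype"):
        if len(sub) < 3:
            log.warning("AS type %s has only %d shared events; skipped", t, len(sub))
            continue
        rho, p = stats.spearmanr(sub["a"], sub["b"])
        rows.append(
            dict(
                etype=t,
                n=len(sub),
                rho=float(rho),
                p_value=float(p),
                median_a=float(sub["a"].median()),
                median_b=float(sub["b"].median()),
            )
        )
    return pd.DataFrame(rows)


def _perm_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int, rng) -> float:
    """Two-sided label-permutation p for |mean(a) - mean(b)|.

    Exact enumeration when there are at most 20 label assignments, otherwise
    ``n_perm`` random assignments.  The observed assignment is included in
    the reference set, so the smallest exact 3v3 p is 2/20.
    """
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    obs = abs(a.mean() - b.mean())
    total_sum = pooled.sum()
    n_assign = math.comb(n, na)
    eps = 1e-12
    if n_assign <= 20:
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (total_sum - sa) / (n - na))
            if stat >= obs - eps:
                count += 1
        return count / n_assign
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sa = pooled[perm[:na]].sum()
        stat = abs(sa / na - (total_sum - sa) / (n - na))
        if stat >= obs - eps:
            count += 1
    return (count + 1) / (n_perm + 1)


def _ttest_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def differential_as(
    psi_a: pd.DataFrame,
    psi_b: pd.DataFrame,
    delta_threshold: float = 0.1,
    alpha: float = 0.05,
    method: str = "ttest",
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Differential AS calls between two conditions.

    ``psi_a``/``psi_b`` are events x replicates frames (index = event_id).
    Events with any NA replicate are excluded (logged).  dPSI is the
    replicate-mean of A minus B; an event is significant iff
    |dPSI| > ``delta_threshold`` and p < ``alpha``.
    """
    if method not in ("ttest", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    shared = psi_a.index.intersection(psi_b.index)
    a_df, b_df = psi_a.loc[shared], psi_b.loc[shared]
    ok = a_df.notna().all(axis=1) & b_df.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("%d events with NA replicates excluded", n_dropped)
    a_df, b_df = a_df[ok], b_df[ok]
    rng = np.random.default_rng(seed)
    rows = []
    for ev in a_df.index:
        a = a_df.loc[ev].to_numpy(dtype=float)
        b = b_df.loc[ev].to_numpy(dtype=float)
        delta = float(a.mean() - b.mean())
        if method == "permutation":
            p = _perm_pvalue(a, b, n_perm, rng)
        else:
            p = _ttest_pvalue(a, b)
        rows.append(
            dict(
                event_id=ev,
                delta_psi=delta,
                p_value=p,
                significant=bool(abs(delta) > delta_threshold and p < alpha),
            )
        )
    return pd.DataFrame(rows).set_index("event_id")


@dataclass
class CallOverlap:
    n_a_only: int
    n_shared: int
    n_b_only: int
    rho_all: float  # Spearman over all shared tested events
    rho_significant: float  # over the union of significant events (NaN if < 3)


def overlap_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> CallOverlap:
    """Venn counts of significant events from two assays plus rank
    correlation of the two dPSI vectors (reported over all shared tested
    events and over the union of significant ones)."""
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise ValueError("no shared tested events")
    a, b = calls_a.loc[shared], calls_b.loc[shared]
    sig_a = set(a.index[a["significant"]])
    sig_b = set(b.index[b["significant"]])
    rho_all = float(stats.spearmanr(a["delta_psi"], b["delta_psi"]).statistic)
    union = sorted(sig_a | sig_b)
    if len(union) >= 3:
        rho_sig = float(
            stats.spearmanr(
                a.loc[union, "delta_psi"], b.loc[union, "delta_psi"]
            ).statistic
        )
    else:
        rho_sig = float("nan")
    return CallOverlap(
        n_a_only=len(sig_a - sig_b),
        n_shared=len(sig_a & sig_b),
        n_b_only=len(sig_b - sig_a),
        rho_all=rho_all,
        rho_significant=rho_sig,
    )
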