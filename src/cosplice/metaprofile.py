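"""Scaled average coverage profiles (metagene and intron-anchored).

A metagene profile anchors every gene at its TSS and TES, keeps fixed-width
flank bins (default 2 kb of 50-bp bins) and length-scales the gene body into
a fixed number of bins; minus-strand genes are reversed so bin 0 is always
the 5' end.  Intron-anchored profiles do the same around introns with
fixed-width exonic flanks, optionally normalized bin-wise to a control track
(e.g. histone H3 for histone-modification ChIP), and are averaged within
intron groups (typically PIR quantile groups).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)


class CoverageTrack:
    """Per-base numeric coverage, one dense non-negative array per
    chromosome."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}
        for c, a in self.arrays.items():
            if (a < 0).any():
                raise ValueError(f"negative coverage on {c}")

    @classmethod
    def from_bedgraph(cls, path: str, chrom_sizes: dict[str, int] | None = None):
        """Read a bedGraph (0-based half-open intervals)."""
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
        )
        sizes = dict(chrom_sizes or {})
        for c, sub in df.groupby("chrom"):
            sizes.setdefault(c, int(sub["end"].max()))
        arrays = {c: np.zeros(sizes[c]) for c in df["chrom"].unique()}
        for c, sub in df.groupby("chrom"):
            a = arrays[c]
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                a[s:e] += v
        return cls(arrays)

    @classmethod
    def from_sam(cls, path: str, min_mapq: int = 0):
        """Per-base read coverage from an alignment file (aligned blocks
        only; splice gaps contribute nothing)."""
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            arrays = {
                name: np.zeros(length)
                for name, length in zip(fh.references, fh.lengths)
            }
            for aln in fh:
                if (
                    aln.is_unmapped
                    or aln.is_secondary
                    or aln.is_supplementary
                    or (aln.mapping_quality or 0) < min_mapq
                ):
                    continue
                a = arrays[aln.reference_name]
                for s, e in aln.get_blocks():
                    a[s:e] += 1
        return cls(arrays)

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions outside the
        chromosome are NaN."""
        a = self.arrays.get(chrom)
        out = np.full(end - start, np.nan)
        if a is None:
            return out
        lo, hi = max(start, 0), min(end, len(a))
        if lo < hi:
            out[lo - start: hi - start] = a[lo:hi]
        return out


@dataclass
class MetaProfile:
    """Mean signal per bin over a set of anchored, scaled regions."""

    values: np.ndarray
    n_regions: int
    upstream_bins: int
    body_bins: int
    downstream_bins: int
    flank_bin_size: int = 0

    @property
    def upstream(self) -> np.ndarray:
        return self.values[: self.upstream_bins]

    @property
    def body(self) -> np.ndarray:
        return self.values[self.upstream_bins: self.upstream_bins + self.body_bins]

    @property
    def downstream(self) -> np.ndarray:
        return self.values[self.upstream_bins + self.body_bins:]


def _bin_means(vals: np.ndarray, n_bins: int) -> np.ndarray:
    chunks = np.array_split(vals, n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN chunks
        return np.array(
            [np.nanmean(ch) if len(ch) else np.nan for ch in chunks]
        )


def _region_bins(
    track: CoverageTrack,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    flank: int,
    body_bins: int,
    flank_bin_size: int,
) -> np.ndarray | None:
    if end - start < body_bins:
        log.warning("region %s:%d-%d shorter than %d bins; skipped",
                    chrom, start, end, body_bins)
        return None
    vals = track.slice(chrom, start - flank, end + flank)
    if strand == "-":
        vals = vals[::-1]
    up, body, down = vals[:flank], vals[flank: flank + (end - start)], vals[flank + (end - start):]
    n_flank_bins = flank // flank_bin_size if flank else 0
    parts = []
    if n_flank_bins:
        parts.append(_bin_means(up, n_flank_bins))
    parts.append(_bin_means(body, body_bins))
    if n_flank_bins:
        parts.append(_bin_means(down, n_flank_bins))
    return np.concatenate(parts)


def metagene_profile(
    track: CoverageTrack,
    genes,
    flank: int = 2000,
    body_bins: int = 100,
    flank_bin_size: int = 50,
) -> MetaProfile:
    """Average TSS/TES-anchored profile over genes: ``flank`` bp of
    fixed-width bins on each side and a length-scaled body."""
    if flank % flank_bin_size:
        raise ValueError("flank must be a multiple of flank_bin_size")
    mats = []
    for g in genes:
        s, e = g.span
        row = _region_bins(
            track, g.chrom, s, e, g.strand, flank, body_bins, flank_bin_size
        )
        if row is not None:
            mats.append(row)
    if not mats:
        raise ValueError("no usable genes")
    stacked = np.vstack(mats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(stacked, axis=0)
    return MetaProfile(
        values=mean,
        n_regions=len(mats),
        upstream_bins=flank // flank_bin_size,
        body_bins=body_bins,
        downstream_bins=flank // flank_bin_size,
        flank_bin_size=flank_bin_size,
    )


def intron_profile_by_group(
    track: CoverageTrack,
    control: CoverageTrack | None,
    introns,
    group_labels,
    exon_flank: int = 150,
    body_bins: int = 60,
    flank_bin_size: int = 15,
    mode: str = "ratio",
) -> dict[int, MetaProfile]:
    """Intron-anchored profiles per group, normalized bin-wise to a control
    track when one is given.

    Per intron, the signal (and control) is binned into fixed-width exonic
    flank bins plus a length-scaled intron body; the per-bin statistic is
    track/control (``mode="ratio"``) or log2(track/control)
    (``mode="log2"``); bins with zero control are NaN.  Profiles are the
    nanmean over the introns of each group.
    """
    if exon_flank % flank_bin_size:
        raise ValueError("exon_flank must be a multiple of flank_bin_size")
    if mode not in ("ratio", "log2"):
        raise ValueError(f"unknown mode {mode!r}")
    group_labels = np.asarray(group_labels)
    introns = list(introns)
    if len(introns) != len(group_labels):
        raise ValueError("introns and group_labels must align")
    per_group: dict[int, list[np.ndarray]] = {}
    for intr, grp in zip(introns, group_labels):
        sig = _region_bins(
            track, intr.chrom, intr.start, intr.end, intr.strand,
            exon_flank, body_bins, flank_bin_size,
        )
        if sig is None:
            continue
        if control is not None:
            ctl = _region_bins(
                control, intr.chrom, intr.start, intr.end, intr.strand,
                exon_flank, body_bins, flank_bin_size,
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                sig = np.where(ctl > 0, sig / ctl, np.nan)
            if np.isnan(sig).all():
                log.warning("control all-zero around %s; NaN profile",
                            intr.intron_id)
        if mode == "log2":
            with np.errstate(divide="ignore", invalid="ignore"):
                sig = np.where(sig > 0, np.log2(sig), np.nan)
        per_group.setdefault(int(grp), []).append(sig)
    n_flank_bins = exon_flank // flank_bin_size
    out = {}
    for grp, rows in sorted(per_group.items()):
        stacked = np.vstack(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            mean = np.nanmean(stacked, axis=0)
        out[grp] = MetaProfile(
            values=mean,
            n_regions=len(rows),
            upstream_bins=n_flank_bins,
            body_bins=body_bins,
            downstream_bins=n_flank_bins,
            flank_bin_size=flank_bin_size,
        )
    return out
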