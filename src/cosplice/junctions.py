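"""Junction-read classification and counting at constitutive introns.

Each uniquely mapped primary alignment is classified, per intron, as:

* ``EE``  - a spliced read whose gap matches the intron exactly (both splice
  sites), with at least ``min_overhang`` aligned nucleotides in each flanking
  block;
* ``EI5`` - a contiguous aligned block spanning the 5' splice site
  (transcription direction) with ``min_overhang`` nucleotides on both the
  exonic and intronic side;
* ``EI3`` - symmetric at the 3' splice site;
* ``none`` otherwise (including near-miss gaps from alternative splice
  sites, which do not inform retention of the constitutive junction).

A read that contiguously covers the whole intron would satisfy both EI
definitions; it is assigned ``EI5`` (one category per alignment per intron).
Counting is a single streaming pass over the alignment file with an interval
tree over introns, so plain SAM input works without an index.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import ConstitutiveIntron, GeneModel

log = logging.getLogger(__name__)

CATEGORIES = ("ei5", "ei3", "ee")


def merged_blocks(aln: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Aligned reference blocks with zero-length gaps (e.g. around
    insertions/deletions) merged, so only splice gaps (N) separate blocks."""
    blocks: list[list[int]] = []
    pos = aln.reference_start
    for op, ln in aln.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            if blocks and blocks[-1][1] == pos:
                blocks[-1][1] = pos + ln
            else:
                blocks.append([pos, pos + ln])
            pos += ln
        elif op == 2:  # D consumes reference but stays contiguous
            if blocks and blocks[-1][1] == pos:
                blocks[-1][1] = pos + ln
            else:
                blocks.append([pos, pos + ln])
            pos += ln
        elif op == 3:  # N: splice gap
            pos += ln
        # I, S, H, P consume no reference
    return [(s, e) for s, e in blocks]


def classify_blocks(
    blocks: Sequence[tuple[int, int]],
    intron_start: int,
    intron_end: int,
    strand: str,
    min_overhang: int = 3,
) -> str:
    """Classify a block decomposition against one intron. Returns
    ``"ee"``, ``"ei5"``, ``"ei3"`` or ``"none"``."""
    ov = min_overhang
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if e1 == intron_start and s2 == intron_end:
            if (e1 - s1) >= ov and (e2 - s2) >= ov:
                return "ee"
            return "none"
    p5 = intron_start if strand == "+" else intron_end
    p3 = intron_end if strand == "+" else intron_start
    for s, e in blocks:
        if s <= p5 - ov and e >= p5 + ov:
            return "ei5"
    for s, e in blocks:
        if s <= p3 - ov and e >= p3 + ov:
            return "ei3"
    return "none"


def _strand_ok(aln: pysam.AlignedSegment, strand: str, strandedness: str) -> bool:
    if strandedness == "unstranded":
        return True
    rev = aln.is_reverse
    if aln.is_paired and aln.is_read2:
        rev = not rev  # orient mate 2 like mate 1
    if strandedness == "RF":  # dUTP: read 1 antisense to the transcript
        return rev == (strand == "+")
    if strandedness == "FR":
        return rev == (strand == "-")
    raise ValueError(f"unknown strandedness {strandedness!r}")


def classify_alignment(
    aln: pysam.AlignedSegment,
    intron: ConstitutiveIntron,
    min_overhang: int = 3,
    strandedness: str = "RF",
) -> str:
    """Classify one alignment at one intron (``ee``/``ei5``/``ei3``/``none``)."""
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
        return "none"
    if aln.reference_name != intron.chrom:
        return "none"
    if not _strand_ok(aln, intron.strand, strandedness):
        return "none"
    return classify_blocks(
        merged_blocks(aln), intron.start, intron.end, intron.strand, min_overhang
    )


def _intron_trees(
    introns: Sequence[ConstitutiveIntron],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for intr in introns:
        trees.setdefault(intr.chrom, IntervalTree()).addi(
            intr.start, intr.end, intr
        )
    return trees


def _check_chroms(path_refs: Iterable[str], chroms: Iterable[str]) -> None:
    missing = sorted(set(chroms) - set(path_refs))
    if missing:
        raise ValueError(
            "annotation chromosomes absent from alignment header: "
            + ", ".join(missing)
        )


def count_junction_reads(
    path: str,
    introns: Sequence[ConstitutiveIntron],
    min_overhang: int = 3,
    strandedness: str = "RF",
    min_mapq: int = 30,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Count EI5/EI3/EE reads per constitutive intron for one sample.

    Only primary, uniquely mapped alignments (MAPQ >= ``min_mapq``) count.
    For paired-end data, one fragment increments a category at an intron at
    most once even if both mates support it.
    Returns a frame with columns intron_id, sample_id, ei5, ei3, ee
    (all introns present, zero-filled).
    """
    counts: dict[tuple[str, str], int] = {}
    seen_pairs: set[tuple[str, str, str]] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        _check_chroms(fh.references, {i.chrom for i in introns})
        trees = _intron_trees(introns)
        for aln in fh:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or (aln.mapping_quality or 0) < min_mapq
            ):
                continue
            tree = trees.get(aln.reference_name)
            if not tree:
                continue
            hits = tree[aln.reference_start: aln.reference_end]
            if not hits:
                continue
            blocks = merged_blocks(aln)
            for hit in hits:
                intr: ConstitutiveIntron = hit.data
                if not _strand_ok(aln, intr.strand, strandedness):
                    continue
                cat = classify_blocks(
                    blocks, intr.start, intr.end, intr.strand, min_overhang
                )
                if cat == "none":
                    continue
                if aln.is_paired:
                    key = (aln.query_name, intr.intron_id, cat)
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                counts[(intr.intron_id, cat)] = counts.get((intr.intron_id, cat), 0) + 1
    rows = {
        i.intron_id: {c: counts.get((i.intron_id, c), 0) for c in CATEGORIES}
        for i in introns
    }
    df = pd.DataFrame.from_dict(rows, orient="index").reset_index(names="intron_id")
    df.insert(1, "sample_id", sample_id)
    return df


def intron_exon_density_ratio(
    path: str,
    genes: Sequence[GeneModel],
    min_mapq: int = 30,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Per-gene intron/exon read-density ratio.

    A read is assigned to the overlapping gene with the largest aligned
    overlap, then to exonic or intronic space by majority overlap within that
    gene (exons = union across isoforms; introns = gene span minus that
    union).  Densities are reads per bp; the ratio is flagged NaN for
    intronless genes or zero exon density.
    """
    gene_trees: dict[str, IntervalTree] = {}
    exon_unions: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        s, e = g.span
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
        exon_unions[g.gene_id] = g.exon_union

    exon_reads: dict[str, int] = {g.gene_id: 0 for g in genes}
    intron_reads: dict[str, int] = {g.gene_id: 0 for g in genes}

    def _overlap(blocks, ivs) -> int:
        total = 0
        for bs, be in blocks:
            for s, e in ivs:
                lo, hi = max(bs, s), min(be, e)
                if lo < hi:
                    total += hi - lo
        return total

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        _check_chroms(fh.references, {g.chrom for g in genes})
        for aln in fh:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or (aln.mapping_quality or 0) < min_mapq
            ):
                continue
            tree = gene_trees.get(aln.reference_name)
            if not tree:
                continue
            hits = tree[aln.reference_start: aln.reference_end]
            if not hits:
                continue
            blocks = merged_blocks(aln)
            best, best_ov, best_ex = None, -1, 0
            for hit in hits:
                g: GeneModel = hit.data
                span_ov = _overlap(blocks, [g.span])
                if span_ov > best_ov:
                    best, best_ov = g, span_ov
                    best_ex = _overlap(blocks, exon_unions[g.gene_id])
            assert best is not None
            if best_ex >= best_ov - best_ex:
                exon_reads[best.gene_id] += 1
            else:
                intron_reads[best.gene_id] += 1

    recs = []
    for g in genes:
        exon_bp = sum(e - s for s, e in exon_unions[g.gene_id])
        intron_bp = g.gene_length - exon_bp
        ed = exon_reads[g.gene_id] / exon_bp if exon_bp else np.nan
        idn = intron_reads[g.gene_id] / intron_bp if intron_bp else np.nan
        ratio = idn / ed if (intron_bp and exon_bp and ed > 0) else np.nan
        recs.append(
            dict(
                gene_id=g.gene_id,
                sample_id=sample_id,
                exon_reads=exon_reads[g.gene_id],
                intron_reads=intron_reads[g.gene_id],
                exon_bp=exon_bp,
                intron_bp=intron_bp,
                exon_density=ed,
                intron_density=idn,
                ratio=ratio,
            )
        )
    return pd.DataFrame(recs)


def compare_density_ratios(ratios_a: pd.DataFrame, ratios_b: pd.DataFrame) -> dict:
    """Paired two-sided Wilcoxon signed-rank comparison of per-gene
    intron/exon density ratios between two assays (e.g. CB vs polyA)."""
    from scipy import stats

    a = ratios_a.set_index("gene_id")["ratio"]
    b = ratios_b.set_index("gene_id")["ratio"]
    shared = a.index.intersection(b.index)
    x, y = a.loc[shared], b.loc[shared]
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) == 0:
        raise ValueError("no genes with defined ratios in both assays")
    if np.allclose(x, y):
        p = 1.0
    else:
        p = float(stats.wilcoxon(x, y, zero_method="zsplit").pvalue)
    return {
        "n": int(len(x)),
        "median_a": float(np.median(x)),
        "median_b": float(np.median(y)),
        "p_value": p,
    }
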