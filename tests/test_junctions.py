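"""Junction-read classification and counting."""

import numpy as np
import pandas as pd
import pysam
import pytest

import cosplice as cs
from cosplice.junctions import classify_blocks

from conftest import make_gene, write_sam

INTRON = dict(start=200, end=300)


def _intron(strand="+", gene="g1", chrom="chr1"):
    return cs.ConstitutiveIntron(
        intron_id=f"{gene}:200-300", gene_id=gene, chrom=chrom, strand=strand,
        start=200, end=300, dist_to_tes=100, ordinal=1,
    )


@pytest.mark.parametrize(
    "blocks,strand,expected",
    [
        ([(180, 200), (300, 320)], "+", "ee"),  # exact splice gap
        ([(190, 210)], "+", "ei5"),  # spans 5'SS on + strand
        ([(290, 310)], "+", "ei3"),
        ([(190, 210)], "-", "ei3"),  # same block is the 3'SS on - strand
        ([(290, 310)], "-", "ei5"),
        ([(180, 200), (305, 325)], "+", "none"),  # gap off by 5 at the 3'SS
        ([(150, 190)], "+", "none"),  # no boundary contact
        ([(198, 200), (300, 320)], "+", "none"),  # 2 nt overhang < 3
        ([(199, 202)], "+", "none"),  # spans boundary but < overhang inside
        ([(150, 350)], "+", "ei5"),  # covers the whole intron: 5'SS wins
    ],
)
def test_classify_blocks_cases(blocks, strand, expected):
    assert classify_blocks(blocks, 200, 300, strand, min_overhang=3) == expected


def test_categories_mutually_exclusive(rng):
    """An EE call requires an exact gap at the intron, which geometrically
    precludes a block spanning either splice site; fuzzed block layouts
    agree with independent per-category predicates."""
    for _ in range(500):
        n_blocks = int(rng.integers(1, 3))
        blocks, pos = [], int(rng.integers(100, 320))
        for _ in range(n_blocks):
            ln = int(rng.integers(1, 120))
            blocks.append((pos, pos + ln))
            pos += ln + int(rng.integers(1, 150))
        ov = 3
        ee = any(
            e1 == 200 and s2 == 300 and (e1 - s1) >= ov and (e2 - s2) >= ov
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:])
        )
        ei5 = any(s <= 200 - ov and e >= 200 + ov for s, e in blocks)
        ei3 = any(s <= 300 - ov and e >= 300 + ov for s, e in blocks)
        got = classify_blocks(blocks, 200, 300, "+", ov)
        assert not (ee and (ei5 or ei3))  # exclusivity of the definitions
        expected = "ee" if ee else "ei5" if ei5 else "ei3" if ei3 else "none"
        assert got == expected


def _count(path, introns, **kw):
    kw.setdefault("strandedness", "unstranded")
    kw.setdefault("min_mapq", 30)
    return cs.count_junction_reads(path, introns, **kw).set_index("intron_id")


def test_count_empty_sam(tmp_path):
    path = write_sam(tmp_path / "empty.sam", [])
    out = _count(path, [_intron()])
    assert out.loc["g1:200-300", ["ei5", "ei3", "ee"]].tolist() == [0, 0, 0]


def test_count_basic_and_order_invariance(tmp_path):
    rows = [
        ("r1", 0, "chr1", 180, 60, "20M100N20M"),  # ee
        ("r2", 0, "chr1", 190, 60, "20M"),  # ei5
        ("r3", 0, "chr1", 290, 60, "20M"),  # ei3
        ("r4", 0, "chr1", 120, 60, "20M"),  # none
    ]
    p1 = write_sam(tmp_path / "a.sam", rows)
    p2 = write_sam(tmp_path / "b.sam", rows[::-1])
    out1, out2 = _count(p1, [_intron()]), _count(p2, [_intron()])
    assert out1.loc["g1:200-300", ["ei5", "ei3", "ee"]].tolist() == [1, 1, 1]
    pd.testing.assert_frame_equal(out1, out2)


def test_secondary_and_low_mapq_excluded(tmp_path):
    rows = [
        ("r1", 0, "chr1", 180, 60, "20M100N20M"),
        ("r1", 256, "chr1", 180, 60, "20M100N20M"),  # secondary duplicate
        ("r2", 0, "chr1", 180, 5, "20M100N20M"),  # below MAPQ threshold
    ]
    out = _count(write_sam(tmp_path / "s.sam", rows), [_intron()])
    assert out.loc["g1:200-300", "ee"] == 1


def test_strandedness_filter(tmp_path):
    # RF library: reads from a + intron align on the reverse strand
    rows = [
        ("fwd", 0, "chr1", 180, 60, "20M100N20M"),
        ("rev", 16, "chr1", 180, 60, "20M100N20M"),
    ]
    path = write_sam(tmp_path / "st.sam", rows)
    rf = cs.count_junction_reads(path, [_intron("+")], strandedness="RF")
    fr = cs.count_junction_reads(path, [_intron("+")], strandedness="FR")
    un = cs.count_junction_reads(path, [_intron("+")], strandedness="unstranded")
    assert rf["ee"].iloc[0] == 1 and fr["ee"].iloc[0] == 1 and un["ee"].iloc[0] == 2


def test_paired_fragment_counts_once(tmp_path):
    # both mates of one fragment span the same boundary: one increment
    rows = [
        ("frag", 1 | 64, "chr1", 190, 60, "20M"),
        ("frag", 1 | 128 | 16, "chr1", 192, 60, "20M"),
    ]
    out = _count(write_sam(tmp_path / "p.sam", rows), [_intron()])
    assert out.loc["g1:200-300", "ei5"] == 1


def test_chromosome_mismatch_error(tmp_path):
    path = write_sam(tmp_path / "c.sam", [])
    with pytest.raises(ValueError, match="chrX"):
        cs.count_junction_reads(path, [_intron(chrom="chrX")])


def test_counts_match_placement_oracle(tmp_path, rng):
    """Reads tiled over a toy two-intron gene: counts equal a brute-force
    interval-arithmetic enumeration over every read."""
    introns = [
        cs.ConstitutiveIntron("g:100-250", "g", "chr1", "+", 100, 250, 0, 1),
        cs.ConstitutiveIntron("g:350-500", "g", "chr1", "+", 350, 500, 0, 2),
    ]
    rows, expected = [], {i.intron_id: {"ei5": 0, "ei3": 0, "ee": 0} for i in introns}
    for i in range(500):
        start = int(rng.integers(0, 560))
        if rng.random() < 0.3:  # spliced read over one of the introns
            intr = introns[int(rng.integers(0, 2))]
            left = int(rng.integers(1, 30))
            rows.append(
                (f"s{i}", 0, "chr1", intr.start - left, 60,
                 f"{left}M{intr.end - intr.start}N{30 - left}M")
            )
            blocks = [(intr.start - left, intr.start), (intr.end, intr.end + 30 - left)]
        else:
            rows.append((f"c{i}", 0, "chr1", start, 60, "30M"))
            blocks = [(start, start + 30)]
        for intr in introns:
            cat = classify_blocks(blocks, intr.start, intr.end, "+", 3)
            if cat != "none":
                expected[intr.intron_id][cat] += 1
    out = _count(write_sam(tmp_path / "o.sam", rows), introns)
    for intr in introns:
        assert out.loc[intr.intron_id, ["ei5", "ei3", "ee"]].to_dict() == \
            expected[intr.intron_id]


class TestDensityRatio:
    def _gene(self):
        return make_gene("g1", "+", [[(0, 100), (200, 300)]])

    def test_uniform_coverage_ratio_one(self, tmp_path):
        rows = [(f"r{i}", 0, "chr1", p, 60, "10M") for i, p in enumerate(range(0, 290))]
        out = cs.intron_exon_density_ratio(
            write_sam(tmp_path / "u.sam", rows), [self._gene()]
        )
        assert out["ratio"].iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_exon_only_reads_ratio_zero(self, tmp_path):
        rows = [(f"r{i}", 0, "chr1", p, 60, "10M") for i, p in enumerate(range(0, 90, 5))]
        out = cs.intron_exon_density_ratio(
            write_sam(tmp_path / "e.sam", rows), [self._gene()]
        )
        assert out["ratio"].iloc[0] == 0.0

    def test_intronless_gene_flagged(self, tmp_path):
        g = make_gene("g1", "+", [[(0, 300)]])
        rows = [("r0", 0, "chr1", 10, 60, "10M")]
        out = cs.intron_exon_density_ratio(write_sam(tmp_path / "i.sam", rows), [g])
        assert np.isnan(out["ratio"].iloc[0])

    def test_paired_comparison(self, tmp_path):
        g = self._gene()
        rows_a = [(f"r{i}", 0, "chr1", p, 60, "10M") for i, p in enumerate(range(0, 290, 2))]
        rows_b = [(f"r{i}", 0, "chr1", p, 60, "10M") for i, p in enumerate(range(0, 90, 2))]
        a = cs.intron_exon_density_ratio(write_sam(tmp_path / "a.sam", rows_a), [g])
        b = cs.intron_exon_density_ratio(write_sam(tmp_path / "b.sam", rows_b), [g])
        res = cs.compare_density_ratios(a, b)
        assert res["median_a"] > res["median_b"]
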