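"""Gene models, constitutive introns, and stratification covariates.

Parses GTF/GFF3 annotation into gene/transcript/exon models, derives introns
as the exact interval complement of exons, and identifies *constitutive*
introns: introns whose boundaries are identical in every annotated isoform of
the gene and which never overlap an exon of any isoform.  These are the
substrate for percent-intron-retention (PIR) analysis, because exon-exon and
exon-intron junction reads at a constitutive intron are unambiguous.

Coordinate conventions
----------------------
Files (GTF/GFF3) are 1-based inclusive; everything in memory is 0-based
half-open.  Exons are stored in ascending genomic order regardless of strand;
transcription-direction logic (TSS/TES, intron ordinals, distance to TES) is
derived from the strand where needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: exons in ascending genomic order, 0-based half-open."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(
                    f"exons of {self.transcript_id} not sorted/disjoint: "
                    f"({s1},{e1}) vs ({s2},{e2})"
                )
        if self.exons[-1][0] >= self.exons[-1][1]:
            raise ValueError(f"empty exon in {self.transcript_id}")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons (genomic order)."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def tss(self) -> int:
        s, e = self.span
        return s if self.strand == "+" else e

    @property
    def tes(self) -> int:
        s, e = self.span
        return e if self.strand == "+" else s


@dataclass
class GeneModel:
    """A gene and its isoforms; covariates come from the representative
    transcript (the longest; ties broken by smallest transcript_id)."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.strand != self.strand or t.chrom != self.chrom:
                raise ValueError(
                    f"transcript {t.transcript_id} disagrees with gene "
                    f"{self.gene_id} on chrom/strand"
                )

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def gene_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def representative(self) -> TranscriptModel:
        return sorted(self.transcripts, key=lambda t: (-t.length, t.transcript_id))[0]

    @property
    def exon_count(self) -> int:
        return len(self.representative.exons)

    @property
    def exon_union(self) -> list[Interval]:
        """Merged union of exons across all isoforms."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


@dataclass(frozen=True)
class ConstitutiveIntron:
    """An intron with identical boundaries in every isoform of its gene,
    overlapping no exon of any isoform."""

    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    dist_to_tes: int  # 3' end of intron to representative TES, transcription direction
    ordinal: int  # 1 = most 5' in transcription direction

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_lines(path: str) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(f"unparseable record at {path}:{i}: {line.rstrip()!r}")


def load_annotation(path: str, dialect: str | None = None) -> list[GeneModel]:
    """Parse a GTF or GFF3 file into :class:`GeneModel` objects.

    ``dialect`` may be ``"gtf"`` or ``"gff3"``; by default it is inferred from
    the file extension.  Transcripts without exons are skipped with a warning;
    malformed records raise :class:`ValueError` naming the offending line.
    """
    path = str(path)
    if dialect is None:
        low = path.lower()
        dialect = "gff3" if (low.endswith(".gff") or low.endswith(".gff3")) else "gtf"
    _validate_lines(path)
    kwargs = dict(dbfn=":memory:", force=True, keep_order=True,
                  merge_strategy="create_unique")
    try:
        db = gffutils.create_db(path, disable_infer_genes=True,
                                disable_infer_transcripts=True, **kwargs)
        if not any(True for _ in db.features_of_type("gene")):
            # exon-only GTF: let gffutils infer the gene/transcript hierarchy
            db = gffutils.create_db(path, **kwargs)
    except ValueError:
        raise
    except Exception as exc:  # gffutils raises various parse errors
        raise ValueError(f"failed to parse {path}: {exc}") from exc

    tx_types = ("transcript", "mRNA")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        txs: list[TranscriptModel] = []
        for t in db.children(g, level=1):
            if t.featuretype not in tx_types:
                continue
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            )
            if not exons:
                log.warning("transcript %s has no exons; skipped", t.id)
                continue
            txs.append(TranscriptModel(t.id, t.seqid, t.strand, tuple(exons)))
        if not txs:
            log.warning("gene %s has no usable transcripts; skipped", g.id)
            continue
        genes.append(GeneModel(g.id, g.seqid, g.strand, txs))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str) -> None:
    """Serialize gene models back to GTF (1-based inclusive)."""
    with open(str(path), "w") as fh:
        for g in genes:
            gs, ge = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tcosplice\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\tcosplice\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tcosplice\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{tattrs}\n"
                    )


def _overlaps(iv: Interval, others: Iterable[Interval]) -> bool:
    s, e = iv
    return any(s < oe and os_ < e for os_, oe in others)


def extract_constitutive_introns(
    genes: Iterable[GeneModel],
) -> list[ConstitutiveIntron]:
    """Introns present with identical boundaries in every isoform of a gene
    and overlapping no exon of any isoform.

    Single-transcript genes contribute all their introns.  Ordinals count
    from the 5' end in transcription direction; ``dist_to_tes`` is measured
    from the intron's 3' end to the representative transcript's TES along the
    direction of transcription.
    """
    out: list[ConstitutiveIntron] = []
    for g in genes:
        common = set(g.transcripts[0].introns)
        for t in g.transcripts[1:]:
            common &= set(t.introns)
        all_exons = [iv for t in g.transcripts for iv in t.exons]
        keep = [iv for iv in common if not _overlaps(iv, all_exons)]
        keep.sort(key=lambda iv: iv[0], reverse=(g.strand == "-"))
        rep = g.representative
        for ordinal, (s, e) in enumerate(keep, 1):
            if g.strand == "+":
                dist = rep.span[1] - e
            else:
                dist = s - rep.span[0]
            out.append(
                ConstitutiveIntron(
                    intron_id=f"{g.gene_id}:{s}-{e}",
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    strand=g.strand,
                    start=s,
                    end=e,
                    dist_to_tes=int(dist),
                    ordinal=ordinal,
                )
            )
    return out


def introns_to_frame(introns: Sequence[ConstitutiveIntron]) -> pd.DataFrame:
    """Tabulate constitutive introns (TSV-ready)."""
    return pd.DataFrame(
        {
            "intron_id": [i.intron_id for i in introns],
            "gene_id": [i.gene_id for i in introns],
            "chrom": [i.chrom for i in introns],
            "start": [i.start for i in introns],
            "end": [i.end for i in introns],
            "strand": [i.strand for i in introns],
            "length": [i.length for i in introns],
            "dist_to_tes": [i.dist_to_tes for i in introns],
            "ordinal": [i.ordinal for i in introns],
        }
    )


def assign_quantile_groups(values, k: int = 5) -> np.ndarray:
    """Label each value with its empirical-quantile group 1..k.

    Group boundaries are the i/k quantiles; values equal to a boundary go to
    the lower group.  Raises if fewer than ``k`` distinct values exist.
    """
    v = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be finite and non-empty")
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values, got {np.unique(v).size}")
    cuts = np.quantile(v, np.arange(1, k) / k)
    return (1 + (v[:, None] > cuts[None, :]).sum(axis=1)).astype(int)
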