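"""Synthetic genomes, truth tables, and nascent/mature RNA-seq reads.

The generator emulates the data-generating assumptions behind paired
chromatin-bound (nascent) and polyA (mature) RNA-seq of a plant-like genome:

* per-intron *cotranscriptional* retention probabilities, either constant or
  logistic in a covariate (intron length or distance to the transcription end
  site);
* posttranscriptional completion of splicing: in mature RNA an intron's
  retention is its nascent retention times (1 - completion probability);
* 5'->3' exponential decay of nascent read density (rate per kb), mimicking
  the prevalence of incomplete transcripts near the TSS;
* per-gene stability factors linking mature to nascent abundance (lognormal,
  with optional planted stable/unstable subpopulations);
* tissue effects as transcription-level log2 fold changes shared by both
  assays; and
* replicate-level multiplicative count noise.

Reads are single-end, error-free and fixed-length (base quality plays no
role downstream), always MAPQ 60 ("uniquely mapped"), oriented per the
configured library type (default RF/dUTP).  Every emitted read is logged in
a placement ledger with its EE/EI5/EI3 status per constitutive intron,
derived from molecule-coordinate arithmetic, independent of the alignment
classifier it serves as an oracle for.  Splicing decisions are independent
across the introns of a molecule.

Besides the SAM-level simulator, counts-level generators are provided for
analyses that are defined directly on junction counts, PSI replicates, or
TPM tables; they embody the same assumptions without the read layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    ConstitutiveIntron,
    GeneModel,
    TranscriptModel,
    extract_constitutive_introns,
    introns_to_frame,
    write_gtf,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults describe a soybean-like toy genome
    (intron lengths centred a few hundred bp, genes of a few kb) sequenced
    with a stranded dUTP (RF) single-end library."""

    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (200, 600)
    intergenic_gap: tuple[int, int] = (400, 900)
    chrom_name: str = "chr1"
    # nascent retention model
    retention_model: str = "constant"  # "constant" | "logistic"
    retention: float = 0.3
    retention_covariate: str = "intron_length"  # or "dist_to_tes"
    retention_range: tuple[float, float] = (0.05, 0.8)
    retention_logistic_mid: float | None = None  # default: median covariate
    retention_logistic_scale: float | None = None  # default: std/2
    completion_prob: float = 0.7  # posttranscriptional completion of splicing
    decay_per_kb: float = 0.5  # nascent 5'->3' coverage decay rate
    # per-gene truth
    abundance_sigma: float = 0.8  # lognormal spread of transcription rates
    stability_sigma: float = 0.4  # lognormal spread of stability factors
    n_stable: int = 0  # planted high-stability genes
    n_unstable: int = 0
    stability_multiplier: float = 8.0
    tissue_lfc_sigma: float = 1.0  # transcription-level condition effect (log2)
    # library
    read_length: int = 80
    library: str = "RF"  # RF | FR | unstranded
    as_exemplars: bool = True  # give the first genes a second isoform per AS type
    alt_isoform_weight: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.retention, self.completion_prob, *self.retention_range):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.exon_length[0] < 2 * self.read_length // 2 + 4:
            pass  # exons may be short; reads just never span two junctions then
        if self.intron_length[0] <= 4:
            raise ValueError("introns must be longer than 4 bp")


@dataclass
class Simulation:
    """A generated genome plus all truth needed for parameter recovery."""

    config: SimulationConfig
    genes: list[GeneModel]
    sequences: dict[str, np.ndarray]  # chrom -> byte array of bases
    introns: list[ConstitutiveIntron]
    intron_truth: pd.DataFrame  # per constitutive intron: true retentions
    gene_truth: pd.DataFrame  # per gene: abundance, stability, labels, lfc
    isoform_weights: dict[str, dict[str, float]]
    retention_by_gene: dict[str, dict[tuple[int, int], float]] = field(
        default_factory=dict
    )

    def write_fasta(self, path: str) -> None:
        with open(str(path), "w") as fh:
            for chrom, arr in self.sequences.items():
                fh.write(f">{chrom}\n")
                seq = arr.tobytes().decode()
                for i in range(0, len(seq), 80):
                    fh.write(seq[i: i + 80] + "\n")

    def write_gtf(self, path: str) -> None:
        write_gtf(self.genes, path)


def _logistic_retention(cov: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.retention_range
    mid = cfg.retention_logistic_mid
    scale = cfg.retention_logistic_scale
    if mid is None:
        mid = float(np.median(cov))
    if scale is None:
        scale = float(np.std(cov)) / 2 or 1.0
    return lo + (hi - lo) / (1.0 + np.exp(-(cov - mid) / scale))


def generate_genome(config: SimulationConfig, seed: int) -> Simulation:
    """Build a random genome/annotation plus the truth skeleton.

    Genes are laid on both strands of one chromosome with the configured
    exon/intron structure.  When ``as_exemplars`` is on, the first four
    multi-exon genes carry a second isoform instantiating ES, RI, A5SS and
    A3SS respectively.  Deterministic for a given (config, seed).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    genes: list[GeneModel] = []
    cursor = 2500
    as_types = ["ES", "RI", "A5SS", "A3SS"] if cfg.as_exemplars else []
    iso_weights: dict[str, dict[str, float]] = {}

    for i in range(cfg.n_genes):
        gene_id = f"G{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        want_as = as_types[i] if i < len(as_types) else None
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        if want_as:
            n_ex = max(n_ex, 3)
        ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, max(n_ex - 1, 0)
        )
        exons = []
        pos = cursor
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += int(in_lens[j])
        txs = [TranscriptModel(f"{gene_id}.1", cfg.chrom_name, strand, tuple(exons))]
        weights = {f"{gene_id}.1": 1.0}
        if want_as and n_ex >= 3:
            alt = _alt_isoform(exons, want_as, strand)
            if alt is not None:
                txs.append(
                    TranscriptModel(f"{gene_id}.2", cfg.chrom_name, strand, alt)
                )
                weights = {
                    f"{gene_id}.1": 1.0 - cfg.alt_isoform_weight,
                    f"{gene_id}.2": cfg.alt_isoform_weight,
                }
        iso_weights[gene_id] = weights
        genes.append(GeneModel(gene_id, cfg.chrom_name, strand, txs))
        cursor = pos + int(
            rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1)
        )

    chrom_len = cursor + 2500
    seq = rng.choice(BASES, size=chrom_len)
    for g in genes:
        for t in g.transcripts:
            for s, e in t.introns:
                if g.strand == "+":
                    seq[s: s + 2] = [b"G", b"T"]
                    seq[e - 2: e] = [b"A", b"G"]
                else:
                    seq[s: s + 2] = [b"C", b"T"]
                    seq[e - 2: e] = [b"A", b"C"]

    introns = extract_constitutive_introns(genes)
    itab = introns_to_frame(introns)
    if cfg.retention_model == "constant":
        nascent = np.full(len(itab), cfg.retention)
    elif cfg.retention_model == "logistic":
        cov = itab[cfg.retention_covariate].to_numpy(dtype=float)
        nascent = _logistic_retention(cov, cfg)
    else:
        raise ValueError(f"unknown retention model {cfg.retention_model!r}")
    itab["retention_nascent"] = nascent
    itab["retention_mature"] = nascent * (1.0 - cfg.completion_prob)

    # retention for every distinct intron of every isoform (alt introns get
    # the same model, keyed by interval) so reads can be drawn from any tx
    retention_by_gene: dict[str, dict[tuple[int, int], float]] = {}
    const_lookup = {
        (r.gene_id, r.start, r.end): r.retention_nascent for r in itab.itertuples()
    }
    for g in genes:
        table: dict[tuple[int, int], float] = {}
        for t in g.transcripts:
            for s, e in t.introns:
                key = (g.gene_id, s, e)
                if key in const_lookup:
                    table[(s, e)] = const_lookup[key]
                elif cfg.retention_model == "constant":
                    table[(s, e)] = cfg.retention
                else:
                    cov = float(e - s) if cfg.retention_covariate == "intron_length" \
                        else float(abs((g.span[1] if g.strand == "+" else g.span[0]) - (e if g.strand == "+" else s)))
                    table[(s, e)] = float(
                        _logistic_retention(np.array([cov]), cfg)[0]
                    )
        retention_by_gene[g.gene_id] = table

    n = len(genes)
    abundance = rng.lognormal(mean=2.0, sigma=cfg.abundance_sigma, size=n)
    stability = rng.lognormal(mean=0.0, sigma=cfg.stability_sigma, size=n)
    labels = np.array(["concordant"] * n, dtype=object)
    planted = rng.permutation(n)
    stable_idx = planted[: cfg.n_stable]
    unstable_idx = planted[cfg.n_stable: cfg.n_stable + cfg.n_unstable]
    stability[stable_idx] *= cfg.stability_multiplier
    stability[unstable_idx] /= cfg.stability_multiplier
    labels[stable_idx] = "stable"
    labels[unstable_idx] = "unstable"
    lfc = rng.normal(0.0, cfg.tissue_lfc_sigma, size=n)
    gtab = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "abundance": abundance,
            "stability_factor": stability,
            "stability_label": labels,
            "tissue_lfc": lfc,
            "decay_per_kb": cfg.decay_per_kb,
        }
    )
    return Simulation(
        config=cfg,
        genes=genes,
        sequences={cfg.chrom_name: seq},
        introns=introns,
        intron_truth=itab,
        gene_truth=gtab,
        isoform_weights=iso_weights,
        retention_by_gene=retention_by_gene,
    )


def _alt_isoform(exons, etype: str, strand: str):
    """Second isoform implementing one AS type against the primary exons."""
    exons = list(exons)
    if etype == "ES":
        return tuple(exons[:1] + exons[2:]) if len(exons) >= 3 else None
    if etype == "RI":  # retain intron 1: merge exons 1 and 2
        merged = (exons[0][0], exons[1][1])
        return tuple([merged] + exons[2:])
    intron_len = exons[1][0] - exons[0][1]
    delta = min(40, intron_len - 20)
    if delta <= 0:
        return None
    if etype == "A5SS":
        # move the boundary inside intron 1 nearest the first exon
        if strand == "+":
            first = (exons[0][0], exons[0][1] + delta)
            return tuple([first] + exons[1:])
        second = (exons[1][0] - delta, exons[1][1])
        return tuple(exons[:1] + [second] + exons[2:])
    if etype == "A3SS":
        if strand == "+":
            second = (exons[1][0] - delta, exons[1][1])
            return tuple(exons[:1] + [second] + exons[2:])
        first = (exons[0][0], exons[0][1] + delta)
        return tuple([first] + exons[1:])
    raise ValueError(f"unknown AS type {etype}")


# ---------------------------------------------------------------------------
# read simulation


def _molecule(tx: TranscriptModel, retained: np.ndarray) -> list[tuple[int, int]]:
    """Genomic blocks of one RNA molecule in transcription order, merging
    retained introns into their neighbours."""
    exons = list(tx.exons)
    introns = list(tx.introns)
    blocks: list[list[int]] = [list(exons[0])]
    for j, intr in enumerate(introns):
        if retained[j]:
            blocks[-1][1] = exons[j + 1][1]  # bridge intron + next exon
        else:
            blocks.append(list(exons[j + 1]))
    out = [(s, e) for s, e in blocks]
    if tx.strand == "-":
        out = out[::-1]
    return out


def _truncated_exp_start(rng, lam_per_base: float, max_start: int) -> int:
    """Start offset in molecule coordinates, exponential with rate
    ``lam_per_base`` truncated to [0, max_start]."""
    if lam_per_base <= 0:
        return int(rng.integers(0, max_start + 1))
    u = rng.random()
    z = 1.0 - math.exp(-lam_per_base * (max_start + 1))
    x = -math.log(1.0 - u * z) / lam_per_base
    return min(int(x), max_start)


def _start_mass(lam_per_base: float, mol_len: int, read_len: int) -> float:
    """Total (unnormalized) read-start weight of a molecule: the number of
    admissible start positions, exponentially tilted under 5'->3' decay.
    Sampling molecules proportional to this mass makes every (molecule,
    start) pair carry its physical weight, as in real sequencing where a
    longer molecule yields proportionally more fragments."""
    n = mol_len - read_len + 1
    if n <= 0:
        return 0.0
    if lam_per_base <= 0:
        return float(n)
    return (1.0 - math.exp(-lam_per_base * n)) / (1.0 - math.exp(-lam_per_base))


def _ledger_categories(
    tx: TranscriptModel,
    retained: np.ndarray,
    start_m: int,
    read_len: int,
    min_overhang: int,
) -> dict[tuple[int, int], str]:
    """Per-intron category of a read, by molecule-coordinate arithmetic.

    Walking the molecule 5'->3', each spliced intron is a junction point and
    each retained intron contributes two boundary points; a read informs the
    intron when it covers the point with ``min_overhang`` nt on both sides.
    This is the simulator's own bookkeeping, independent of the CIGAR-based
    classifier it validates.
    """
    ov = min_overhang
    end_m = start_m + read_len
    cats: dict[tuple[int, int], str] = {}
    exons = list(tx.exons)
    introns = list(tx.introns)
    order = range(len(introns)) if tx.strand == "+" else range(len(introns) - 1, -1, -1)
    pos = 0  # molecule coordinate of the current 5' (transcription) end
    # exon lengths in transcription order
    ex_order = exons if tx.strand == "+" else exons[::-1]
    in_order = [introns[j] for j in order]
    ret_order = [bool(retained[j]) for j in order]
    for idx, intr in enumerate(in_order):
        pos += ex_order[idx][1] - ex_order[idx][0]
        if ret_order[idx]:
            b5 = pos  # 5' splice site in molecule coordinates
            b3 = pos + (intr[1] - intr[0])
            if start_m <= b5 - ov and end_m >= b5 + ov:
                cats[intr] = "ei5"
            elif start_m <= b3 - ov and end_m >= b3 + ov:
                cats[intr] = "ei3"
            pos = b3
        else:
            if start_m <= pos - ov and end_m >= pos + ov:
                cats[intr] = "ee"
    return cats


def simulate_reads(
    sim: Simulation,
    assay: str,
    depth: int,
    seed: int,
    out_sam: str,
    condition: str = "A",
    replicate_sigma: float = 0.0,
    sample_id: str | None = None,
    ledger_min_overhang: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ``depth`` single-end reads for one sample and write a
    coordinate-sorted SAM plus a placement ledger.

    ``assay`` is ``"nascent"`` (chromatin-bound: co-transcriptional
    retention, 5'->3' exponential start-position decay) or ``"mature"``
    (polyA: retention reduced by the completion probability, abundance scaled
    by the per-gene stability factor, uniform starts).  Condition ``"B"``
    applies the transcription-level tissue log2 fold change to both assays.

    Returns ``(ledger, reads)``: the ledger has one row per (read,
    constitutive intron) with the read's EE/EI5/EI3 category; ``reads`` has
    one row per emitted read (read_id, gene_id, transcript_id).
    """
    if assay not in ("nascent", "mature"):
        raise ValueError(f"unknown assay {assay!r}")
    cfg = sim.config
    rng = np.random.default_rng(seed)
    sample_id = sample_id or f"{assay}_{condition}"
    rl = cfg.read_length

    gt = sim.gene_truth
    weights = gt["abundance"].to_numpy().copy()
    if condition == "B":
        weights = weights * 2.0 ** gt["tissue_lfc"].to_numpy()
    if assay == "mature":
        weights = weights * gt["stability_factor"].to_numpy()
    if replicate_sigma > 0:
        weights = weights * rng.lognormal(0.0, replicate_sigma, len(weights))
    # molar abundance times (approximate) molecule length: longer molecules
    # yield proportionally more reads
    lens = np.array([g.representative.length for g in sim.genes], dtype=float)
    p = weights * lens
    p /= p.sum()

    const_ids = {
        (r.gene_id, r.start, r.end): r.intron_id
        for r in sim.intron_truth.itertuples()
    }
    lam = cfg.decay_per_kb / 1000.0 if assay == "nascent" else 0.0

    gene_idx = rng.choice(len(sim.genes), size=depth, p=p)
    records = []  # (chrom, pos, qname, flag, cigar, seq)
    ledger_rows = []
    read_rows = []
    chrom_seq = {c: a for c, a in sim.sequences.items()}

    # maximal molecule length per transcript (all introns retained), for the
    # molecule-mass rejection step below
    max_mol_len = {
        t.transcript_id: t.length
        for g in sim.genes
        for t in g.transcripts
    }

    for i in range(depth):
        g = sim.genes[int(gene_idx[i])]
        wmap = sim.isoform_weights[g.gene_id]
        tx_ids = list(wmap)
        if len(tx_ids) == 1:
            tx_id = tx_ids[0]
        else:
            probs = np.array([wmap[t] for t in tx_ids])
            tx_id = tx_ids[int(rng.choice(len(tx_ids), p=probs / probs.sum()))]
        tx = next(t for t in g.transcripts if t.transcript_id == tx_id)
        introns = tx.introns
        ret_p = np.array(
            [sim.retention_by_gene[g.gene_id][iv] for iv in introns], dtype=float
        )
        if assay == "mature":
            ret_p = ret_p * (1.0 - cfg.completion_prob)
        # rejection-sample the splice realization proportional to its read
        # start mass, so retained (longer) molecules yield proportionally
        # more reads, as in real libraries; without this, per-molecule
        # normalization would bias PIR downward
        z_max = _start_mass(lam, max_mol_len[tx.transcript_id], rl)
        if z_max <= 0:
            continue  # transcript shorter than the read length
        for _attempt in range(200):
            retained = (
                rng.random(len(introns)) < ret_p
                if len(introns)
                else np.array([], bool)
            )
            blocks = _molecule(tx, retained)
            mol_len = sum(e - s for s, e in blocks)
            z = _start_mass(lam, mol_len, rl)
            if z > 0 and rng.random() < z / z_max:
                break
        else:
            continue
        start_m = _truncated_exp_start(rng, lam, mol_len - rl)

        # molecule interval -> genomic sub-blocks
        sub: list[tuple[int, int]] = []
        off = 0
        need_lo, need_hi = start_m, start_m + rl
        for bs, be in blocks:
            blen = be - bs
            lo = max(need_lo - off, 0)
            hi = min(need_hi - off, blen)
            if lo < hi:
                if tx.strand == "+":
                    sub.append((bs + lo, bs + hi))
                else:
                    sub.append((be - hi, be - lo))
            off += blen
        sub.sort()
        cigar_parts = []
        for k, (s, e) in enumerate(sub):
            if k:
                gap = s - sub[k - 1][1]
                cigar_parts.append(f"{gap}N")
            cigar_parts.append(f"{e - s}M")
        cigar = "".join(cigar_parts)
        if cfg.library == "RF":
            flag = 16 if g.strand == "+" else 0
        elif cfg.library == "FR":
            flag = 0 if g.strand == "+" else 16
        else:
            flag = 16 if rng.random() < 0.5 else 0
        seq = b"".join(
            chrom_seq[g.chrom][s:e].tobytes() for s, e in sub
        ).decode()
        qname = f"{sample_id}:{i:08d}"
        records.append((g.chrom, sub[0][0], qname, flag, cigar, seq))
        read_rows.append((qname, g.gene_id, tx.transcript_id))

        cats = _ledger_categories(tx, retained, start_m, rl, ledger_min_overhang)
        for iv, cat in cats.items():
            key = (g.gene_id, iv[0], iv[1])
            if key in const_ids:  # only constitutive introns are counted
                ledger_rows.append((qname, const_ids[key], cat, g.gene_id))

    records.sort(key=lambda r: (r[0], r[1]))
    with open(str(out_sam), "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, arr in sim.sequences.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(arr)}\n")
        for chrom, pos, qname, flag, cigar, seq in records:
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{'I' * len(seq)}\n"
            )
    ledger = pd.DataFrame(
        ledger_rows, columns=["read_id", "intron_id", "category", "gene_id"]
    )
    reads = pd.DataFrame(read_rows, columns=["read_id", "gene_id", "transcript_id"])
    return ledger, reads


def ledger_counts(ledger: pd.DataFrame, introns, sample_id: str = "sample") -> pd.DataFrame:
    """Collapse a placement ledger to per-intron EI5/EI3/EE counts, with the
    same shape as :func:`cosplice.junctions.count_junction_reads` output."""
    ids = [i.intron_id for i in introns]
    table = pd.DataFrame(0, index=pd.Index(ids, name="intron_id"),
                         columns=["ei5", "ei3", "ee"])
    if len(ledger):
        piv = ledger.groupby(["intron_id", "category"]).size().unstack(fill_value=0)
        for col in ("ei5", "ei3", "ee"):
            if col in piv:
                table.loc[piv.index, col] = piv[col]
    out = table.reset_index()
    out.insert(1, "sample_id", sample_id)
    return out


def emit_truth_tables(sim: Simulation, outdir: str | None = None) -> dict[str, pd.DataFrame]:
    """Per-intron and per-gene truth tables (written as TSVs when ``outdir``
    is given); read-level ledgers are returned by :func:`simulate_reads`."""
    tables = {"introns": sim.intron_truth.copy(), "genes": sim.gene_truth.copy()}
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(os.path.join(outdir, f"truth_{name}.tsv"), sep="\t", index=False)
    return tables


# ---------------------------------------------------------------------------
# counts-level generators


def simulate_junction_counts(
    retention: np.ndarray,
    n_informative: int | np.ndarray,
    seed: int,
    intron_ids=None,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Junction counts straight from the retention model: with ``n``
    boundary-informative molecules per splice site, EI5 and EI3 are
    independent Binomial(n, r) draws (each retained molecule can be seen at
    either boundary) and EE is Binomial(n, 1 - r)."""
    rng = np.random.default_rng(seed)
    r = np.asarray(retention, dtype=float)
    n = np.broadcast_to(np.asarray(n_informative), r.shape)
    ei5 = rng.binomial(n, r)
    ei3 = rng.binomial(n, r)
    ee = rng.binomial(n, 1.0 - r)
    ids = intron_ids if intron_ids is not None else [f"I{i:05d}" for i in range(len(r))]
    return pd.DataFrame(
        {"intron_id": ids, "sample_id": sample_id, "ei5": ei5, "ei3": ei3, "ee": ee}
    )


def simulate_psi_replicates(
    true_psi: np.ndarray,
    n_replicates: int,
    noise_sd: float,
    seed: int,
    event_ids=None,
) -> pd.DataFrame:
    """Replicate PSI tables: truth plus clipped Gaussian replicate noise."""
    rng = np.random.default_rng(seed)
    psi = np.asarray(true_psi, dtype=float)
    mat = np.clip(
        psi[:, None] + rng.normal(0.0, noise_sd, (len(psi), n_replicates)), 0.0, 1.0
    )
    ids = event_ids if event_ids is not None else [f"E{i:05d}" for i in range(len(psi))]
    return pd.DataFrame(
        mat, index=pd.Index(ids, name="event_id"),
        columns=[f"rep{j + 1}" for j in range(n_replicates)],
    )


def simulate_stability_tpm(
    n_concordant: int,
    n_stable: int,
    n_unstable: int,
    seed: int,
    multiplier: float = 8.0,
    noise_sd: float = 0.3,
    slope: float = 1.0,
    intercept: float = 0.0,
    cb_log2_range: tuple[float, float] = (1.0, 10.0),
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Paired CB/polyA TPM vectors with planted stable/unstable genes.

    polyA TPM follows ``2**(intercept + slope*log2(cb))`` times lognormal
    noise (sd ``noise_sd`` in natural log), times ``multiplier`` for planted
    stable genes and 1/``multiplier`` for planted unstable ones.  Returns
    (tpm_cb, tpm_polya, true labels).
    """
    rng = np.random.default_rng(seed)
    n = n_concordant + n_stable + n_unstable
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    cb = 2.0 ** rng.uniform(*cb_log2_range, n)
    mult = np.ones(n)
    labels = np.array(["concordant"] * n, dtype=object)
    mult[n_concordant: n_concordant + n_stable] = multiplier
    labels[n_concordant: n_concordant + n_stable] = "stable"
    mult[n_concordant + n_stable:] = 1.0 / multiplier
    labels[n_concordant + n_stable:] = "unstable"
    polya = (
        2.0 ** (intercept + slope * np.log2(cb))
        * mult
        * np.exp(rng.normal(0.0, noise_sd, n))
    )
    return pd.Series(cb, genes), pd.Series(polya, genes), pd.Series(labels, genes)


def simulate_foldchange_tpm(
    n_genes: int,
    seed: int,
    lfc_sigma: float = 1.0,
    stability_sigma: float = 0.4,
    replicate_sigma: float = 0.15,
    n_replicates: int = 3,
) -> dict[str, pd.DataFrame]:
    """Replicate TPM tables for two conditions in two assays where the
    tissue effect acts at transcription only: mature abundance is nascent
    times a per-gene stability factor shared by the conditions.  Returns
    keys cb_1, cb_2, polya_1, polya_2."""
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    base = rng.lognormal(3.0, 1.0, n_genes)
    lfc = rng.normal(0.0, lfc_sigma, n_genes)
    stability = rng.lognormal(0.0, stability_sigma, n_genes)
    cond = {"1": base, "2": base * 2.0 ** lfc}
    out: dict[str, pd.DataFrame] = {}
    for assay, factor in (("cb", np.ones(n_genes)), ("polya", stability)):
        for cname, mean in cond.items():
            reps = {
                f"rep{j + 1}": mean * factor * rng.lognormal(0.0, replicate_sigma, n_genes)
                for j in range(n_replicates)
            }
            out[f"{assay}_{cname}"] = pd.DataFrame(reps, index=genes)
    return out
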