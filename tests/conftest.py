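"""Shared fixtures: toy annotations, SAM writers, and one session-scoped
simulated dataset reused by the read-level tests."""

from __future__ import annotations

import numpy as np
import pytest

import cosplice as cs


def write_sam(path, rows, chroms=(("chr1", 100000),)):
    """Write a minimal SAM file.  ``rows`` are tuples
    (qname, flag, chrom, pos0, mapq, cigar) with 0-based positions."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, ln in chroms:
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for qname, flag, chrom, pos0, mapq, cigar in rows:
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}"
                f"\t*\t0\t0\t*\t*\n"
            )
    return str(path)


def make_gene(gene_id, strand, exon_sets, chrom="chr1"):
    """Gene from per-transcript exon interval lists (0-based half-open)."""
    txs = [
        cs.TranscriptModel(f"{gene_id}.{i + 1}", chrom, strand, tuple(sorted(exons)))
        for i, exons in enumerate(exon_sets)
    ]
    return cs.GeneModel(gene_id, chrom, strand, txs)


@pytest.fixture(scope="session")
def sam_sim(tmp_path_factory):
    """One simulated genome with nascent + mature reads and their ledgers."""
    out = tmp_path_factory.mktemp("sim")
    cfg = cs.SimulationConfig(n_genes=20)
    sim = cs.generate_genome(cfg, seed=42)
    sim.write_gtf(out / "annotation.gtf")
    sim.write_fasta(out / "genome.fa")
    nascent_sam = str(out / "nascent.sam")
    mature_sam = str(out / "mature.sam")
    led_n, reads_n = cs.simulate_reads(sim, "nascent", 30000, seed=43, out_sam=nascent_sam)
    led_m, reads_m = cs.simulate_reads(sim, "mature", 30000, seed=44, out_sam=mature_sam)
    return dict(
        dir=out,
        sim=sim,
        nascent_sam=nascent_sam,
        mature_sam=mature_sam,
        ledger_nascent=led_n,
        ledger_mature=led_m,
        reads_nascent=reads_n,
        reads_mature=reads_m,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
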