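"""Metagene coverage profiles of nascent vs mature reads.

Nascent RNA-seq coverage decays from the 5' to the 3' end of gene bodies
(incomplete transcripts accumulate near the TSS); mature RNA coverage is
flat.  Profiles are anchored at TSS/TES with 2-kb flanks and a length-scaled
body.
"""

import tempfile
from pathlib import Path

import numpy as np

import cosplice as cs

cfg = cs.SimulationConfig(
    n_genes=20, exons_per_gene=(1, 1), exon_length=(10000, 10000),
    read_length=30, decay_per_kb=0.3, as_exemplars=False,
)
sim = cs.generate_genome(cfg, seed=41)
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    profiles = {}
    for assay in ("nascent", "mature"):
        sam = str(tmp / f"{assay}.sam")
        cs.simulate_reads(sim, assay, depth=100000, seed=42, out_sam=sam)
        track = cs.CoverageTrack.from_sam(sam)
        profiles[assay] = cs.metagene_profile(
            track, sim.genes, flank=2000, body_bins=10, flank_bin_size=100
        )

for assay, prof in profiles.items():
    body = prof.body / prof.body.max()
    bars = " ".join(f"{v:.2f}" for v in body)
    print(f"{assay:8s} body (TSS->TES, max-normalized): {bars}")
print("The nascent profile falls monotonically along the body "
      f"(5'->3' decay rate {cfg.decay_per_kb}/kb); the mature profile "
      "stays near 1.0 throughout.")
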