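#!/usr/bin/env python
"""Generate the synthetic study genome, annotation, mask and callset.

Study conditions: 50 protein-coding genes (~140 kbp), plant-like GC 0.36,
G4 motifs planted on the coding strand across all seven structural-region
labels, background SNP density 0.01/bp with a 2.0-fold elevation inside
pG4s, transition-biased substitution spectrum.  Outputs go to
results/synthetic/ and downstream drivers read them from there.
"""
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))
from _shared import SEED, SYNTH  # noqa: E402

from pg4var.synthetic_data import (SimConfig, simulate_genome,
                                   simulate_variants, write_bundle)


def main():
    cfg = SimConfig(n_genes=50, seed=SEED)
    bundle = simulate_genome(cfg)
    variants = simulate_variants(bundle.fasta, bundle.truth, cfg)
    paths = write_bundle(bundle, SYNTH, variants)
    n = len(bundle.fasta["chr1"])
    print(f"genome: {n:,} bp, {len(bundle.truth.genes)} genes")
    print(f"planted motifs: {len(bundle.truth.planted)} "
          f"({len(bundle.truth.pg4_intervals)} detector-delimited pG4 intervals)")
    print(f"variants: {len(variants)} "
          f"(background {cfg.snp_density_background}/bp, fold {cfg.pg4_density_fold} in pG4s)")
    for key, path in paths.items():
        print(f"  {key}: {os.path.relpath(path)}")


if __name__ == "__main__":
    main()
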