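# pg4var

Sequence variability of predicted pre-mRNA G-quadruplexes (pG4s).

G-quadruplexes are four-stranded nucleic-acid structures that can fold in
G-rich RNA; in pre-mRNA they can modulate translation, splicing and
polyadenylation, and they are also associated with genomic instability.
`pg4var` asks, for the G-rich intervals of protein-coding genes that could
fold after transcription: where do they sit within gene architecture, do
they accumulate more or fewer SNPs than their host regions, and do the
substitutions that occur tend to destabilize the predicted structure?

The package implements the full analysis as a tested library plus numbered
analysis drivers:

1. **Detection** — a G4Hunter implementation: every G in a run of *n*
   consecutive Gs scores +min(*n*, 4), every C scores −min(*n*, 4), other
   bases 0; a window's G4Hscore is its mean base score, bounded by ±4.
   Three sliding-window passes (ws, t) = (20, 1.7), (30, 1.4), (25, 1.6)
   are unioned, merged at distance 0, and each merged interval is rescored:

   `G4Hscore(i..j) = (1 / (j − i)) · Σ s(k)` for base scores `s(k)` computed
   with full-sequence run context. Both strands are scanned; masked
   (lowercase/N) bases score 0.
2. **Annotation** — representative transcript per gene (longest CDS),
   merged catalogs for 5′UTR, 3′UTR, intron, CDS and the ±30 bp windows
   around 5′UTR/CDS, CDS/3′UTR and exon–intron junctions; a pG4 is assigned
   to every label that fully contains it, on the coding strand only.
3. **Enrichment** — per-label density (pG4/kbp of merged length) against a
   null of 300 length-preserving uniform re-placements within gene bodies;
   fold enrichment FE = observed / mean(null), with an add-one-corrected
   two-sided empirical p.
4. **Variability** — SNP sites per bp inside pG4s vs their host regions
   (2×2 Pearson χ²), 90-position SNP landscapes (30 bp flanks around a
   body linearly resampled to 30 points), per-pG4 two-sided Fisher
   classification into variable/conserved/ns, and an OLS regression of the
   density ratio on fold enrichment.
5. **ΔG4Hscore** — per region, the 12 background substitution
   probabilities P(alt | ref) estimated from the callset; theoretical
   distributions of the signed score change Δ = G4Hscore(mutated) −
   G4Hscore(reference) over all positions (weights = background
   probabilities) or over variant-carrying positions only; Wilcoxon
   rank-sum comparison against the observed Δ of the callset's
   substitutions.

A synthetic-data module generates genomes, GFF3 annotations, soft-masks and
site-level VCFs with known ground truth (planted G4 motifs, configurable
background SNP density, within-pG4 density fold and substitution spectrum),
so the whole pipeline runs and is validated without any download.

## Worked example

```bash
python analysis/01_simulate.py            # synthetic genome + callset
python analysis/02_detect_and_annotate.py
python analysis/03_enrichment.py
python analysis/04_variability.py
python analysis/05_delta_score.py
```

The drivers write their tables under `results/` and print summaries; on the
default seed the run produces:

```
genome: 137,184 bp, 50 genes
planted motifs: 112 (113 detector-delimited pG4 intervals)
variants: 1378 (background 0.01/bp, fold 2.0 in pG4s)
...
detected 113 pG4s; 113 retained on coding strands
  FiveUTR        n=  20 density=1.548/kbp (merged 12,920 bp)
  ...
  FiveUTR        pG4 0.0238/bp vs control 0.0128/bp ratio=1.87 chi2 ***
  Intron         pG4 0.0225/bp vs control 0.0098/bp ratio=2.30 chi2 ***
```

Every detected pG4 contains a planted motif; the per-label SNP-density
ratios scatter around the planted 2.0-fold elevation (small labels are
noisy at this genome size), and the χ² contrast flags the high-count
labels.  The same pipeline is exposed as a CLI
(`pg4var simulate|detect|annotate|enrich|variability|deltascore|all`) for
running on real FASTA/GFF3/VCF inputs.

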