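# Methods

## Scoring model

Per-base G4Hunter scores are computed on the full sequence before any
windowing: a base in a maximal run of *n* identical Gs scores +min(*n*, 4),
in a run of Cs −min(*n*, 4), and A/T/U/N score 0. Lowercase (soft-masked)
bases score 0 by default, so detection on a masked genome avoids repeats
without any further filtering; a flag restores case-insensitive scoring.
Reverse complementation reverses and negates the score vector, which is the
basis of the strand-antisymmetry property tests. Because runs longer than
four score identically to runs of four, an interval's score depends on at
most 4 bp of context beyond each edge; the substitution machinery exploits
this for an exact, padded local rescoring.

## Detection dialect

Detection follows a three-pass protocol — (ws, t) = (20, 1.7), (30, 1.4),
(25, 1.6) — where every qualifying window marks its entire ws-length span,
marked spans are merged when they overlap or book-end (distance-0 merge,
the default of the common interval-merge tools), and each merged interval
is rescored as its mean base score (the absolute value is reported; the
sign is carried by the strand field). Two consequences are deliberate:
detected intervals are never shorter than the smallest window, and they can
extend several bases beyond the G-rich core when windows reaching into the
flank still clear the threshold. The post-hoc trimming/extension of hits to
G-run boundaries found in the original G4Hunter tool is **not** applied;
this plain merge-then-rescore dialect is documented rather than hidden.

## Gene models and regions

One representative transcript per gene: the mRNA with the longest total CDS
(ties broken by smallest transcript id). UTRs are derived as exonic bases
outside the CDS span, split by side relative to the strand; introns are
exon gaps. Seven region catalogs are built genome-wide and merged per
label: 5′UTR, 3′UTR, intron, CDS (exons without UTRs), and 60-bp junction
windows [j − 30, j + 30) around the 5′UTR/CDS junction, the CDS/3′UTR
junction and every exon–intron boundary, clipped only by chromosome
bounds. A pG4 is retained when fully inside a gene body whose strand
matches its G-rich strand (smallest gene id on ties), deduplicated on
(chrom, start, end, strand), and assigned to every label whose merged
interval fully contains it — base and junction catalogs are independent,
so multi-label assignment is normal.

## Enrichment null

The null re-places each pG4 uniformly at random among all start positions
(in any gene body long enough) with its length preserved and the host
gene's strand inherited; placements are independent and may overlap — the
simplest exchangeable null. Whether the original analysis constrained
placements to the source region or gene is not determinable; gene bodies
are the minimal faithful reading of "genic coordinates". Each of the 300
iterations is re-assigned with the same containment/dedup logic (a
vectorized path proven equal to the full assignment in tests) and reduced
to per-label densities. Fold enrichment is observed density over simulated
mean. The empirical p-value is the add-one-corrected two-sided formula
p = 2·min(#sim ≥ obs + 1, #sim ≤ obs + 1)/(iterations + 1), capped at 1.

Because the underlying statistic is an integer count, null draws tie with
the observation at an appreciable rate on small genomes, making this p
conservative (sub-uniform) — a property of the estimator, not a defect.
The calibration test therefore checks validity (P(p ≤ α) ≤ α plus Monte
Carlo error on an α grid) and tests uniformity on the randomized
tie-broken transform u = (#sim > obs + U·(1 + #ties))/(n + 1),
p* = 2·min(u, 1 − u), whose null distribution is exactly uniform.

## Variability statistics

Densities are variant *sites* per bp of merged interval length (each site
counts once regardless of allele count; indels count at their leftmost
reference base when enabled; masked bases are not removed from
denominators). The region contrast is a 2×2 Pearson χ² (1 df, no
continuity correction) of [variant, non-variant positions] × [inside pG4s,
region outside pG4s], flagged when an expected cell drops below 1. The
per-pG4 classification is a two-sided Fisher's exact test of the pG4
against its host region minus **all** pG4 footprints; `variable` /
`conserved` require p < α (default 0.05, raw p-values as in the primary
analysis — an optional Benjamini–Hochberg mode is off by default) *and* the
density inequality in the matching direction.

Landscapes average per-position variant counts over (30 bp 5′ flank, body,
30 bp 3′ flank); bodies are resampled to 30 points by linear interpolation
over [0, L − 1] inclusive, so the first and last body positions are
preserved exactly (length-30 bodies pass through unchanged — an identity
the tests pin down). Minus-strand profiles are reversed before averaging
so position 0 is always 5′-most; flank positions beyond chromosome bounds
are masked out of the average rather than counted as zeros; flanks are
taken purely by distance and may leave the host region.

## ΔG4Hscore

The substitution spectrum is the 12 conditional probabilities P(alt | ref)
counted from the region's own SNPs (uniform 1/3 fallback with a warning
for a reference base never observed to substitute). Δ is the signed change
of the interval mean score evaluated on the G-rich strand (minus-strand
pG4s: the plus-strand mean is negated, so plus-strand VCF alleles map
directly). Signed Δ is the default — required to see a preference for
score-lowering changes — with an absolute-value mode available.

Theoretical samples are multisets over candidate positions × 3 alternative
bases with spectrum weights (per-position weights sum to 1); the
`fixed_positions` model restricts candidates to variant-carrying positions,
separating the substitution-type effect from the positional effect. A
per-position-expectation mode (weighted mean Δ per position) is provided as
the alternative reading of the theoretical construction. Since a rank test
has no native weights, the weighted multiset is expanded by seeded
categorical sampling (default 10 draws per position) before a two-sided
Mann–Whitney comparison (normal approximation with tie correction) against
the observed Δs, pooled per region label.

## Synthetic data

The generator lays out 1.5–3 kbp genes (1–4 exons, ~15%/20% of exonic
length as 5′/3′ UTR) with 300–800 bp intergenic spacers on a single
chromosome at background GC 0.36 — compact plant-like gene architecture
and dicot-like GC. G4 motifs (canonical four-to-five G-tract quadruplexes
with 1–3 nt loops, plus a mixed-tract G-rich stretch) are planted on the
coding strand fully inside one interval of a target label; every default
motif is ≥ 21 nt with an internal ws = 20 window mean ≥ 1.7, so detection
recovers each planted copy regardless of flanking sequence. Soft-masking
is applied to intergenic segments only (a stand-in for repeat masking; the
spec of real repeat families is out of scope).

Variants are independent per-site Bernoulli draws at 0.01/bp background —
typical of large plant resequencing callsets in genic space — with a
2.0-fold multiplier inside the genome's pG4 intervals *as the detector
delimits them* (detected intervals extend a few bases beyond planted
motifs; applying the fold to detector-delimited intervals makes
"within-pG4 density" a well-defined planted quantity that the analysis can
recover without dilution by flanking bases). Alternative alleles follow a
transition-biased spectrum (Ts:Tv = 2:1 per reference base) unless
configured otherwise; optional 1–2 bp indels at a flat rate. Everything is
byte-identical per seed. Not emulated: linkage, demography, selection,
genotype frequencies, overlapping genes, alternative isoforms and real
repeat families — so passing tests demonstrate correctness of the
statistical machinery under its own assumptions, not robustness to every
property of real callsets.

## Problem sizes and numerical choices

The test suite validates scoring against an independent run-length oracle
on 1,000 random sequences; enrichment calibration uses 200 replicates ×
200 iterations on a 50-gene genome; parameter recovery uses an ~2.3 Mbp
800-gene genome (fold-2 recovery within 10%, Fisher calibration on >2,000
pG4s under a fold-1 callset); ΔG4Hscore calibration uses 200 replicate
null draws against a pooled theoretical sample. These sizes keep every
statistical check well-powered while the full suite runs in about a
minute. Ties in rank statistics use the tie-corrected normal
approximation; degenerate inputs (empty samples, zero-length regions,
constant landscapes) raise typed errors or return defined zero profiles as
documented in the module docstrings. All internal coordinates are 0-based
half-open with conversion only at the GFF3/VCF/BED boundaries; all
randomness flows through numpy Generators seeded from the configuration,
and every output table header records the package version, a configuration
hash and the seed.

## Known limitations

Single representative transcript per gene (isoform-aware regions are out
of scope); no genotype-frequency weighting — every site counts once; the
shuffle null is not GC- or length-matched beyond length preservation; the
ΔG4Hscore model considers single substitutions only (no indel or
multi-substitution effects); and pattern-based (G₃N₁₋₇)₃G₃ detection and
thermodynamic stability prediction are explicitly out of scope.
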