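"""Synthetic genomes, annotations and callsets with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-gene genome at plant-like GC content, a self-consistent GFF3 gene
annotation (exons, CDS, flanking UTRs, introns), G4-forming motifs planted
into chosen structural regions on the coding strand, soft-masked intergenic
segments, and a site-level VCF whose SNP density is elevated by a
configurable fold inside pG4s and whose alternative alleles follow a
configurable 12-entry substitution spectrum.

What it does not emulate: linkage, demography, selection, genotype
frequencies, sequencing error or real repeat families — variants are
independent Bernoulli draws per site, which is exactly the exchangeable
null the downstream statistics assume.

Everything is deterministic per seed (byte-identical FASTA/GFF3/VCF on
re-run).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import GeneModel, JUNCTION_LABELS, LABELS
from .errors import ConfigError
from .g4hunter import DEFAULT_PARAMS, PG4Interval, detect_genome, revcomp, window_means, base_scores
from .variants import INDEL, SNP, Variant

CHROM = "chr1"
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Planted motif library: canonical four-G-tract quadruplex sequences with
#: short loops plus G-rich stretches of mixed tract lengths.  Every motif is
#: long enough (>= 21 nt) that at least one ws=20 window lies fully inside
#: it with mean score >= 1.7, so detection cannot miss a planted copy
#: regardless of the flanking background.
DEFAULT_MOTIFS: Tuple[str, ...] = (
    "GGGGTTAGGGGTTAGGGGTTAGGGG",   # four G4 tracts, TTA loops (telomere-like)
    "GGGTTGGGTTGGGTTGGGTTGGG",     # five G3 tracts, TT loops
    "GGGGAGGGGAGGGGAGGGGAGGGG",    # five G4 tracts, single-A loops
    "GGGGTGGGTTGGGGTGGGTTGGGG",    # mixed G3/G4 tracts (non-canonical spacing)
)

#: Transition-biased conditional substitution probabilities (Ts:Tv = 2:1
#: within each reference base), a realistic default for plant callsets.
def transition_biased_spectrum() -> np.ndarray:
    p = np.zeros((4, 4))
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for i, ref in enumerate(BASES):
        for alt in BASES:
            if alt == ref:
                continue
            p[i, _BASE_INDEX[alt]] = 0.5 if alt == transitions[ref] else 0.25
    return p


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and callset.

    Defaults follow the analysis' stated conditions: genic SNP background
    density 0.01 per bp, a 2.0-fold density elevation inside pG4s, and a
    plant-like background GC of 0.36; gene architecture is a compact
    multi-exon model organism gene (1.5-3 kbp, 1-4 exons, ~15%/20% of the
    exonic length as 5'/3' UTR).
    """

    n_genes: int = 50
    gene_length_range: Tuple[int, int] = (1500, 3000)
    exons_per_gene_range: Tuple[int, int] = (1, 4)
    utr_fractions: Tuple[float, float] = (0.15, 0.20)  # (5', 3') of exonic length
    intergenic_range: Tuple[int, int] = (300, 800)
    background_gc: float = 0.36
    pg4_motif_set: Tuple[str, ...] = DEFAULT_MOTIFS
    pg4_planting_rates: Dict[str, float] = field(default_factory=lambda: {
        "FiveUTR": 0.4, "ThreeUTR": 0.4, "Intron": 0.5, "CDS": 0.6,
        "FiveUTR_CDS": 0.15, "ThreeUTR_CDS": 0.15, "IntronExon": 0.2,
    })
    mask_fraction: float = 0.05
    snp_density_background: float = 0.01  # per bp
    pg4_density_fold: float = 2.0
    substitution_spectrum: np.ndarray = field(default_factory=transition_biased_spectrum)
    indel_rate: float = 0.0
    junction_flank: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name, (lo, hi) in (("gene_length_range", self.gene_length_range),
                               ("exons_per_gene_range", self.exons_per_gene_range),
                               ("intergenic_range", self.intergenic_range)):
            if lo > hi or lo < 1:
                raise ConfigError(f"invalid {name}: ({lo}, {hi})")
        if not 0 < self.background_gc < 1:
            raise ConfigError(f"background_gc must be in (0, 1): {self.background_gc}")
        for rate in (self.mask_fraction, self.snp_density_background, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ConfigError(f"rates must lie in [0, 1]: {rate}")
        if self.pg4_density_fold < 0:
            raise ConfigError("pg4_density_fold must be >= 0")
        for lab, r in self.pg4_planting_rates.items():
            if lab not in LABELS or not 0 <= r <= 1:
                raise ConfigError(f"bad planting rate {lab}={r}")
        spec = np.asarray(self.substitution_spectrum, dtype=float)
        if spec.shape != (4, 4) or not np.allclose(spec.sum(axis=1), 1.0) \
                or not np.allclose(np.diag(spec), 0) or (spec < 0).any():
            raise ConfigError("substitution_spectrum must be 4x4 conditional rows")
        min_len = min(self.gene_length_range[0] // 10, 60)
        for m in self.pg4_motif_set:
            if set(m) - set("ACGT"):
                raise ConfigError(f"motif has non-ACGT characters: {m}")
            if len(m) > 60:
                raise ConfigError(f"motif longer than a junction window: {m}")
            scores = base_scores(m)
            inside = window_means(scores, 20)
            if len(inside) == 0 or inside.max() < 1.7:
                raise ConfigError(
                    f"motif cannot be detected at (ws=20, t=1.7) in isolation: {m}"
                )


@dataclass
class PlantedMotif:
    chrom: str
    start: int
    end: int
    strand: str
    label: str
    motif: str
    gene_id: str


@dataclass
class GroundTruth:
    """What the generator actually put into the genome."""

    planted: List[PlantedMotif]
    genes: List[GeneModel]
    chrom_sizes: Dict[str, int]
    spectrum: np.ndarray
    background_density: float
    pg4_density_fold: float
    #: pG4 intervals of the finished genome, as the detector delimits them;
    #: the variant-density fold applies to these (they contain every planted
    #: motif, typically with a few bp of flanking extension).
    pg4_intervals: List[PG4Interval] = field(default_factory=list)

    def planted_intervals(self) -> List[Tuple[str, int, int]]:
        return [(p.chrom, p.start, p.end) for p in self.planted]

    def to_json(self) -> str:
        return json.dumps({
            "planted": [asdict(p) for p in self.planted],
            "chrom_sizes": self.chrom_sizes,
            "spectrum": np.asarray(self.spectrum).tolist(),
            "background_density": self.background_density,
            "pg4_density_fold": self.pg4_density_fold,
            "pg4_intervals": [
                [q.chrom, q.start, q.end, q.strand, q.g4hscore] for q in self.pg4_intervals
            ],
        }, indent=1)


@dataclass
class SyntheticBundle:
    config: SimConfig
    fasta: Dict[str, str]
    gff3: str
    mask_bed: str
    truth: GroundTruth


# ---------------------------------------------------------------------------
# gene architecture


def _partition(rng: np.random.Generator, total: int, k: int, minimum: int) -> List[int]:
    """k positive parts of `total`, each >= minimum, multinomially jittered."""
    if total < k * minimum:
        raise ConfigError(f"cannot split {total} into {k} parts of >= {minimum}")
    extra = rng.multinomial(total - k * minimum, np.full(k, 1 / k))
    return [minimum + int(x) for x in extra]


def _tx_to_genomic(exons: Sequence[Tuple[int, int]], strand: str,
                   lo: int, hi: int) -> List[Tuple[int, int]]:
    """Map a transcript-coordinate range [lo, hi) to genomic intervals."""
    blocks = list(exons) if strand == "+" else [(s, e) for s, e in reversed(exons)]
    out: List[Tuple[int, int]] = []
    t = 0
    for s, e in blocks:
        size = e - s
        a, b = max(lo, t), min(hi, t + size)
        if b > a:
            if strand == "+":
                out.append((s + (a - t), s + (b - t)))
            else:
                out.append((e - (b - t), e - (a - t)))
        t += size
    return sorted(out)


def _build_gene(rng: np.random.Generator, cfg: SimConfig, gene_id: str,
                chrom: str, offset: int) -> Tuple[GeneModel, int]:
    glen = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
    n_ex = int(rng.integers(cfg.exons_per_gene_range[0], cfg.exons_per_gene_range[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    if n_ex > 1:
        intron_total = min(int(0.3 * glen), glen - n_ex * 100)
        intron_lens = _partition(rng, intron_total, n_ex - 1, 70)
    else:
        intron_lens = []
    exonic = glen - sum(intron_lens)
    exon_lens = _partition(rng, exonic, n_ex, 90)
    exons: List[Tuple[int, int]] = []
    cur = offset
    for i, el in enumerate(exon_lens):
        exons.append((cur, cur + el))
        cur += el + (intron_lens[i] if i < len(intron_lens) else 0)
    five_len = int(round(cfg.utr_fractions[0] * exonic))
    three_len = int(round(cfg.utr_fractions[1] * exonic))
    if exonic - five_len - three_len < 60:
        raise ConfigError("UTR fractions leave less than 60 bp of CDS")
    cds_lo, cds_hi = (five_len, exonic - three_len)
    cds = _tx_to_genomic(exons, strand, cds_lo, cds_hi)
    gene = GeneModel(gene_id, chrom, strand, f"{gene_id}.1", exons, cds)
    return gene, cur


def _gff3_text(genes: Sequence[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        s0, e0 = g.span
        attrs = f"ID={g.gene_id};Name={g.gene_id}"
        lines.append(f"{g.chrom}\tpg4var_sim\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t{attrs}")
        lines.append(
            f"{g.chrom}\tpg4var_sim\tmRNA\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t"
            f"ID={g.transcript_id};Parent={g.gene_id}"
        )
        for kind, ivals, phase in (
            ("exon", g.exons, "."),
            ("CDS", g.cds, "0"),
            ("five_prime_UTR", g.five_utr, "."),
            ("three_prime_UTR", g.three_utr, "."),
        ):
            for i, (s, e) in enumerate(ivals, 1):
                lines.append(
                    f"{g.chrom}\tpg4var_sim\t{kind}\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.transcript_id}.{kind}{i};Parent={g.transcript_id}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sequence simulation


def _background_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _gene_label_intervals(g: GeneModel, flank: int) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {
        "FiveUTR": list(g.five_utr),
        "ThreeUTR": list(g.three_utr),
        "Intron": list(g.introns),
        "CDS": list(g.cds),
        "FiveUTR_CDS": [],
        "ThreeUTR_CDS": [],
        "IntronExon": [],
    }
    j5, j3 = g.junction_5p(), g.junction_3p()
    if j5 is not None:
        out["FiveUTR_CDS"].append((max(0, j5 - flank), j5 + flank))
    if j3 is not None:
        out["ThreeUTR_CDS"].append((max(0, j3 - flank), j3 + flank))
    for s, e in g.introns:
        out["IntronExon"].append((max(0, s - flank), s + flank))
        out["IntronExon"].append((max(0, e - flank), e + flank))
    return out


def simulate_genome(cfg: SimConfig) -> SyntheticBundle:
    """Generate a genome, its annotation, a soft-mask and the ground truth.

    Gene models are laid out along a single chromosome with intergenic
    spacers; G4 motifs are planted on the coding strand fully inside one
    interval of their target label (reverse-complemented for minus-strand
    genes); intergenic segments are soft-masked to the requested fraction.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes: List[GeneModel] = []
    cursor = int(rng.integers(*cfg.intergenic_range))
    for i in range(cfg.n_genes):
        gene, cursor = _build_gene(rng, cfg, f"gene_{i + 1:04d}", CHROM, cursor)
        genes.append(gene)
        cursor += int(rng.integers(cfg.intergenic_range[0], cfg.intergenic_range[1] + 1))
    genome_len = cursor
    seq = _background_sequence(rng, genome_len, cfg.background_gc)

    # plant motifs; keep a margin from label-interval edges where possible so
    # window-span extension of detected intervals stays inside the label
    occupied = np.zeros(genome_len, dtype=bool)
    planted: List[PlantedMotif] = []
    margin = 12
    for g in genes:
        label_ivals = _gene_label_intervals(g, cfg.junction_flank)
        for label in LABELS:
            rate = cfg.pg4_planting_rates.get(label, 0.0)
            if rate <= 0 or rng.random() >= rate:
                continue
            motif = cfg.pg4_motif_set[int(rng.integers(len(cfg.pg4_motif_set)))]
            mlen = len(motif)
            candidates = [iv for iv in label_ivals[label] if iv[1] - iv[0] >= mlen]
            if not candidates:
                continue
            s_iv, e_iv = candidates[int(rng.integers(len(candidates)))]
            lo = s_iv + margin if e_iv - s_iv >= mlen + 2 * margin else s_iv
            hi = (e_iv - margin if e_iv - s_iv >= mlen + 2 * margin else e_iv) - mlen
            placed = False
            for _ in range(20):  # rejection sampling against overlaps
                start = int(rng.integers(lo, hi + 1))
                if not occupied[max(0, start - 1) : start + mlen + 1].any():
                    placed = True
                    break
            if not placed:
                continue
            insert = motif if g.strand == "+" else revcomp(motif)
            seq[start : start + mlen] = np.frombuffer(insert.encode(), dtype=np.uint8)
            occupied[start : start + mlen] = True
            planted.append(PlantedMotif(CHROM, start, start + mlen, g.strand,
                                        label, motif, g.gene_id))

    # soft-mask intergenic segments up to the requested genome fraction
    genic = np.zeros(genome_len, dtype=bool)
    for g in genes:
        genic[g.span[0] : g.span[1]] = True
    mask_rows: List[Tuple[int, int]] = []
    target = int(cfg.mask_fraction * genome_len)
    masked = 0
    inter = _intergenic_intervals(genes, genome_len)
    order = rng.permutation(len(inter))
    for k in order:
        if masked >= target:
            break
        s_iv, e_iv = inter[k]
        if e_iv - s_iv < 40:
            continue
        seg_len = int(min(e_iv - s_iv, rng.integers(50, 301), target - masked + 50))
        start = int(rng.integers(s_iv, e_iv - seg_len + 1))
        mask_rows.append((start, start + seg_len))
        masked += seg_len
    sequence = seq.tobytes().decode("ascii")
    chars = list(sequence)
    for s, e in mask_rows:
        chars[s:e] = [c.lower() for c in chars[s:e]]
    sequence = "".join(chars)

    fasta = {CHROM: sequence}
    truth = GroundTruth(
        planted=planted,
        genes=genes,
        chrom_sizes={CHROM: genome_len},
        spectrum=np.asarray(cfg.substitution_spectrum, dtype=float),
        background_density=cfg.snp_density_background,
        pg4_density_fold=cfg.pg4_density_fold,
        pg4_intervals=detect_genome(fasta, DEFAULT_PARAMS),
    )
    mask_bed = "".join(f"{CHROM}\t{s}\t{e}\n" for s, e in sorted(mask_rows))
    return SyntheticBundle(cfg, fasta, _gff3_text(genes), mask_bed, truth)


def _intergenic_intervals(genes: Sequence[GeneModel], genome_len: int
                          ) -> List[Tuple[int, int]]:
    out = []
    cur = 0
    for g in sorted(genes, key=lambda g: g.span):
        if g.span[0] > cur:
            out.append((cur, g.span[0]))
        cur = max(cur, g.span[1])
    if cur < genome_len:
        out.append((cur, genome_len))
    return out


# ---------------------------------------------------------------------------
# variant simulation


def simulate_variants(
    fasta: Dict[str, str],
    truth: GroundTruth,
    cfg: SimConfig,
    seed: Optional[int] = None,
    density_fold: Optional[float] = None,
) -> List[Variant]:
    """Site-level Bernoulli variant placement.

    Every position carries the background SNP probability, multiplied by
    the density fold inside the genome's pG4 intervals; alternative alleles
    are drawn from the configured substitution spectrum conditional on the
    (plus-strand) reference base.  Optional short indels are placed at a
    flat ``indel_rate``.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    fold = cfg.pg4_density_fold if density_fold is None else density_fold
    spectrum = np.asarray(cfg.substitution_spectrum, dtype=float)
    cum = np.cumsum(spectrum, axis=1)
    variants: List[Variant] = []
    fold_regions = truth.pg4_intervals or [
        PG4Interval(c, s, e, "+", 1.0) for c, s, e in truth.planted_intervals()
    ]
    for chrom in sorted(fasta):
        seq = fasta[chrom].upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        p = np.full(n, cfg.snp_density_background, dtype=float)
        for q in fold_regions:
            if q.chrom == chrom:
                p[q.start : q.end] *= fold
        np.clip(p, 0.0, 0.95, out=p)
        ref_idx = np.full(n, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            ref_idx[arr == ord(b)] = i
        eligible = ref_idx >= 0
        snp_pos = np.flatnonzero((rng.random(n) < p) & eligible)
        u = rng.random(len(snp_pos))
        rows = cum[ref_idx[snp_pos]]
        alt_idx = (u[:, None] > rows).sum(axis=1)
        for pos, ai in zip(snp_pos.tolist(), alt_idx.tolist()):
            variants.append(Variant(chrom, pos, seq[pos], BASES[ai], SNP))
        if cfg.indel_rate > 0:
            indel_pos = np.flatnonzero((rng.random(n) < cfg.indel_rate) & eligible)
            snp_set = set(snp_pos.tolist())
            for pos in indel_pos.tolist():
                if pos in snp_set or pos + 3 >= n or not eligible[pos + 1 : pos + 3].all():
                    continue
                size = int(rng.integers(1, 3))
                if rng.random() < 0.5:  # deletion
                    variants.append(
                        Variant(chrom, pos, seq[pos : pos + 1 + size], seq[pos], INDEL))
                else:  # insertion
                    ins = "".join(BASES[int(b)] for b in rng.integers(0, 4, size))
                    variants.append(Variant(chrom, pos, seq[pos], seq[pos] + ins, INDEL))
    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return variants


# ---------------------------------------------------------------------------
# bundle output


def write_bundle(bundle: SyntheticBundle, outdir,
                 variants: Optional[Sequence[Variant]] = None) -> Dict[str, str]:
    """Write FASTA/GFF3/mask BED/ground truth (and a VCF if given)."""
    import os

    from .seqio import write_fasta
    from .variants import write_vcf

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gff3": os.path.join(outdir, "annotation.gff3"),
        "mask_bed": os.path.join(outdir, "mask.bed"),
        "truth": os.path.join(outdir, "ground_truth.json"),
    }
    write_fasta(bundle.fasta, paths["fasta"])
    with open(paths["gff3"], "w") as fh:
        fh.write(bundle.gff3)
    with open(paths["mask_bed"], "w") as fh:
        fh.write(bundle.mask_bed)
    with open(paths["truth"], "w") as fh:
        fh.write(bundle.truth.to_json())
    if variants is not None:
        paths["vcf"] = os.path.join(outdir, "variants.vcf")
        write_vcf(variants, bundle.truth.chrom_sizes, paths["vcf"])
    return paths
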