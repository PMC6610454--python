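"""End-to-end orchestration: detect -> annotate -> enrich -> variability -> delta.

Internal coordinates are 0-based half-open everywhere; conversions happen at
the I/O boundaries (GFF3/VCF are 1-based on disk, BED output is 0-based).
Every output table starts with header comment lines carrying the package
version, a hash of the configuration and the seeds, so identical configs
produce byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (LABELS, RegionCatalog, assign_pg4s, build_region_catalog,
                         parse_gff)
from .delta_score import (ALL_POSITIONS, FIXED_POSITIONS, DeltaSample,
                          background_spectrum, compare_distributions,
                          observed_sample, theoretical_sample)
from .enrichment import GenicSpace, enrichment_test
from .errors import ConfigError, InsufficientDataError
from .g4hunter import DEFAULT_PARAMS, detect_genome, write_bed
from .intervals import GenomicIntervals
from .seqio import apply_mask_bed, read_fasta
from .variability import (classify_all, enrichment_variability_regression,
                          landscape, region_variability_test, snp_density)
from .variants import SNP, filter_snps, read_vcf

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    fasta: str
    gff3: str
    vcf: str
    outdir: str
    mask_bed: Optional[str] = None
    detection_params: Tuple[Tuple[int, float], ...] = DEFAULT_PARAMS
    junction_flank: int = 30
    landscape_flank: int = 30
    landscape_body: int = 30
    iterations: int = 300
    alpha: float = 0.05
    include_indels: bool = False
    mc_draws: int = 10
    regression_exclude: Tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in ("fasta", "gff3", "vcf"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise ConfigError(f"{name} file not found: {path}")
        if self.mask_bed and not os.path.exists(self.mask_bed):
            raise ConfigError(f"mask_bed file not found: {self.mask_bed}")
        if self.iterations < 2:
            raise ConfigError("iterations must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location does not affect results
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(cfg: AnalysisConfig) -> List[str]:
    return [f"pg4var {__version__}", f"config_hash={cfg.hash()}", f"seed={cfg.seed}"]


def _write_tsv(df: pd.DataFrame, path: str, header_lines: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_all(cfg: AnalysisConfig) -> Dict[str, pd.DataFrame]:
    """Run every stage in dependency order, writing all outputs to cfg.outdir."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    header = _header(cfg)
    out: Dict[str, pd.DataFrame] = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    # -- detect ------------------------------------------------------------
    name = stage("detect")
    try:
        fasta = read_fasta(cfg.fasta)
        if cfg.mask_bed:
            fasta = apply_mask_bed(fasta, cfg.mask_bed)
        pg4s = detect_genome(fasta, cfg.detection_params)
        write_bed(pg4s, os.path.join(cfg.outdir, "pg4s.bed"))
        log.info("detected %d pG4s", len(pg4s))
    except Exception as e:  # pragma: no cover - defensive wrapper
        raise RuntimeError(f"stage {name} failed: {e}") from e

    # -- annotate ----------------------------------------------------------
    name = stage("annotate")
    chrom_sizes = {c: len(s) for c, s in fasta.items()}
    genes = parse_gff(cfg.gff3, from_string=False)
    catalog = build_region_catalog(genes, cfg.junction_flank, chrom_sizes)
    assignment = assign_pg4s(pg4s, catalog, genes)
    assignment.to_tsv(os.path.join(cfg.outdir, "assignments.tsv"), header)
    out["assignments"] = assignment.table
    log.info("genes=%d assigned=%d discarded_strand=%d discarded_intergenic=%d",
             len(genes), len(assignment.table),
             assignment.n_discarded_strand, assignment.n_discarded_intergenic)

    # -- enrichment --------------------------------------------------------
    name = stage("enrich")
    space = GenicSpace.from_genes(genes)
    enr = enrichment_test(pg4s, catalog, space, genes,
                          iterations=cfg.iterations, seed=cfg.seed)
    enr_df = pd.DataFrame([asdict(r) for r in enr])
    _write_tsv(enr_df, os.path.join(cfg.outdir, "enrichment.tsv"), header)
    out["enrichment"] = enr_df

    # -- variability -------------------------------------------------------
    name = stage("variability")
    variants = read_vcf(cfg.vcf)
    snps = filter_snps(variants)
    used = variants if cfg.include_indels else snps
    log.info("variants=%d (snps=%d)", len(variants), len(snps))
    region_rows, class_rows, points = [], [], []
    fe_by_label = dict(zip(enr_df["label"], enr_df["fold_enrichment"]))
    for label in LABELS:
        label_pg4s = assignment.pg4s_for(label)
        region = catalog[label]
        if not label_pg4s or region.total_length == 0:
            continue
        pg4_density = snp_density(label_pg4s, used, cfg.include_indels)
        control_density = snp_density(region, used, cfg.include_indels)
        try:
            chi2 = region_variability_test(label_pg4s, region, used, cfg.include_indels)
            chi2_stat, chi2_p, low = chi2
        except Exception:
            chi2_stat, chi2_p, low = float("nan"), float("nan"), True
        region_rows.append((label, len(label_pg4s), pg4_density, control_density,
                            pg4_density / control_density if control_density else float("nan"),
                            chi2_stat, chi2_p, low))
        prof = landscape(label_pg4s, used, chrom_sizes,
                         cfg.landscape_flank, cfg.landscape_body, cfg.include_indels)
        ldf = pd.DataFrame({
            "position": np.arange(len(prof.values)),
            "segment": (["flank5"] * prof.flank + ["body"] * prof.body
                        + ["flank3"] * prof.flank),
            "mean_count": prof.values,
            "scaled": prof.scaled(),
        })
        _write_tsv(ldf, os.path.join(cfg.outdir, f"landscape_{label}.tsv"), header)
        for c in classify_all(label_pg4s, region, used, cfg.alpha, cfg.include_indels):
            class_rows.append((label,) + tuple(asdict(c).values()))
        if control_density > 0 and label in fe_by_label:
            points.append((label, fe_by_label[label], pg4_density / control_density))
    reg_df = pd.DataFrame(
        region_rows,
        columns=["label", "n_pg4", "pg4_density", "control_density",
                 "density_ratio", "chi2", "p_value", "low_count"])
    _write_tsv(reg_df, os.path.join(cfg.outdir, "variability_regions.tsv"), header)
    out["variability_regions"] = reg_df
    cls_df = pd.DataFrame(
        class_rows,
        columns=["label", "pg4_id", "observed_variants", "pg4_length",
                 "region_variants", "region_length", "fisher_p", "pg4_class"])
    _write_tsv(cls_df, os.path.join(cfg.outdir, "pg4_classification.tsv"), header)
    out["pg4_classification"] = cls_df
    try:
        reg = enrichment_variability_regression(points, set(cfg.regression_exclude))
        regdf = pd.DataFrame([{
            "slope": reg.slope, "intercept": reg.intercept,
            "pearson_r": reg.pearson_r, "n_used": reg.n_used,
            "excluded": ",".join(reg.excluded)}])
    except InsufficientDataError:
        regdf = pd.DataFrame(columns=["slope", "intercept", "pearson_r",
                                      "n_used", "excluded"])
    _write_tsv(regdf, os.path.join(cfg.outdir, "regression.tsv"), header)
    out["regression"] = regdf

    # -- delta score -------------------------------------------------------
    name = stage("deltascore")
    delta_rows = []
    for label in LABELS:
        label_pg4s = assignment.pg4s_for(label)
        region = catalog[label]
        if not label_pg4s or region.total_length == 0:
            continue
        spectrum = background_spectrum(snps, region)
        obs = observed_sample(label_pg4s, fasta, snps)
        if len(obs) == 0:
            continue
        var_pos_by_pg4 = {
            p.key(): sorted(
                v.pos for v in snps
                if v.chrom == p.chrom and p.start <= v.pos < p.end)
            for p in label_pg4s
        }
        for model in (ALL_POSITIONS, FIXED_POSITIONS):
            samples = []
            for p in label_pg4s:
                vpos = var_pos_by_pg4[p.key()]
                if model == FIXED_POSITIONS and not vpos:
                    continue
                samples.append(theoretical_sample(
                    p, fasta[p.chrom], spectrum, model,
                    variant_positions=vpos or None))
            theo = DeltaSample.concat([s for s in samples if len(s)])
            if len(theo) == 0:
                continue
            cmp_res = compare_distributions(obs, theo, cfg.mc_draws,
                                            seed=cfg.seed + 1, label=label)
            delta_rows.append(asdict(cmp_res))
    delta_df = pd.DataFrame(delta_rows)
    _write_tsv(delta_df, os.path.join(cfg.outdir, "delta_comparisons.tsv"), header)
    out["delta_comparisons"] = delta_df
    return out
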