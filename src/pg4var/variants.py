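"""Normalized variants and VCF I/O.

Variants are site-level observations: each record contributes one
:class:`Variant` per ALT allele, positioned 0-based at the leftmost
reference base.  Genotypes, frequencies and samples are deliberately
ignored — downstream statistics count variant *sites*.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .intervals import GenomicIntervals

SNP = "SNP"
INDEL = "INDEL"
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based leftmost reference position
    ref: str
    alt: str
    vtype: str = SNP

    @staticmethod
    def classify(ref: str, alt: str) -> str:
        return SNP if len(ref) == 1 and len(alt) == 1 and ref != alt else INDEL


def read_vcf(path) -> List[Variant]:
    """Read a VCF, decomposing multi-allelic records into one Variant per ALT."""
    import pysam

    out: List[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if alt is None or alt == "*" or alt.startswith("<"):
                    continue
                ref = rec.ref.upper()
                alt = alt.upper()
                if ref == alt:
                    continue
                out.append(Variant(rec.chrom, rec.start, ref, alt,
                                   Variant.classify(ref, alt)))
    return out


def write_vcf(variants: Sequence[Variant], chrom_sizes: Dict[str, int], path) -> None:
    """Minimal valid VCF 4.2 with a single placeholder sample (GT 1/1)."""
    recs = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(chrom_sizes):
            fh.write(f"##contig=<ID={chrom},length={chrom_sizes[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\n")
        for v in recs:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t1/1\n")


def filter_snps(variants: Iterable[Variant]) -> List[Variant]:
    return [v for v in variants if v.vtype == SNP]


def site_positions(
    variants: Iterable[Variant], include_indels: bool = False
) -> Dict[str, np.ndarray]:
    """Sorted unique variant-site positions per chromosome.

    Indels are counted at their leftmost reference position when included.
    """
    by: Dict[str, set] = {}
    for v in variants:
        if v.vtype == SNP or include_indels:
            by.setdefault(v.chrom, set()).add(v.pos)
    return {c: np.array(sorted(ps), dtype=np.int64) for c, ps in by.items()}


def position_counts(
    variants: Iterable[Variant], include_indels: bool = False
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (sorted positions, number of variants at each position)."""
    by: Dict[str, Dict[int, int]] = {}
    for v in variants:
        if v.vtype == SNP or include_indels:
            d = by.setdefault(v.chrom, {})
            d[v.pos] = d.get(v.pos, 0) + 1
    out = {}
    for chrom, d in by.items():
        pos = np.array(sorted(d), dtype=np.int64)
        out[chrom] = (pos, np.array([d[p] for p in pos.tolist()], dtype=np.int64))
    return out


def count_sites_in(
    intervals: GenomicIntervals,
    sites: Dict[str, np.ndarray],
) -> int:
    """Number of variant sites falling inside a merged interval set."""
    total = 0
    for chrom, pos in sites.items():
        total += int(intervals.contains_points(chrom, pos).sum())
    return total


def variants_in(
    variants: Iterable[Variant],
    intervals: GenomicIntervals,
    include_indels: bool = True,
) -> List[Variant]:
    return [
        v for v in variants
        if (v.vtype == SNP or include_indels)
        and intervals.contains_points(v.chrom, np.array([v.pos]))[0]
    ]
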