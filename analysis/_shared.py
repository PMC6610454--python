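"""Shared input loading for the numbered analysis drivers."""
from __future__ import annotations

import os

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SYNTH = os.path.join(RESULTS, "synthetic")
SEED = 1


def load_inputs():
    """(fasta dict, genes, catalog, chrom_sizes, variants) from 01's outputs."""
    from pg4var.annotation import build_region_catalog, parse_gff
    from pg4var.seqio import read_fasta
    from pg4var.variants import read_vcf

    fasta = read_fasta(os.path.join(SYNTH, "genome.fa"))
    genes = parse_gff(os.path.join(SYNTH, "annotation.gff3"), from_string=False)
    chrom_sizes = {c: len(s) for c, s in fasta.items()}
    catalog = build_region_catalog(genes, 30, chrom_sizes)
    variants = read_vcf(os.path.join(SYNTH, "variants.vcf"))
    return fasta, genes, catalog, chrom_sizes, variants


def detect_and_assign(fasta, genes, catalog):
    from pg4var.annotation import assign_pg4s
    from pg4var.g4hunter import detect_genome

    pg4s = detect_genome(fasta)
    return pg4s, assign_pg4s(pg4s, catalog, genes)
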