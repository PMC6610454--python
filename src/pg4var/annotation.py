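"""Gene models, structural-region catalogs and pG4 region assignment.

Seven structural regions are cataloged per genome: 5'UTR, 3'UTR, Intron,
CDS (exonic coding bases, i.e. exons without UTRs), plus three junction
region types defined as the +/-30 bp windows around the 5'UTR/CDS junction
(the start-codon boundary), the CDS/3'UTR junction and every exon-intron
boundary.  A pG4 is assigned to a region label only when it is entirely
contained in one merged interval of that label, and only when its G-rich
strand matches the strand of its host gene (so the structure can form in
the pre-mRNA).
"""
from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MalformedAnnotationError
from .g4hunter import PG4Interval
from .intervals import GenomicIntervals, merge_pairs

log = logging.getLogger(__name__)

LABELS: Tuple[str, ...] = (
    "FiveUTR", "ThreeUTR", "Intron", "CDS",
    "FiveUTR_CDS", "ThreeUTR_CDS", "IntronExon",
)
BASE_LABELS: Tuple[str, ...] = ("FiveUTR", "ThreeUTR", "Intron", "CDS")
JUNCTION_LABELS: Tuple[str, ...] = ("FiveUTR_CDS", "ThreeUTR_CDS", "IntronExon")

Interval = Tuple[int, int]


def derive_regions(
    exons: Sequence[Interval], cds: Sequence[Interval], strand: str
) -> Tuple[List[Interval], List[Interval], List[Interval]]:
    """(five_utr, three_utr, introns) from exon and CDS intervals.

    UTRs are the exonic bases outside the CDS genomic span, split by side;
    which side is 5' depends on the strand.  Introns are the gaps between
    consecutive exons.
    """
    exons = merge_pairs(exons)
    cds = merge_pairs(cds)
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    if not cds:
        raise MalformedAnnotationError("transcript without CDS")
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    left: List[Interval] = []
    right: List[Interval] = []
    for s, e in exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    if strand == "+":
        return left, right, introns
    return right, left, introns


@dataclass
class GeneModel:
    """One representative transcript per protein-coding gene."""

    gene_id: str
    chrom: str
    strand: str
    transcript_id: str
    exons: List[Interval]
    cds: List[Interval]
    five_utr: List[Interval] = field(default_factory=list)
    three_utr: List[Interval] = field(default_factory=list)
    introns: List[Interval] = field(default_factory=list)

    def __post_init__(self):
        self.exons = merge_pairs(self.exons)
        self.cds = merge_pairs(self.cds)
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise MalformedAnnotationError(
                    f"CDS [{cs}, {ce}) of transcript {self.transcript_id} "
                    f"lies outside its exons"
                )
        self.five_utr, self.three_utr, self.introns = derive_regions(
            self.exons, self.cds, self.strand
        )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junction_5p(self) -> Optional[int]:
        """Genomic coordinate of the 5'UTR/CDS boundary, if a 5'UTR exists."""
        if not self.five_utr:
            return None
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]

    def junction_3p(self) -> Optional[int]:
        if not self.three_utr:
            return None
        return self.cds[-1][1] if self.strand == "+" else self.cds[0][0]


def parse_gff(source, from_string: Optional[bool] = None) -> List[GeneModel]:
    """Parse a GFF3 (path, file-like, or text) into representative gene models.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Per gene, the representative transcript is the mRNA with the longest
    total CDS (ties broken by lexicographically smallest transcript id).
    Genes without strand are skipped with a warning; a CDS outside its
    transcript's exons raises :class:`MalformedAnnotationError`.
    """
    import gffutils

    if hasattr(source, "read"):
        source, from_string = source.read(), True
    if from_string is None:
        from_string = isinstance(source, str) and "\n" in source
    db = gffutils.create_db(
        source,
        ":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in "+-":
            log.warning("gene %s has no strand; skipped", gene.id)
            continue
        best: Optional[Tuple[int, str, List[Interval], List[Interval]]] = None
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not exons or not cds:
                continue
            cds_len = sum(e - s for s, e in cds)
            cand = (-cds_len, mrna.id, exons, cds)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            log.warning("gene %s has no coding transcript; skipped", gene.id)
            continue
        _, tx_id, exons, cds = best
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, tx_id, exons, cds))
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


@dataclass
class RegionCatalog:
    """Merged genomic interval sets for the seven structural-region labels."""

    intervals: Dict[str, GenomicIntervals]
    junction_flank: int = 30

    def merged_length(self, label: str) -> int:
        return self.intervals[label].total_length

    def __getitem__(self, label: str) -> GenomicIntervals:
        return self.intervals[label]


def build_region_catalog(
    genes: Sequence[GeneModel],
    junction_flank: int = 30,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> RegionCatalog:
    """Merge per-gene structural regions into genome-wide label catalogs.

    Junction windows span [j - flank, j + flank) around each junction
    coordinate j and are clipped only by chromosome bounds, not gene bounds.
    """
    raw: Dict[str, List[Tuple[str, int, int]]] = {lab: [] for lab in LABELS}

    def add_window(label: str, chrom: str, j: int) -> None:
        lo = max(0, j - junction_flank)
        hi = j + junction_flank
        if chrom_sizes and chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[chrom])
        if hi > lo:
            raw[label].append((chrom, lo, hi))

    for g in genes:
        for s, e in g.five_utr:
            raw["FiveUTR"].append((g.chrom, s, e))
        for s, e in g.three_utr:
            raw["ThreeUTR"].append((g.chrom, s, e))
        for s, e in g.introns:
            raw["Intron"].append((g.chrom, s, e))
        for s, e in g.cds:
            raw["CDS"].append((g.chrom, s, e))
        j5 = g.junction_5p()
        if j5 is not None:
            add_window("FiveUTR_CDS", g.chrom, j5)
        j3 = g.junction_3p()
        if j3 is not None:
            add_window("ThreeUTR_CDS", g.chrom, j3)
        for s, e in g.introns:
            add_window("IntronExon", g.chrom, s)
            add_window("IntronExon", g.chrom, e)

    return RegionCatalog(
        {lab: GenomicIntervals.from_tuples(raw[lab]) for lab in LABELS},
        junction_flank=junction_flank,
    )


def dedupe_pg4s(pg4s: Iterable[PG4Interval]) -> List[PG4Interval]:
    """Unique pG4s by (chrom, start, end, strand), order-preserving."""
    seen = set()
    out = []
    for p in pg4s:
        if p.key() not in seen:
            seen.add(p.key())
            out.append(p)
    return out


@dataclass
class RegionAssignment:
    """Retained pG4s with their host gene and full set of containing labels."""

    table: pd.DataFrame  # pg4_id chrom start end strand g4hscore gene_id labels
    n_input: int = 0
    n_discarded_strand: int = 0
    n_discarded_intergenic: int = 0

    def pg4s_for(self, label: str) -> List[PG4Interval]:
        rows = self.table[self.table["labels"].map(lambda ls: label in ls)]
        return [
            PG4Interval(r.chrom, r.start, r.end, r.strand, r.g4hscore, r.pg4_id)
            for r in rows.itertuples()
        ]

    def counts(self) -> Dict[str, int]:
        return {lab: int(self.table["labels"].map(lambda ls: lab in ls).sum())
                for lab in LABELS}

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        df = self.table.copy()
        df["labels"] = df["labels"].map(lambda ls: ",".join(sorted(ls)))
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)


class _GeneIndex:
    """Per (chrom, strand) containment lookup over (possibly nested) genes."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, List[GeneModel]]] = {}
        grouped: Dict[Tuple[str, str], List[GeneModel]] = {}
        for g in genes:
            grouped.setdefault((g.chrom, g.strand), []).append(g)
        for key, gs in grouped.items():
            gs.sort(key=lambda g: g.span)
            starts = np.array([g.span[0] for g in gs], dtype=np.int64)
            ends = np.array([g.span[1] for g in gs], dtype=np.int64)
            self._by[key] = (starts, np.maximum.accumulate(ends), gs)

    def host(self, chrom: str, start: int, end: int, strand: str) -> Optional[GeneModel]:
        entry = self._by.get((chrom, strand))
        if entry is None:
            return None
        starts, run_max_end, gs = entry
        i = int(np.searchsorted(starts, start, side="right")) - 1
        hits: List[GeneModel] = []
        while i >= 0 and run_max_end[i] > start:
            g = gs[i]
            if g.span[0] <= start and end <= g.span[1]:
                hits.append(g)
            i -= 1
        if not hits:
            return None
        return min(hits, key=lambda g: g.gene_id)


def assign_pg4s(
    pg4s: Sequence[PG4Interval],
    catalog: RegionCatalog,
    genes: Sequence[GeneModel],
) -> RegionAssignment:
    """Assign deduplicated pG4s to every label that fully contains them.

    A pG4 is kept only if it lies entirely within a gene body whose strand
    matches its G-rich strand (first such gene by smallest gene_id).  Base
    and junction labels are independent catalogs, so multi-label assignment
    is expected.
    """
    unique = dedupe_pg4s(pg4s)
    index = _GeneIndex(genes)
    rows = []
    n_strand = n_intergenic = 0
    for p in unique:
        host = index.host(p.chrom, p.start, p.end, p.strand)
        if host is None:
            # distinguish "wrong strand over a gene" from "no gene at all"
            other = index.host(p.chrom, p.start, p.end, "-" if p.strand == "+" else "+")
            if other is not None:
                n_strand += 1
            else:
                n_intergenic += 1
            continue
        labels = frozenset(
            lab for lab in LABELS
            if catalog[lab].contains_interval(p.chrom, p.start, p.end)
        )
        rows.append((p.pg4_id, p.chrom, p.start, p.end, p.strand,
                     p.g4hscore, host.gene_id, labels))
    table = pd.DataFrame(
        rows,
        columns=["pg4_id", "chrom", "start", "end", "strand",
                 "g4hscore", "gene_id", "labels"],
    )
    return RegionAssignment(table, len(unique), n_strand, n_intergenic)
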