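"""FASTA reading/writing helpers (case-preserving, whole-sequence)."""
from __future__ import annotations

from typing import Dict


def read_fasta(path) -> Dict[str, str]:
    """Load all records into memory, preserving softmask case."""
    from pyfaidx import Fasta

    with Fasta(str(path), read_long_names=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def apply_mask_bed(sequences: Dict[str, str], bed_path) -> Dict[str, str]:
    """Lowercase the intervals of a BED file (soft-masking)."""
    out = {k: list(v) for k, v in sequences.items()}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split("\t")[:3]
            if chrom in out:
                s, e = int(s), int(e)
                out[chrom][s:e] = [c.lower() for c in out[chrom][s:e]]
    return {k: "".join(v) for k, v in out.items()}
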