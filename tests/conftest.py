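"""Shared fixtures: independent oracles and small synthetic inputs."""
from __future__ import annotations

from typing import List

import numpy as np
import pytest

from pg4var.synthetic_data import SimConfig, simulate_genome, simulate_variants


def naive_base_scores(seq: str) -> List[int]:
    """Independent run-length re-implementation of per-base G4Hunter scores.

    Deliberately written as a character-walking loop (no numpy, no shared
    code) so it can serve as an oracle for the vectorized implementation.
    Only uppercase G/C score; every base in a run of n identical characters
    scores +/- min(n, 4).
    """
    scores: List[int] = []
    i, n = 0, len(seq)
    while i < n:
        c = seq[i]
        if c in "GC":
            j = i
            while j < n and seq[j] == c:
                j += 1
            val = min(j - i, 4) * (1 if c == "G" else -1)
            scores.extend([val] * (j - i))
            i = j
        else:
            scores.append(0)
            i += 1
    return scores


def random_sequence(rng: np.random.Generator, length: int, gc: float,
                    masked: bool = False) -> str:
    bases = np.array(list("ACGT"))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(bases, size=length, p=probs))
    if masked and rng.random() < 0.3:
        # lowercase a random stretch and sprinkle an N
        a = int(rng.integers(0, length))
        b = int(rng.integers(a, length + 1))
        seq = seq[:a] + seq[a:b].lower() + seq[b:]
        k = int(rng.integers(0, length))
        seq = seq[:k] + "N" + seq[k + 1 :]
    return seq


#: GFF3 for the canonical two-exon fixture gene: exons [0,100) and [200,300),
#: CDS [50,100) + [200,250), giving 5'UTR [0,50), 3'UTR [250,300) and the
#: intron [100,200) on the plus strand.
FIXTURE_GFF_PLUS = """##gff-version 3
chr1\ttest\tgene\t1\t300\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1
chr1\ttest\texon\t1\t100\t.\t+\t.\tID=g1.1.e1;Parent=g1.1
chr1\ttest\texon\t201\t300\t.\t+\t.\tID=g1.1.e2;Parent=g1.1
chr1\ttest\tCDS\t51\t100\t.\t+\t0\tID=g1.1.c1;Parent=g1.1
chr1\ttest\tCDS\t201\t250\t.\t+\t0\tID=g1.1.c2;Parent=g1.1
"""

FIXTURE_GFF_MINUS = FIXTURE_GFF_PLUS.replace("\t+\t", "\t-\t")


@pytest.fixture(scope="session")
def fixture_genes_plus():
    from pg4var.annotation import parse_gff

    return parse_gff(FIXTURE_GFF_PLUS)


@pytest.fixture(scope="session")
def small_bundle():
    """A 15-gene genome with planted motifs and a fold-2 callset."""
    cfg = SimConfig(n_genes=15, seed=11)
    bundle = simulate_genome(cfg)
    variants = simulate_variants(bundle.fasta, bundle.truth, cfg)
    return bundle, variants


@pytest.fixture(scope="session")
def medium_bundle():
    """A 50-gene genome matching the default study conditions."""
    cfg = SimConfig(n_genes=50, seed=5)
    bundle = simulate_genome(cfg)
    variants = simulate_variants(bundle.fasta, bundle.truth, cfg)
    return bundle, variants
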