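"""Shared fixtures: toy transcripts and small simulated screens."""

from __future__ import annotations

import numpy as np
import pytest

from enuscreen.simulate import ScreenConfig, simulate_line, single_locus_model
from enuscreen.variants import TranscriptModel

STOPS = ("TAA", "TAG", "TGA")


def random_cds(rng: np.random.Generator, n_codons: int = 20) -> str:
    """Random CDS with a start, no internal stops, and a stop codon."""
    bases = "ACGT"
    body = []
    while len(body) < n_codons - 2:
        codon = "".join(rng.choice(list(bases), 3))
        if codon not in STOPS:
            body.append(codon)
    return "ATG" + "".join(body) + str(rng.choice(STOPS))


def random_transcript(
    rng: np.random.Generator,
    gene: str = "Toy",
    chrom: str = "chr1",
    n_codons: int = 20,
    strand: str = "+",
) -> tuple[TranscriptModel, list[int]]:
    """A toy transcript plus the genomic position of every CDS base.

    The position list is built by independent bookkeeping (walking exons
    in transcription order), so tests can locate CDS index i on the
    genome without using the model's own coordinate mapping.
    """
    cds = random_cds(rng, n_codons)
    length = len(cds)
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False))
    sizes = np.diff([0, *cuts, length])
    start = int(rng.integers(1000, 2000))
    exons = []
    pos = start
    for size in sizes:
        exons.append((pos, pos + int(size) - 1))
        pos += int(size) + int(rng.integers(50, 200))  # intron gap
    model = TranscriptModel(
        gene=gene, chrom=chrom, strand=strand, cds_exons=tuple(exons), cds_sequence=cds
    )
    genomic: list[int] = []
    if strand == "+":
        for s, e in exons:
            genomic.extend(range(s, e + 1))
    else:
        for s, e in reversed(exons):
            genomic.extend(range(e, s - 1, -1))
    return model, genomic


@pytest.fixture(scope="session")
def small_line():
    """One simulated single-suppressor line at the default study scale."""
    config = ScreenConfig(n2_families_per_line=8, n3_per_family=8)
    return config, simulate_line(config, single_locus_model(), rng_seed=11)
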