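"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from dsbsirna.locus import GeneModel
from dsbsirna.reads import AlignedRead, Library, RawRead, reverse_complement

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def random_gene_model(rng: np.random.Generator, max_exons: int = 5) -> GeneModel:
    """A valid random single-transcript gene starting at a random offset."""
    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, 50))
    exons = []
    for _ in range(n_exons):
        elen = int(rng.integers(30, 200))
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(20, 80))  # intron gap (ignored after last)
    return GeneModel(
        "rand", "chrR", "+", exons[0][0], exons[-1][1], tuple(exons)
    )


def naive_placements(seq: str, reference: str) -> list[AlignedRead]:
    """Exhaustive string-scan oracle for the exact ungapped mapper.

    Same conventions as the mapper: reads containing N are unmapped, the
    start is the leftmost reference base, minus-strand hits are found via
    the reverse complement, and a palindromic read reports plus-strand
    placements only.
    """
    if "N" in seq or not seq:
        return []
    out = []
    for strand, query in (("+", seq), ("-", reverse_complement(seq))):
        if strand == "-" and query == seq:
            continue
        p = reference.find(query)
        while p >= 0:
            out.append(AlignedRead(p, len(seq), strand))
            p = reference.find(query, p + 1)
    return out


def brute_force_coverage(
    lib: Library, window: tuple[int, int], length_filter=(18, 24)
) -> dict[str, np.ndarray]:
    """Per-base overlap counting and end-position placement, one read at a
    time (independent of the vectorized implementation)."""
    lo, hi = window
    out = {
        "sense_cov": np.zeros(hi - lo),
        "anti_cov": np.zeros(hi - lo),
        "sense_end": np.zeros(hi - lo),
        "anti_end": np.zeros(hi - lo),
    }
    scale = 1e6 / lib.total_reads
    for a in lib:
        if not (length_filter[0] <= a.length <= length_filter[1]):
            continue
        cov = out["anti_cov"] if a.strand == "-" else out["sense_cov"]
        for b in range(a.start, a.start + a.length):
            if lo <= b < hi:
                cov[b - lo] += scale
        if a.start >= lo and a.start + a.length <= hi:
            key = "anti_end" if a.strand == "-" else "sense_end"
            out[key][a.start - lo] += scale
    return out


@pytest.fixture
def two_exon_gene() -> GeneModel:
    return GeneModel("g1", "chr2", "+", 100, 400, ((100, 200), (300, 400)))


@pytest.fixture
def four_exon_gene() -> GeneModel:
    return GeneModel(
        "g4", "chr3", "+", 0, 700,
        ((0, 100), (150, 300), (360, 500), (560, 700)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_library(
    aligned: list[AlignedRead], total: int | None = None, name: str = "toy"
) -> Library:
    return Library.from_aligned(name, aligned, total if total is not None else len(aligned))


def uniform_reads(start: int, stop: int, length: int, strand: str = "+") -> list[AlignedRead]:
    """Every start position in [start, stop - length] exactly once."""
    return [
        AlignedRead(s, length, strand, f"u{s}") for s in range(start, stop - length + 1)
    ]
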