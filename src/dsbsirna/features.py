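"""Size-normalized siRNA coverage over exons, introns and splice junctions.

Exons and introns count every read that intersects them; a junction counts
reads spanning its boundary with at least ``min_overhang`` bases on each
side.  Counts are scaled to reads-per-million and divided by the feature's
size — interval length for exons/introns, the number of spanning start
positions (L - 2*overhang + 1) for junctions — so that under uniform read
placement every feature has the same expected density.  Exon-exon
junctions exist only on the spliced (cDNA) axis and are counted by mapping
raw reads against the spliced sequence, excluding reads that also map to
the unspliced genomic sequence (only true spliced-product reads count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .locus import Feature, FeatureSet, GeneModel
from .reads import KmerIndex, Library, RawRead, map_reads


@dataclass
class FeatureCoverage:
    """Per-feature spanning-read counts and size-normalized densities for
    one replicate library."""

    replicate_id: str
    counts: dict[str, int]
    normalized: dict[str, float]
    library_size: int


@dataclass
class ReplicateComparison:
    feature_a: str
    feature_b: str
    values_a: list[float]
    values_b: list[float]
    mean_difference: float
    p_value: float | None
    n: int
    degenerate: bool = False


def count_feature_reads(
    lib: Library,
    fs: FeatureSet,
    g: GeneModel,
    min_overhang: int | None = None,
    reference_length: int | None = None,
) -> FeatureCoverage:
    """Count reads per genomic feature and normalize by feature size.

    Exon-exon junctions in ``fs`` are reported with zero counts here; use
    :func:`count_spliced_junction_reads` for the spliced axis.
    """
    o = min_overhang if min_overhang is not None else fs.min_overhang
    if g.strand == "-":
        if reference_length is None:
            raise ValueError("reference_length required for minus-strand genes")
        g = g.oriented(reference_length)
        lib = lib.oriented(reference_length)
    starts = lib.starts
    ends = lib.starts + lib.lengths
    scale = 1e6 / lib.total_reads
    counts: dict[str, int] = {}
    normalized: dict[str, float] = {}
    for f in fs:
        if f.kind in ("exon", "intron"):
            a, b = f.interval
            if b > g.transcript_end or a < g.tss:
                raise ValueError(f"feature {f.label} outside transcript window")
            c = int(np.count_nonzero((starts < b) & (ends > a)))
        elif f.junction.kind == "exon_exon":
            c = 0  # spliced axis; counted separately
        else:
            p = f.junction.position
            c = int(np.count_nonzero((starts <= p - o) & (ends >= p + o)))
        counts[f.label] = c
        normalized[f.label] = c * scale / f.size
    return FeatureCoverage(lib.name, counts, normalized, lib.total_reads)


def count_spliced_junction_reads(
    reads: Iterable[RawRead],
    g: GeneModel,
    reference: str,
    min_overhang: int = 1,
    exclude_genomic: bool = True,
    max_hits: int = 1,
) -> dict[str, int]:
    """Count reads spanning each exon-exon junction of the spliced cDNA.

    Reads are mapped (exact, ungapped) to the spliced sequence; reads that
    also map to the unspliced genomic sequence are excluded when
    ``exclude_genomic`` (they are not evidence of a spliced product).
    Returns counts keyed like ``derive_features`` labels
    (``exon{i}_exon{i+1}_ee``).
    """
    if g.strand == "-":
        raise ValueError("orient the gene (GeneModel.oriented) before spliced counting")
    cdna = g.spliced_sequence(reference)
    reads = list(reads)
    spliced_lib = map_reads(reads, cdna, max_hits=max_hits, name="spliced")
    genomic_idx = KmerIndex(reference)
    genomic_ids: set[str] = set()
    if exclude_genomic:
        cache: dict[str, bool] = {}
        for r in reads:
            hit = cache.get(r.sequence)
            if hit is None:
                hit = bool(genomic_idx.placements(r.sequence))
                cache[r.sequence] = hit
            if hit:
                genomic_ids.add(r.id)
    junctions = g.exon_exon_positions()
    counts = {f"exon{i}_exon{i + 1}_ee": 0 for i in range(1, len(junctions) + 1)}
    for a in spliced_lib:
        if a.read_id in genomic_ids:
            continue
        for i, p in enumerate(junctions, start=1):
            if a.start <= p - min_overhang and a.start + a.length >= p + min_overhang:
                counts[f"exon{i}_exon{i + 1}_ee"] += 1
    return counts


def compare_features(
    replicates: Sequence[FeatureCoverage],
    feature_a: str | Sequence[str],
    feature_b: str | Sequence[str],
) -> ReplicateComparison:
    """Paired two-sided t-test on per-replicate normalized densities.

    ``feature_a``/``feature_b`` may be single labels or groups (averaged
    per replicate).  Replicates pair the two features within a library, so
    library-level scaling cancels.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates for a t-test")
    ga = [feature_a] if isinstance(feature_a, str) else list(feature_a)
    gb = [feature_b] if isinstance(feature_b, str) else list(feature_b)
    va = [float(np.mean([r.normalized[f] for f in ga])) for r in replicates]
    vb = [float(np.mean([r.normalized[f] for f in gb])) for r in replicates]
    diffs = np.asarray(va) - np.asarray(vb)
    mean_diff = float(diffs.mean())
    label_a = "+".join(ga)
    label_b = "+".join(gb)
    if np.allclose(diffs, diffs[0]):
        return ReplicateComparison(
            label_a, label_b, va, vb, mean_diff, None, len(replicates), degenerate=True
        )
    t = stats.ttest_rel(va, vb)
    return ReplicateComparison(
        label_a, label_b, va, vb, mean_diff, float(t.pvalue), len(replicates)
    )


def enrichment_test(
    table: Sequence[Sequence[int]] | np.ndarray,
    correction: Literal["none", "yates"] = "none",
) -> tuple[float, float]:
    """Pearson chi-square test of a 2x2 hit/non-hit contingency table.

    Used for sub-complex enrichment among screen candidates (e.g. hits
    within the Prp19/Prp19-related complexes vs all spliceosome
    components).  Returns (statistic, p).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=(correction == "yates"))
    return float(chi2), float(p)
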