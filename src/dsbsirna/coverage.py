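"""Strand-resolved siRNA coverage and the upstream/downstream cut ratio.

The central statistic: per-base reads-per-million coverage over the
transcript window, averaged separately between the TSS and the cut site
("upstream") and between the cut and the transcript 3'-end ("downstream"),
with the sgRNA-derived protospacer region excluded; their quotient
measures break-induced siRNA production.  End traces place each
sense-oriented read at its 5'-end and each antisense read at its 3'-end
(the leftmost genomic coordinate of the read for a plus-strand gene, so a
read extends downstream of the indicated position).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .locus import CutSite, GeneModel
from .reads import Library

DEFAULT_LENGTH_FILTER = (18, 24)
DEFAULT_EXCLUSION_PAD = 5


@dataclass
class CoverageTrace:
    """Per-base RPM arrays over the transcript window [tss, transcript_end)."""

    gene_id: str
    window_start: int
    window_end: int
    per_base_rpm_sense: np.ndarray
    per_base_rpm_antisense: np.ndarray
    end_trace_sense: np.ndarray
    end_trace_antisense: np.ndarray
    library_size: int

    @property
    def combined(self) -> np.ndarray:
        return self.per_base_rpm_sense + self.per_base_rpm_antisense

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrace):
            return NotImplemented
        return (
            self.window_start == other.window_start
            and self.window_end == other.window_end
            and self.library_size == other.library_size
            and np.allclose(self.per_base_rpm_sense, other.per_base_rpm_sense)
            and np.allclose(self.per_base_rpm_antisense, other.per_base_rpm_antisense)
            and np.allclose(self.end_trace_sense, other.end_trace_sense)
            and np.allclose(self.end_trace_antisense, other.end_trace_antisense)
        )


@dataclass
class RegionDensityResult:
    """Mean per-base density up/downstream of a cut and their ratio.

    ``ratio`` is ``None`` (with ``undefined=True``) when the downstream
    mean is zero — never infinity, so tabulation across replicates stays
    well-defined.
    """

    upstream_mean_rpm_per_bp: float
    downstream_mean_rpm_per_bp: float
    ratio: float | None
    undefined: bool
    excluded_interval: tuple[int, int]
    upstream_bases: int
    downstream_bases: int
    sense_ratio: float | None = None
    antisense_ratio: float | None = None


def build_coverage(
    lib: Library,
    g: GeneModel,
    read_length_filter: tuple[int, int] = DEFAULT_LENGTH_FILTER,
    reference_length: int | None = None,
) -> CoverageTrace:
    """Strand-resolved per-base RPM coverage and end-position traces.

    Sense/antisense is gene-relative; minus-strand genes (and their
    libraries) are flipped onto the transcription axis first, which
    requires ``reference_length``.  Per-base coverage counts every read
    overlapping the base; end traces count only reads wholly inside the
    window, at their 5'- (sense) or 3'- (antisense) end.
    """
    if lib.total_reads <= 0:
        raise ValueError("library_size must be positive")
    if g.strand == "-":
        if reference_length is None:
            raise ValueError("reference_length required for minus-strand genes")
        g = g.oriented(reference_length)
        lib = lib.oriented(reference_length)

    lo, hi = g.tss, g.transcript_end
    n = hi - lo
    scale = 1e6 / lib.total_reads

    starts, lengths, is_minus = lib.starts, lib.lengths, lib.is_minus
    lmin, lmax = read_length_filter
    keep = (lengths >= lmin) & (lengths <= lmax)
    starts, lengths, is_minus = starts[keep], lengths[keep], is_minus[keep]
    ends = starts + lengths

    sense_cov = np.zeros(n)
    anti_cov = np.zeros(n)
    sense_end = np.zeros(n)
    anti_end = np.zeros(n)
    # after orientation the gene is plus-strand: sense reads = plus strand
    for minus_flag, cov, endtr in ((False, sense_cov, sense_end), (True, anti_cov, anti_end)):
        sel = is_minus == minus_flag
        s, e = starts[sel], ends[sel]
        a = np.clip(s - lo, 0, n)
        b = np.clip(e - lo, 0, n)
        ov = a < b
        diff = np.zeros(n + 1)
        np.add.at(diff, a[ov], 1.0)
        np.add.at(diff, b[ov], -1.0)
        cov += np.cumsum(diff[:-1]) * scale
        # end trace: reads wholly inside the window, at their leftmost base
        # (5'-end of a sense read, 3'-end of an antisense read on the + axis)
        inside = (s >= lo) & (e <= hi)
        np.add.at(endtr, s[inside] - lo, scale)

    return CoverageTrace(
        g.gene_id, lo, hi, sense_cov, anti_cov, sense_end, anti_end, lib.total_reads
    )


def _region_mean(cov: np.ndarray, mask: np.ndarray) -> float:
    return float(cov[mask].mean()) if mask.any() else float("nan")


def cut_ratio(
    trace: CoverageTrace,
    g: GeneModel,
    cut: CutSite,
    exclusion_pad: int = DEFAULT_EXCLUSION_PAD,
    reference_length: int | None = None,
) -> RegionDensityResult:
    """Upstream/downstream mean per-base density around a cut site.

    Upstream = [tss, cut), downstream = [cut, transcript_end), both minus
    the protospacer interval padded by ``exclusion_pad`` on each side
    (reads derived from the sgRNA itself map there).  Means combine sense
    and antisense coverage; per-strand ratios are reported alongside.
    A read straddling the cut contributes its overlapped bases to each
    side (the statistic is a per-base average, not a read count).
    """
    if g.strand == "-":
        if reference_length is None:
            raise ValueError("reference_length required for minus-strand genes")
        cut = cut.oriented(reference_length, g.strand)
        g = g.oriented(reference_length)
    lo, hi = trace.window_start, trace.window_end
    if not (lo < cut.cut_position < hi):
        raise ValueError(
            f"cut {cut.cut_position} outside transcript window [{lo}, {hi})"
        )
    n = hi - lo
    pos = np.arange(lo, hi)
    ex_lo = cut.protospacer[0] - exclusion_pad
    ex_hi = cut.protospacer[1] + exclusion_pad
    excluded = (pos >= ex_lo) & (pos < ex_hi)
    up = (pos < cut.cut_position) & ~excluded
    down = (pos >= cut.cut_position) & ~excluded
    if not up.any() or not down.any():
        raise ValueError("empty upstream or downstream region after exclusion")

    def _ratio(cov: np.ndarray) -> tuple[float, float, float | None, bool]:
        um = _region_mean(cov, up)
        dm = _region_mean(cov, down)
        if dm > 0:
            return um, dm, um / dm, False
        return um, dm, None, True

    um, dm, ratio, undef = _ratio(trace.combined)
    _, _, s_ratio, _ = _ratio(trace.per_base_rpm_sense)
    _, _, a_ratio, _ = _ratio(trace.per_base_rpm_antisense)
    return RegionDensityResult(
        upstream_mean_rpm_per_bp=um,
        downstream_mean_rpm_per_bp=dm,
        ratio=ratio,
        undefined=undef,
        excluded_interval=(ex_lo, ex_hi),
        upstream_bases=int(up.sum()),
        downstream_bases=int(down.sum()),
        sense_ratio=s_ratio,
        antisense_ratio=a_ratio,
    )


# ---------------------------------------------------------------------------
# bedGraph export / import
# ---------------------------------------------------------------------------

def write_tracks(trace: CoverageTrace, out_prefix: str | Path, chrom: str = ".") -> list[Path]:
    """Write four bedGraph tracks: sense/antisense x coverage/end-trace."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tracks = {
        "sense.coverage": trace.per_base_rpm_sense,
        "antisense.coverage": trace.per_base_rpm_antisense,
        "sense.ends": trace.end_trace_sense,
        "antisense.ends": trace.end_trace_antisense,
    }
    paths = []
    for tag, arr in tracks.items():
        path = out_prefix.parent / f"{out_prefix.name}.{tag}.bedgraph"
        _write_bedgraph(arr, trace.window_start, path, chrom)
        paths.append(path)
    return paths


def _write_bedgraph(arr: np.ndarray, offset: int, path: Path, chrom: str) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{path.stem}"\n')
        if len(arr) == 0:
            return
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        for a, b in zip(starts, ends):
            v = arr[a]
            if v != 0:
                fh.write(f"{chrom}\t{offset + a}\t{offset + b}\t{v:.10g}\n")


def read_bedgraph(path: str | Path, window: tuple[int, int]) -> np.ndarray:
    """Inverse of the bedGraph writer over a known window (zeros elsewhere)."""
    lo, hi = window
    arr = np.zeros(hi - lo)
    for line in open(path):
        if line.startswith(("track", "#")) or not line.strip():
            continue
        _, a, b, v = line.split()
        a, b = max(int(a), lo), min(int(b), hi)
        if a < b:
            arr[a - lo : b - lo] = float(v)
    return arr
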