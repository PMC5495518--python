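"""Small-RNA read processing at locus scale.

FASTQ in (gzip-transparent, via Biopython), barcode demultiplexing,
3'-adapter trimming and an ungapped, mismatch-free k-mer-index mapper that
stands in for a genome aligner when the reference is a single locus of a
few kilobases.  Externally mapped reads can be ingested from SAM (via
pysam) or BED6.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 24


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


@dataclass(frozen=True)
class AlignedRead:
    """An ungapped placement; ``start`` is the leftmost reference base,
    ``strand`` is relative to the reference (+ = reference orientation)."""

    start: int
    length: int
    strand: Literal["+", "-"]
    read_id: str = ""


class Library:
    """Mapped reads of one sequencing library.

    Placements are held in parallel numpy arrays (memory-lean for large
    simulated libraries); iteration yields :class:`AlignedRead`.
    ``total_reads`` is the reads-per-million denominator.
    """

    def __init__(
        self,
        name: str,
        total_reads: int,
        starts: np.ndarray | Sequence[int] = (),
        lengths: np.ndarray | Sequence[int] = (),
        strands: np.ndarray | Sequence[bool] = (),
        read_ids: Sequence[str] | None = None,
        stats: dict | None = None,
    ) -> None:
        self.name = name
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        # True = minus strand
        self.is_minus = np.asarray(strands, dtype=bool)
        self.read_ids = list(read_ids) if read_ids is not None else None
        self.stats = stats or {}
        if not (len(self.starts) == len(self.lengths) == len(self.is_minus)):
            raise ValueError("parallel placement arrays must have equal length")
        if total_reads < len(self.starts):
            # placements may exceed reads only through multi-hits; callers
            # pass the true read count, so guard against nonsense here
            if not self.stats.get("multi_hit_placements"):
                raise ValueError("total_reads smaller than number of aligned reads")
        self.total_reads = int(total_reads)

    @classmethod
    def from_aligned(
        cls, name: str, aligned: Iterable[AlignedRead], total_reads: int,
        stats: dict | None = None,
    ) -> "Library":
        aligned = list(aligned)
        return cls(
            name,
            total_reads,
            [a.start for a in aligned],
            [a.length for a in aligned],
            [a.strand == "-" for a in aligned],
            [a.read_id for a in aligned],
            stats,
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[AlignedRead]:
        ids = self.read_ids
        for i in range(len(self.starts)):
            yield AlignedRead(
                int(self.starts[i]),
                int(self.lengths[i]),
                "-" if self.is_minus[i] else "+",
                ids[i] if ids is not None else f"{self.name}_{i}",
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Library):
            return NotImplemented
        return (
            self.total_reads == other.total_reads
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.lengths, other.lengths)
            and np.array_equal(self.is_minus, other.is_minus)
        )

    def oriented(self, reference_length: int) -> "Library":
        """Flip placements onto the reverse-complemented reference axis."""
        return Library(
            self.name,
            self.total_reads,
            reference_length - (self.starts + self.lengths),
            self.lengths,
            ~self.is_minus,
            self.read_ids,
            self.stats,
        )


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield RawRead(
                rec.id,
                str(rec.seq).upper(),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            q = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{q}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# demultiplexing and trimming
# ---------------------------------------------------------------------------

@dataclass
class DemuxResult:
    libraries: dict[str, list[RawRead]]
    unassigned: list[RawRead]

    @property
    def unassigned_count(self) -> int:
        return len(self.unassigned)


def demultiplex(reads: Iterable[RawRead], barcodes: dict[str, str]) -> DemuxResult:
    """Assign each read to the library whose barcode exactly matches its
    5' prefix; the barcode is stripped.  Non-matching reads go to the
    unassigned bin."""
    seqs = list(barcodes.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate barcode sequences")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("barcodes must have equal length")
    blen = len(seqs[0])
    by_seq = {v: k for k, v in barcodes.items()}
    out: dict[str, list[RawRead]] = {k: [] for k in barcodes}
    unassigned: list[RawRead] = []
    for r in reads:
        label = by_seq.get(r.sequence[:blen])
        if label is None:
            unassigned.append(r)
        else:
            out[label].append(
                RawRead(r.id, r.sequence[blen:], r.quality[blen:] if r.quality else None)
            )
    return DemuxResult(out, unassigned)


def trim_adapter(
    read: RawRead,
    adapter: str,
    min_overlap: int = 5,
    min_len: int = DEFAULT_MIN_LEN,
) -> RawRead | None:
    """Remove the 3' adapter from one read; ``None`` if too short after.

    A full internal adapter occurrence removes the adapter and everything
    3' of it; otherwise the longest read suffix that exactly matches an
    adapter prefix of length >= ``min_overlap`` is removed.
    """
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    seq = read.sequence
    pos = seq.find(adapter)
    if pos >= 0:
        cut = pos
    else:
        cut = len(seq)
        for k in range(min(len(seq), len(adapter) - 1), min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    if cut < min_len:
        return None
    if cut == len(seq):
        return read
    return RawRead(read.id, seq[:cut], read.quality[:cut] if read.quality else None)


@dataclass
class TrimResult:
    kept: list[RawRead]
    rejected: int


def trim_adapters(
    reads: Iterable[RawRead],
    adapter: str,
    min_overlap: int = 5,
    min_len: int = DEFAULT_MIN_LEN,
) -> TrimResult:
    kept, rejected = [], 0
    for r in reads:
        t = trim_adapter(r, adapter, min_overlap, min_len)
        if t is None:
            rejected += 1
        else:
            kept.append(t)
    return TrimResult(kept, rejected)


# ---------------------------------------------------------------------------
# exact ungapped mapper
# ---------------------------------------------------------------------------

class KmerIndex:
    """Seed-and-verify exact matcher over a single reference sequence.

    Seeds of length ``k`` are indexed; a query is placed wherever its first
    k-mer seeds and the full sequence matches without mismatches or gaps.
    Matches on the minus strand are found by querying the reverse
    complement; the reported start is always the leftmost reference base.
    """

    def __init__(self, reference: str, k: int = 12) -> None:
        if not reference:
            raise ValueError("empty reference")
        self.reference = reference.upper()
        self.k = min(k, len(self.reference))
        self._index: dict[str, list[int]] = {}
        for i in range(len(self.reference) - self.k + 1):
            self._index.setdefault(self.reference[i : i + self.k], []).append(i)

    def _occurrences(self, seq: str) -> list[int]:
        if len(seq) < self.k:
            # short query: fall back to direct scan
            out, p = [], self.reference.find(seq)
            while p >= 0:
                out.append(p)
                p = self.reference.find(seq, p + 1)
            return out
        ref = self.reference
        return [
            p for p in self._index.get(seq[: self.k], ())
            if ref.startswith(seq, p)
        ]

    def placements(self, seq: str) -> list[AlignedRead]:
        """All exact placements of ``seq`` on both strands."""
        seq = seq.upper()
        if "N" in seq or not seq:
            return []
        hits = [AlignedRead(p, len(seq), "+") for p in self._occurrences(seq)]
        rc = reverse_complement(seq)
        minus = [AlignedRead(p, len(seq), "-") for p in self._occurrences(rc)]
        if rc == seq:  # palindromic read: one placement per locus, call it +
            return hits
        return hits + minus


def map_reads(
    reads: Iterable[RawRead],
    reference: str,
    max_hits: int = 1,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    rpm_denominator: Literal["input", "mapped"] = "input",
    name: str = "library",
    index: KmerIndex | None = None,
) -> Library:
    """Map reads to a locus reference, exact-match, ungapped, both strands.

    Reads with 1..``max_hits`` placements contribute all their placements;
    reads with more are discarded as multi-mappers; reads containing N or
    outside the length filter are unmapped.  ``total_reads`` follows
    ``rpm_denominator`` ('input': all reads entering mapping, the default;
    'mapped': only reads that produced placements).
    """
    idx = index or KmerIndex(reference)
    cache: dict[str, list[AlignedRead]] = {}
    starts: list[int] = []
    lengths: list[int] = []
    minus: list[bool] = []
    ids: list[str] = []
    n_input = n_mapped = n_unmapped = n_multi = n_filtered = 0
    for r in reads:
        n_input += 1
        if not (min_len <= len(r.sequence) <= max_len):
            n_filtered += 1
            continue
        seq = r.sequence
        hits = cache.get(seq)
        if hits is None:
            hits = idx.placements(seq)
            cache[seq] = hits
        if not hits:
            n_unmapped += 1
        elif len(hits) > max_hits:
            n_multi += 1
        else:
            n_mapped += 1
            for h in hits:
                starts.append(h.start)
                lengths.append(h.length)
                minus.append(h.strand == "-")
                ids.append(r.id)
    stats = {
        "input": n_input,
        "mapped": n_mapped,
        "unmapped": n_unmapped,
        "multi_hit_discarded": n_multi,
        "length_filtered": n_filtered,
        "multi_hit_placements": max_hits > 1,
    }
    total = n_input if rpm_denominator == "input" else n_mapped
    return Library(name, total, starts, lengths, minus, ids, stats)


# ---------------------------------------------------------------------------
# SAM / BED6 ingestion and export
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path, reference_name: str, name: str | None = None) -> Library:
    """Ingest externally mapped reads from SAM or BED6.

    SAM: POS is 1-based (converted), flag 16 = minus strand; unmapped
    records are skipped but counted into ``total_reads``.  BED6 is 0-based
    half-open with the strand in column 6.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return _read_sam(path, reference_name, name or path.stem)
    return _read_bed6(path, reference_name, name or path.stem)


def _read_sam(path: Path, reference_name: str, name: str) -> Library:
    starts, lengths, minus, ids = [], [], [], []
    total = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            total += 1
            if rec.is_unmapped:
                continue
            if rec.reference_name != reference_name:
                continue
            starts.append(rec.reference_start)
            lengths.append(rec.query_length or rec.reference_length)
            minus.append(rec.is_reverse)
            ids.append(rec.query_name)
    return Library(name, total, starts, lengths, minus, ids, {"input": total})


def _read_bed6(path: Path, reference_name: str, name: str) -> Library:
    starts, lengths, minus, ids = [], [], [], []
    total = 0
    for lineno, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
        if cols[0] != reference_name:
            continue
        try:
            a, b = int(cols[1]), int(cols[2])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from e
        total += 1
        starts.append(a)
        lengths.append(b - a)
        minus.append(cols[5] == "-")
        ids.append(cols[3])
    return Library(name, total, starts, lengths, minus, ids, {"input": total})


def write_bed6(lib: Library, path: str | Path, reference_name: str) -> None:
    with open(Path(path), "w") as fh:
        for a in lib:
            fh.write(
                f"{reference_name}\t{a.start}\t{a.start + a.length}\t{a.read_id}\t0\t{a.strand}\n"
            )


def write_sam(lib: Library, path: str | Path, reference_name: str, reference_length: int) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in lib:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.read_id or "read"
            rec.flag = 16 if a.strand == "-" else 0
            rec.reference_id = 0
            rec.reference_start = a.start
            rec.mapping_quality = 255
            rec.cigarstring = f"{a.length}M"
            rec.query_sequence = "N" * a.length
            out.write(rec)
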