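"""Gene models, cut sites and derived splice features.

Coordinates are 0-based, half-open everywhere inside the package; GFF3
(1-based, closed) and BED12 (0-based, half-open) conversions happen only in
the readers/writers.  A gene is a single transcript model: a transcription
start, a transcript end and an ordered list of exons whose gaps are the
introns.  Minus-strand genes are re-oriented onto the transcription axis
(via :meth:`GeneModel.oriented`) before any coverage analysis, so that
"upstream" always means 5' of the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

Interval = tuple[int, int]

JunctionKind = Literal["exon_intron_5p", "intron_exon_3p", "exon_exon"]
FeatureKind = Literal["exon", "intron", "junction"]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class GeneNotFoundError(KeyError):
    """Requested gene id absent from an annotation file."""


@dataclass(frozen=True)
class GeneModel:
    """Single-isoform transcript model on the genomic axis.

    ``exons`` are non-overlapping half-open intervals sorted by genomic
    coordinate; for a minus-strand gene transcription order is the reverse
    of the stored order.  ``tss``/``transcript_end`` bound the exons
    (``tss`` is the leftmost genomic base of the transcript window; the
    biological start of a minus-strand transcript is ``transcript_end-1``).
    """

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    tss: int
    transcript_end: int
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError("gene model needs at least one exon")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for a, b in exons:
            if b - a < 1:
                raise AnnotationError(f"exon {a}-{b} has length < 1")
            if prev_end is not None and a < prev_end + 1:
                raise AnnotationError("exons overlap or abut without an intron")
            prev_end = b
        if exons[0][0] != self.tss or exons[-1][1] != self.transcript_end:
            raise AnnotationError(
                "tss/transcript_end must bound the exons "
                f"({self.tss}, {self.transcript_end}) vs {exons}"
            )

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        """Transcript window length (exons + introns)."""
        return self.transcript_end - self.tss

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def oriented(self, reference_length: int) -> "GeneModel":
        """Return an equivalent plus-strand model on the transcription axis.

        For a plus-strand gene this is the identity.  For a minus-strand
        gene coordinates are flipped onto the reverse-complemented
        reference (x -> reference_length - x), so downstream analyses can
        treat every gene as plus-strand.
        """
        if self.strand == "+":
            return self
        L = reference_length
        exons = tuple(
            sorted((L - b, L - a) for a, b in self.exons)
        )
        return GeneModel(
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand="+",
            tss=L - self.transcript_end,
            transcript_end=L - self.tss,
            exons=exons,
        )

    def spliced_sequence(self, reference: str) -> str:
        """cDNA sequence of the transcript given the reference (plus axis)."""
        return "".join(reference[a:b] for a, b in self.exons)

    def exon_exon_positions(self) -> tuple[int, ...]:
        """Exon-exon junction positions on the spliced (cDNA) axis."""
        out, cum = [], 0
        for a, b in self.exons[:-1]:
            cum += b - a
            out.append(cum)
        return tuple(out)


@dataclass(frozen=True)
class Junction:
    """A boundary between two adjacent bases.

    ``position`` is the 0-based index of the first base after the boundary.
    ``exon_exon`` junctions live on the spliced (cDNA) axis; the genomic
    kinds on the genomic axis.
    """

    kind: JunctionKind
    position: int
    flanking: tuple[str, str]


@dataclass(frozen=True)
class CutSite:
    """A cas9 cut: the blunt-cut boundary plus the sgRNA protospacer."""

    cut_position: int
    protospacer: Interval
    label: str = ""

    def __post_init__(self) -> None:
        a, b = self.protospacer
        if b <= a:
            raise AnnotationError("protospacer interval empty")
        if not (a - 1 <= self.cut_position <= b + 1):
            raise AnnotationError(
                f"cut {self.cut_position} not inside/adjacent to protospacer {a}-{b}"
            )

    def oriented(self, reference_length: int, strand: str) -> "CutSite":
        if strand == "+":
            return self
        L = reference_length
        a, b = self.protospacer
        return CutSite(L - self.cut_position, (L - b, L - a), self.label)


@dataclass(frozen=True)
class Feature:
    """One exon, intron or junction with its normalization size."""

    label: str
    kind: FeatureKind
    interval: Interval | None
    junction: Junction | None
    size: int


@dataclass(frozen=True)
class FeatureSet:
    features: tuple[Feature, ...]
    read_length: int
    min_overhang: int

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def labels(self, kind: str | None = None) -> list[str]:
        return [f.label for f in self.features if kind is None or f.kind == kind]


def junction_size(read_length: int, min_overhang: int) -> int:
    """Number of distinct start positions of a read spanning a junction."""
    return read_length - 2 * min_overhang + 1


def derive_features(
    g: GeneModel, read_length: int = 21, min_overhang: int = 1
) -> FeatureSet:
    """Enumerate exons, introns and junctions with normalization sizes.

    Genomic junctions (``exon_intron_5p`` at each exon->intron boundary,
    ``intron_exon_3p`` at each intron->exon boundary) are positioned on the
    genomic axis in transcription order; ``exon_exon`` junctions on the
    spliced axis.  Junction size is the spanning-start count
    ``read_length - 2*min_overhang + 1``.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if read_length < 2 * min_overhang:
        raise ValueError("read_length must be >= 2*min_overhang")
    jsize = junction_size(read_length, min_overhang)
    feats: list[Feature] = []
    for i, (a, b) in enumerate(g.exons, start=1):
        feats.append(Feature(f"exon{i}", "exon", (a, b), None, b - a))
    for i, (a, b) in enumerate(g.introns, start=1):
        feats.append(Feature(f"intron{i}", "intron", (a, b), None, b - a))
        feats.append(
            Feature(
                f"exon{i}_intron{i}_5p",
                "junction",
                None,
                Junction("exon_intron_5p", a, (f"exon{i}", f"intron{i}")),
                jsize,
            )
        )
        feats.append(
            Feature(
                f"intron{i}_exon{i + 1}_3p",
                "junction",
                None,
                Junction("intron_exon_3p", b, (f"intron{i}", f"exon{i + 1}")),
                jsize,
            )
        )
    for i, pos in enumerate(g.exon_exon_positions(), start=1):
        feats.append(
            Feature(
                f"exon{i}_exon{i + 1}_ee",
                "junction",
                None,
                Junction("exon_exon", pos, (f"exon{i}", f"exon{i + 1}")),
                jsize,
            )
        )
    return FeatureSet(tuple(feats), read_length, min_overhang)


# ---------------------------------------------------------------------------
# annotation I/O (GFF3 1-based closed, BED12 0-based half-open)
# ---------------------------------------------------------------------------

def read_gene_model(path: str | Path, gene_id: str) -> GeneModel:
    """Read one gene from a GFF3 or BED12 file (format chosen by extension,
    falling back to content sniffing)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path, gene_id)
    if suffix == ".bed":
        return _read_bed12(path, gene_id)
    # sniff: BED12 lines have 12 whitespace fields with numeric col 2
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            n = len(line.split())
            return _read_bed12(path, gene_id) if n == 12 else _read_gff3(path, gene_id)
    raise AnnotationError(f"{path}: empty annotation file")


def _read_gff3(path: Path, gene_id: str) -> GeneModel:
    exons: list[Interval] = []
    chrom = strand = None
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise AnnotationError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
        seqid, _source, ftype, start, end, _score, st, _phase, attrs = cols
        attr = _parse_gff_attrs(attrs, path, lineno)
        owner = attr.get("Parent", attr.get("ID", attr.get("gene_id", "")))
        if ftype.lower() != "exon" or owner != gene_id:
            continue
        try:
            a, b = int(start) - 1, int(end)  # 1-based closed -> 0-based half-open
        except ValueError as e:
            raise AnnotationError(f"{path}:{lineno}: non-numeric coordinate") from e
        if b <= a:
            raise AnnotationError(f"{path}:{lineno}: empty interval {start}..{end}")
        exons.append((a, b))
        chrom, strand = seqid, st
    if not exons:
        raise GeneNotFoundError(f"gene {gene_id!r} not found in {path}")
    exons.sort()
    return GeneModel(gene_id, chrom, strand, exons[0][0], exons[-1][1], tuple(exons))


def _parse_gff_attrs(attrs: str, path: Path, lineno: int) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise AnnotationError(f"{path}:{lineno}: malformed attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def _read_bed12(path: Path, gene_id: str) -> GeneModel:
    for lineno, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) != 12:
            raise AnnotationError(f"{path}:{lineno}: expected 12 BED12 columns, got {len(cols)}")
        if cols[3] != gene_id:
            continue
        try:
            chrom_start = int(cols[1])
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
        except ValueError as e:
            raise AnnotationError(f"{path}:{lineno}: non-numeric BED12 field") from e
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise AnnotationError(f"{path}:{lineno}: block count mismatch")
        exons = tuple(
            (chrom_start + s, chrom_start + s + sz) for s, sz in zip(starts, sizes)
        )
        return GeneModel(
            gene_id, cols[0], cols[5], exons[0][0], exons[-1][1], exons
        )
    raise GeneNotFoundError(f"gene {gene_id!r} not found in {path}")


def write_gene_model(g: GeneModel, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("bed12" if path.suffix.lower() == ".bed" else "gff3")
    with open(path, "w") as fh:
        if fmt == "bed12":
            sizes = ",".join(str(b - a) for a, b in g.exons)
            starts = ",".join(str(a - g.tss) for a, b in g.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.tss, g.transcript_end, g.gene_id, 0, g.strand,
                        g.tss, g.transcript_end, 0, len(g.exons), sizes, starts,
                    )
                )
                + "\n"
            )
        elif fmt == "gff3":
            fh.write("##gff-version 3\n")
            fh.write(
                "\t".join(
                    (
                        g.chrom, "dsbsirna", "gene", str(g.tss + 1),
                        str(g.transcript_end), ".", g.strand, ".", f"ID={g.gene_id}",
                    )
                )
                + "\n"
            )
            for a, b in g.exons:
                fh.write(
                    "\t".join(
                        (
                            g.chrom, "dsbsirna", "exon", str(a + 1), str(b),
                            ".", g.strand, ".", f"Parent={g.gene_id}",
                        )
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_cut_sites(path: str | Path) -> list[CutSite]:
    """Cut sites from 4-column TSV (chrom, cut, proto_start, proto_end) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            entries = yaml.safe_load(fh) or []
        return [
            CutSite(
                int(e["cut_position"]),
                (int(e["protospacer_start"]), int(e["protospacer_end"])),
                str(e.get("label", "")),
            )
            for e in entries
        ]
    sites = []
    for lineno, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 4:
            raise AnnotationError(f"{path}:{lineno}: expected >= 4 columns")
        sites.append(
            CutSite(
                int(cols[1]), (int(cols[2]), int(cols[3])),
                cols[4] if len(cols) > 4 else cols[0],
            )
        )
    return sites


def write_cut_sites(sites: Sequence[CutSite], path: str | Path, chrom: str = ".") -> None:
    with open(Path(path), "w") as fh:
        for s in sites:
            fh.write(
                f"{chrom}\t{s.cut_position}\t{s.protospacer[0]}\t{s.protospacer[1]}\t{s.label}\n"
            )
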