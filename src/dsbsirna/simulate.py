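"""Synthetic inputs with recorded ground truth.

Three generators mirror the three assays the package analyzes:

* :func:`simulate_sirna_library` — a small-RNA library from a cut locus.
  The positional model is piecewise-uniform: a uniform background over the
  whole transcript plus an induced component confined to the zone between
  the TSS and the cut (the break-induced siRNA-producing region, sense
  reads from the unspliced pre-mRNA and antisense reads from its reverse
  complement), weighted so the expected upstream/downstream per-base
  density ratio equals ``induction_ratio``; plus an artifactual read peak
  from the sgRNA itself at the protospacer.  Cuts in intron-less genes or
  upstream of the first intron damp the induced component, emulating the
  splicing requirement.  Sense reads are genomic substrings, so no
  simulated read ever spans an exon-exon junction on the spliced axis.
* :func:`simulate_screen` — replicate 384-well dual-luciferase plates with
  positive/negative/Renilla/thread controls, multiplicative plate effects,
  a power-law FLuc-RLuc coupling and spiked hits acting on RLuc only.
* :func:`simulate_qpcr` — long-format Ct tables with planted fold changes
  (Ct = baseline - log2(fold) + Gaussian noise).

Identical seed + config give byte-identical written outputs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from . import screen as scr
from .locus import CutSite, GeneModel, write_cut_sites, write_gene_model
from .qpcr import AMPLICON_PRE, AMPLICON_SPLICED, AMPLICON_TOTAL, CT_COLUMNS
from .reads import RawRead, reverse_complement, write_fasta, write_fastq

# CG15098-like default layout: four exons separated by three short introns,
# ~3 kb transcript (coordinates relative to the transcript start)
DEFAULT_EXON_LAYOUT = ((0, 300), (360, 1500), (1560, 2400), (2460, 3000))


@dataclass
class LocusSimConfig:
    """Stated world of one cut-locus small-RNA library."""

    exon_layout: tuple[tuple[int, int], ...] = DEFAULT_EXON_LAYOUT
    intronless: bool = False
    cut_position: int = 1800          # relative to the transcript start
    induction_ratio: float = 20.0     # target upstream/downstream density ratio
    sgrna_peak_fraction: float = 0.02
    background_rate: float = 1.0      # relative per-base background weight
    expression: float = 1.0           # relative host-gene expression
    unspliced_damping: float = 0.03   # induction multiplier without an upstream intron
    read_length: int = 21
    library_size: int = 1_000_000
    flank: int = 100
    gene_id: str = "simgene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.induction_ratio < 1:
            raise ValueError("induction_ratio must be >= 1")
        if not 0 <= self.sgrna_peak_fraction <= 1:
            raise ValueError("sgrna_peak_fraction must be in [0, 1]")
        if self.intronless:
            self.exon_layout = ((0, self.exon_layout[-1][1]),)


@dataclass
class SimulatedLibrary:
    """A generated library plus its ground truth.

    Reads are stored as placement arrays (memory-lean for 1e6-read
    libraries); :meth:`iter_reads` materializes them as sequences.
    """

    config: LocusSimConfig
    reference: str
    gene: GeneModel
    cut: CutSite
    starts: np.ndarray
    lengths: np.ndarray
    is_minus: np.ndarray
    is_sgrna: np.ndarray
    truth: dict

    def iter_reads(self) -> Iterator[RawRead]:
        ref = self.reference
        for i in range(len(self.starts)):
            s, l = int(self.starts[i]), int(self.lengths[i])
            seq = ref[s : s + l]
            if self.is_minus[i]:
                seq = reverse_complement(seq)
            tag = "sg" if self.is_sgrna[i] else ("as" if self.is_minus[i] else "s")
            yield RawRead(f"sim_{i}_{tag}", seq)

    @property
    def reads(self) -> list[RawRead]:
        return list(self.iter_reads())

    def write(self, out_dir: str | Path, name: str = "simlib") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": out / f"{name}.fastq",
            "fasta": out / f"{name}.fa",
            "gene": out / f"{name}.bed",
            "cuts": out / f"{name}.cuts.tsv",
            "truth": out / f"{name}.truth.yaml",
        }
        write_fastq(self.iter_reads(), paths["fastq"])
        write_fasta({self.gene.chrom: self.reference}, paths["fasta"])
        write_gene_model(self.gene, paths["gene"], fmt="bed12")
        write_cut_sites([self.cut], paths["cuts"], chrom=self.gene.chrom)
        with open(paths["truth"], "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=True)
        return paths


def simulate_sirna_library(cfg: LocusSimConfig) -> SimulatedLibrary:
    rng = np.random.default_rng(cfg.seed)
    glen = cfg.exon_layout[-1][1]
    if not (0 < cfg.cut_position < glen):
        raise ValueError("cut_position must lie inside the transcript")
    L = cfg.read_length
    flank = cfg.flank
    ref_len = glen + 2 * flank
    reference = "".join(
        rng.choice(np.array(list("ACGT")), size=ref_len)
    )
    exons = tuple((a + flank, b + flank) for a, b in cfg.exon_layout)
    gene = GeneModel(cfg.gene_id, "simlocus", "+", flank, flank + glen, exons)
    cut_gen = flank + cfg.cut_position
    proto = (max(cut_gen - 17, 0), min(cut_gen + 3, ref_len))
    cut = CutSite(cut_gen, proto, label=f"cut@{cfg.cut_position}")

    introns = gene.introns
    damped = cfg.intronless or (not introns) or cut_gen <= introns[0][0]
    factor = cfg.unspliced_damping if damped else 1.0
    r_eff = 1.0 + (cfg.induction_ratio - 1.0) * factor * cfg.expression

    N = cfg.library_size
    n_sg = int(round(cfg.sgrna_peak_fraction * N))
    n_rest = N - n_sg
    tss, tend = gene.tss, gene.transcript_end
    U, T = cut_gen - tss, tend - tss
    if r_eff > 1.0 and cut_gen - L < tss:
        raise ValueError(
            f"cut at {cfg.cut_position} leaves no room for induced reads; "
            f"need cut_position >= read_length ({L}) for induction_ratio > 1"
        )
    n_bg = int(round(n_rest / (1.0 + (U / T) * (r_eff - 1.0))))
    n_ind = n_rest - n_bg

    bg_starts = rng.integers(tss, tend - L + 1, size=n_bg)
    ind_starts = (
        rng.integers(tss, cut_gen - L + 1, size=n_ind)
        if n_ind
        else np.empty(0, dtype=np.int64)
    )
    sg_starts = np.full(n_sg, proto[0], dtype=np.int64)
    starts = np.concatenate([bg_starts, ind_starts, sg_starts])
    lengths = np.concatenate(
        [np.full(n_bg + n_ind, L, dtype=np.int64), np.full(n_sg, proto[1] - proto[0], dtype=np.int64)]
    )
    is_minus = np.concatenate(
        [rng.random(n_bg + n_ind) < 0.5, np.zeros(n_sg, dtype=bool)]
    )
    is_sg = np.concatenate([np.zeros(n_bg + n_ind, dtype=bool), np.ones(n_sg, dtype=bool)])
    truth = {
        "seed": cfg.seed,
        "library_size": N,
        "n_background": int(n_bg),
        "n_induced": int(n_ind),
        "n_sgrna": int(n_sg),
        "induction_ratio_target": float(cfg.induction_ratio),
        "induction_ratio_effective": float(r_eff),
        "damped": bool(damped),
        "cut_position_genomic": int(cut_gen),
        "protospacer": [int(proto[0]), int(proto[1])],
        "gene_id": cfg.gene_id,
        "exon_layout": [list(map(int, e)) for e in cfg.exon_layout],
        "read_length": int(L),
    }
    return SimulatedLibrary(
        cfg, reference, gene, cut, starts, lengths, is_minus, is_sg, truth
    )


# ---------------------------------------------------------------------------
# screen plates
# ---------------------------------------------------------------------------

@dataclass
class PlateSimConfig:
    """Stated world of a replicated 384-well dual-luciferase screen."""

    n_plates: int = 3                 # replicate plates of one layout
    n_rows: int = 16
    n_cols: int = 24
    baseline_fluc: float = 1e5
    baseline_rluc: float = 5e4
    plate_effect_sd: float = 0.15     # log-scale multiplicative, per channel
    well_sd_fluc: float = 0.25        # transfection spread (log scale)
    noise_sd: float = 0.10            # residual RLuc channel noise (log scale)
    rluc_fluc_coupling: float = 1.0   # RLuc ~ FLuc^b baseline coupling
    n_spiked: int = 15
    spike_effect: float = 3.0         # in residual-SD units, on RLuc only
    spiked_hits: dict[str, float] | None = None
    pos_ctrl_effect: float = 6.0
    rluc_ctrl_effect: float = -6.0
    thread_fluc_factor: float = 0.02  # dead-cell signal collapse
    seed: int = 0


def _plate_layout(cfg: PlateSimConfig) -> pd.DataFrame:
    """Fixed control layout on row A; all remaining wells are sample genes."""
    rows = []
    gene_no = 0
    ctrl = (
        [("pos_ctrl:Ago2", "Ago2"), ("pos_ctrl:Dcr-2", "Dcr-2"), ("pos_ctrl:Ago1", "Ago1")]
        + [("neg_ctrl:GFP", "GFP")] * 4
        + [("neg_ctrl:DsRed", "DsRed")] * 4
        + [(scr.RLUC_CTRL, "Rluc")] * 2
        + [(scr.THREAD_CTRL, "thread")] * 4
    )
    for r in range(cfg.n_rows):
        for c in range(cfg.n_cols):
            well = f"{chr(ord('A') + r)}{c + 1:02d}"
            if r == 0 and c < len(ctrl):
                ann, gene = ctrl[c]
            else:
                gene_no += 1
                ann, gene = scr.SAMPLE, f"gene_{gene_no:04d}"
            rows.append((well, ann, gene))
    return pd.DataFrame(rows, columns=["well", "annotation", "target_gene"])


def simulate_screen(cfg: PlateSimConfig) -> tuple[pd.DataFrame, dict]:
    """Two-channel plate data in long format plus the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    layout = _plate_layout(cfg)
    genes = layout.loc[layout["annotation"] == scr.SAMPLE, "target_gene"].tolist()
    if cfg.spiked_hits is not None:
        hits = dict(cfg.spiked_hits)
    else:
        chosen = rng.choice(genes, size=min(cfg.n_spiked, len(genes)), replace=False)
        hits = {str(g): cfg.spike_effect for g in chosen}

    frames = []
    for p in range(cfg.n_plates):
        plate_id = f"plate_{p + 1:02d}"
        pe_f = rng.normal(0.0, cfg.plate_effect_sd)
        pe_r = rng.normal(0.0, cfg.plate_effect_sd)
        n = len(layout)
        e1 = rng.normal(0.0, cfg.well_sd_fluc, size=n)
        e2 = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
        log_f = math.log(cfg.baseline_fluc) + pe_f + e1
        log_r = (
            math.log(cfg.baseline_rluc)
            + pe_r
            + cfg.rluc_fluc_coupling * e1
            + e2
        )
        effect = np.zeros(n)
        ann = layout["annotation"].to_numpy()
        tgt = layout["target_gene"].to_numpy()
        effect[np.isin(ann, list(scr.POS_CTRL))] = cfg.pos_ctrl_effect * cfg.noise_sd
        effect[ann == scr.RLUC_CTRL] = cfg.rluc_ctrl_effect * cfg.noise_sd
        for g, e in hits.items():
            effect[tgt == g] = e * cfg.noise_sd
        log_r = log_r + effect
        thread = ann == scr.THREAD_CTRL
        log_f = np.where(thread, log_f + math.log(cfg.thread_fluc_factor), log_f)
        log_r = np.where(thread, log_r + math.log(cfg.thread_fluc_factor), log_r)
        frame = layout.copy()
        frame.insert(0, "plate_id", plate_id)
        frame["fluc_raw"] = np.exp(log_f)
        frame["rluc_raw"] = np.exp(log_r)
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)[scr.PLATE_COLUMNS]
    truth = {
        "seed": cfg.seed,
        "n_plates": cfg.n_plates,
        "spiked_hits": {k: float(v) for k, v in sorted(hits.items())},
        "noise_sd": cfg.noise_sd,
        "n_sample_genes": len(genes),
    }
    return df, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def _default_baseline() -> dict[str, float]:
    # spliced message ~ total transcript (Ct gap 0.2 cycles); pre-mRNA a
    # small fraction of the steady-state pool (8 cycles ~ 0.4%)
    return {AMPLICON_PRE: 28.0, AMPLICON_SPLICED: 20.2, AMPLICON_TOTAL: 20.0}


@dataclass
class QpcrSimConfig:
    """Stated world of a Ct table with planted fold changes."""

    baseline_ct: dict[str, float] = field(default_factory=_default_baseline)
    # (condition, amplicon) -> fold relative to baseline; unlisted pairs are 1
    planted_folds: dict[tuple[str, str], float] = field(default_factory=dict)
    conditions: tuple[str, ...] = ("control", "cut")
    noise_sd: float = 0.1
    replicates: int = 3
    sample: str = "locus"
    seed: int = 0


def simulate_qpcr(cfg: QpcrSimConfig) -> tuple[pd.DataFrame, dict]:
    """Ct = baseline - log2(planted fold) + Gaussian noise, per replicate."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for cond in cfg.conditions:
        for amp, base in cfg.baseline_ct.items():
            fold = cfg.planted_folds.get((cond, amp), 1.0)
            for rep in range(1, cfg.replicates + 1):
                noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
                rows.append(
                    (cfg.sample, amp, cond, rep, base - math.log2(fold) + noise)
                )
    df = pd.DataFrame(rows, columns=CT_COLUMNS)
    truth = {
        "seed": cfg.seed,
        "planted_folds": {f"{c}|{a}": float(f) for (c, a), f in sorted(cfg.planted_folds.items())},
        "noise_sd": cfg.noise_sd,
        "replicates": cfg.replicates,
    }
    return df, truth
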