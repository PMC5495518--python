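"""Dual-luciferase RNAi screen scoring.

Pipeline, per the classic plate-screen recipe: per-channel log transform
and plate-median centering (median of the sample wells; no variance
adjustment), exclusion of predominantly-dead wells via the thread
(apoptosis-inhibitor) controls, a LOESS fit of normalized Renilla on
normalized firefly signal (span 0.9, tricube weights, local polynomial),
LOESS residuals ("resi") standardized into z-scores against the
sample-well residual distribution, and candidate calls at thresholds set
from the negative-control (GFP/DsRed knockdown) z distribution at
mean +/- 1 SD.

Sign convention: the Renilla reporter is repressed by break-induced
siRNAs, so knocking down a factor *required* for siRNA biogenesis
de-represses RLuc — a positive residual.  Genes whose mean z exceeds the
upper threshold are positive candidates (siRNA-pathway stimulators); genes
below the lower threshold are negative candidates (repressors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

SAMPLE = "sample"
POS_CTRL = {"pos_ctrl:Ago2", "pos_ctrl:Dcr-2", "pos_ctrl:Ago1"}
NEG_CTRL = {"neg_ctrl:GFP", "neg_ctrl:DsRed"}
RLUC_CTRL = "rluc_ctrl"
THREAD_CTRL = "thread_ctrl"
EMPTY = "empty"

PLATE_COLUMNS = ["plate_id", "well", "fluc_raw", "rluc_raw", "annotation", "target_gene"]


def read_plates(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return df


def is_neg_ctrl(annotation: pd.Series) -> pd.Series:
    return annotation.isin(NEG_CTRL)


def is_pos_ctrl(annotation: pd.Series) -> pd.Series:
    return annotation.isin(POS_CTRL)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_plates(wells: pd.DataFrame, log_base: float = math.e) -> pd.DataFrame:
    """Log-transform and plate-median-center each channel separately.

    The centering median is taken over the valid *sample* wells of the
    plate; thread and empty wells never enter it.  Wells with nonpositive
    raw values are flagged ``invalid`` and excluded from all downstream
    steps (their count is in ``df.attrs['n_invalid']``).
    """
    df = wells.copy()
    lb = math.log(log_base)
    df["valid"] = (df["fluc_raw"] > 0) & (df["rluc_raw"] > 0)
    df.loc[df["annotation"] == EMPTY, "valid"] = False
    for ch in ("fluc", "rluc"):
        df[f"{ch}_norm"] = np.nan
        logv = np.where(df["valid"], np.log(df[f"{ch}_raw"].where(df["valid"], 1.0)) / lb, np.nan)
        df[f"_log_{ch}"] = logv
    for _, idx in df.groupby("plate_id").groups.items():
        sub = df.loc[idx]
        med_mask = sub["valid"] & (sub["annotation"] == SAMPLE)
        for ch in ("fluc", "rluc"):
            med = sub.loc[med_mask, f"_log_{ch}"].median()
            df.loc[idx, f"{ch}_norm"] = sub[f"_log_{ch}"] - med
    df = df.drop(columns=["_log_fluc", "_log_rluc"])
    df.attrs["n_invalid"] = int((~df["valid"]).sum())
    return df


def average_replicates(df_norm: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate plates: mean normalized values per target gene
    (controls keyed by annotation + well so layout positions stay
    distinct)."""
    df = df_norm[df_norm["valid"]].copy()
    key = np.where(
        df["annotation"] == SAMPLE, df["target_gene"], df["annotation"] + "@" + df["well"]
    )
    df["_key"] = key
    out = (
        df.groupby(["_key", "annotation", "target_gene"], as_index=False)
        .agg(fluc_norm=("fluc_norm", "mean"), rluc_norm=("rluc_norm", "mean"),
             n_replicates=("fluc_norm", "size"))
        .drop(columns=[])
    )
    return out.rename(columns={"_key": "key"})


def dead_cell_filter(df_norm: pd.DataFrame) -> pd.DataFrame:
    """Flag wells whose raw FLuc falls below the per-plate mean of the
    thread-control wells (predominantly dead cells)."""
    df = df_norm.copy()
    df["dead"] = False
    for plate, idx in df.groupby("plate_id").groups.items():
        sub = df.loc[idx]
        thr_wells = sub[(sub["annotation"] == THREAD_CTRL) & sub["valid"]]
        if thr_wells.empty:
            continue
        floor = thr_wells["fluc_raw"].mean()
        df.loc[idx, "dead"] = sub["fluc_raw"] < floor
    return df


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

@dataclass
class LoessFit:
    span: float
    degree: int
    x: np.ndarray
    y: np.ndarray
    fitted_values: np.ndarray
    residuals: np.ndarray


def loess_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.9,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression prediction.

    For each evaluation point the ``ceil(span * n)`` nearest training
    points in x get tricube weights ``(1 - (d/dmax)^3)^3`` and a
    polynomial of the given degree is fitted by weighted least squares and
    evaluated at the point.  Degenerate neighborhoods (all x identical)
    fall back to the weighted mean.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    n = len(x_train)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    q = int(math.ceil(span * n))
    if q < degree + 2:
        raise ValueError("span * n must be >= degree + 2 points")
    order = np.argsort(x_train)
    xs, ys = x_train[order], y_train[order]
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        nn = np.argpartition(d, q - 1)[:q]
        dn, xn, yn = d[nn], xs[nn], ys[nn]
        dmax = dn.max()
        if dmax == 0:
            out[i] = yn.mean()
            continue
        w = (1 - (dn / dmax) ** 3) ** 3
        if np.count_nonzero(w) < degree + 1 or np.ptp(xn[w > 0]) == 0:
            out[i] = float(np.average(yn, weights=np.maximum(w, 1e-12)))
            continue
        # centered design for conditioning
        xc = xn - x0
        X = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yn * sw, rcond=None)
        out[i] = beta[0]
    return out


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.9, degree: int = 2
) -> LoessFit:
    """Fit LOESS at the data points themselves; residual = y - fitted."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fitted = loess_predict(x, y, x, span=span, degree=degree)
    return LoessFit(span, degree, x, y, fitted, y - fitted)


# ---------------------------------------------------------------------------
# scoring and candidate calling
# ---------------------------------------------------------------------------

@dataclass
class ScreenThresholds:
    neg_mean: float
    neg_sd: float

    @property
    def upper(self) -> float:
        return self.neg_mean + self.neg_sd

    @property
    def lower(self) -> float:
        return self.neg_mean - self.neg_sd


def score_wells(
    df_norm: pd.DataFrame,
    span: float = 0.9,
    degree: int = 2,
    z_variant: Literal["standard", "robust"] = "standard",
    fit_controls: bool = False,
) -> pd.DataFrame:
    """Per-well LOESS residuals and z-scores, fitted per plate.

    The curve is fitted on the valid, live sample wells (controls are
    scored against it but excluded from fitting unless ``fit_controls``).
    z standardizes the residual against the sample-well residual
    distribution: mean/SD, or median/1.4826*MAD for the robust variant.
    """
    df = df_norm.copy()
    if "dead" not in df.columns:
        df = dead_cell_filter(df)
    df["resi"] = np.nan
    df["z"] = np.nan
    for plate, idx in df.groupby("plate_id").groups.items():
        sub = df.loc[idx]
        usable = sub["valid"] & ~sub["dead"] & (sub["annotation"] != THREAD_CTRL)
        fit_mask = usable & (sub["annotation"] == SAMPLE)
        if fit_controls:
            fit_mask = usable
        xs = sub.loc[fit_mask, "fluc_norm"].to_numpy()
        ys = sub.loc[fit_mask, "rluc_norm"].to_numpy()
        score_mask = usable
        xe = sub.loc[score_mask, "fluc_norm"].to_numpy()
        pred = loess_predict(xs, ys, xe, span=span, degree=degree)
        resi = sub.loc[score_mask, "rluc_norm"].to_numpy() - pred
        df.loc[sub.index[score_mask], "resi"] = resi
        samp = sub.loc[fit_mask].index
        samp_resi = df.loc[samp, "resi"].to_numpy()
        if z_variant == "robust":
            center = float(np.median(samp_resi))
            scale = 1.4826 * float(np.median(np.abs(samp_resi - center)))
        else:
            center = float(np.mean(samp_resi))
            scale = float(np.std(samp_resi, ddof=1))
        if scale == 0 or not np.isfinite(scale):
            raise ValueError(f"plate {plate}: zero residual scale")
        df.loc[sub.index[score_mask], "z"] = (
            df.loc[sub.index[score_mask], "resi"] - center
        ) / scale
    return df


def control_thresholds(scored: pd.DataFrame) -> ScreenThresholds:
    """Thresholds at mean +/- 1 SD of the negative-control well z values."""
    neg = scored.loc[is_neg_ctrl(scored["annotation"]), "z"].dropna()
    if neg.empty:
        raise ValueError("no scored negative-control wells")
    return ScreenThresholds(float(neg.mean()), float(neg.std(ddof=1)))


def call_candidates(
    scored: pd.DataFrame, thresholds: ScreenThresholds | None = None
) -> pd.DataFrame:
    """Per-gene screen scores: mean z across replicate plates plus a call.

    The threshold comes from the well-level negative-control z spread,
    while gene scores average across replicate plates; replication
    therefore tightens the null-gene distribution relative to the
    threshold and keeps the false-positive rate low.
    """
    thresholds = thresholds or control_thresholds(scored)
    samp = scored[(scored["annotation"] == SAMPLE) & scored["z"].notna()]
    per_gene = samp.groupby("target_gene", as_index=False).agg(
        z=("z", "mean"), resi=("resi", "mean"), n_wells=("z", "size")
    )
    per_gene["call"] = "none"
    per_gene.loc[per_gene["z"] > thresholds.upper, "call"] = "positive_candidate"
    per_gene.loc[per_gene["z"] < thresholds.lower, "call"] = "negative_candidate"
    per_gene.attrs["thresholds"] = thresholds
    return per_gene


# ---------------------------------------------------------------------------
# validation and cross-assay comparison
# ---------------------------------------------------------------------------

@dataclass
class ValidationRecord:
    target_gene: str
    trigger_outcomes: tuple[str, str, str]  # 'positive' / 'negative'
    counter_screen: Literal["specific", "core_pathway_or_transcription"]


def validate_candidates(records: Sequence[ValidationRecord]) -> pd.DataFrame:
    """Apply the 2-of-3 independent-trigger rule then the counter-screen.

    A gene is retained only if at least two of its three distinct RNAi
    triggers scored positive AND the miR-277 counter-screen reporter was
    unchanged (knockdown is specific, not a core-pathway/transcription
    effect).  Incomplete records are flagged, not judged.
    """
    rows = []
    for rec in records:
        if len(rec.trigger_outcomes) != 3 or any(
            t not in ("positive", "negative") for t in rec.trigger_outcomes
        ):
            rows.append((rec.target_gene, None, None, "incomplete", "missing_trigger"))
            continue
        n_pos = sum(t == "positive" for t in rec.trigger_outcomes)
        if n_pos < 2:
            rows.append((rec.target_gene, n_pos, rec.counter_screen, "dropped", "triggers_lt_2_of_3"))
        elif rec.counter_screen != "specific":
            rows.append((rec.target_gene, n_pos, rec.counter_screen, "dropped", "counter_screen"))
        else:
            rows.append((rec.target_gene, n_pos, rec.counter_screen, "retained", ""))
    return pd.DataFrame(
        rows, columns=["target_gene", "n_positive_triggers", "counter_screen", "final_call", "failed_rule"]
    )


def compare_screens(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    groups: dict[str, str] | None = None,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> pd.DataFrame:
    """Join per-gene effect strengths of two assays and classify genes.

    ``scores_a``/``scores_b`` are per-gene tables from
    :func:`call_candidates` (columns ``target_gene`` and ``z``).  Genes
    above threshold in both assays are shared-effect; above only one are
    assay-specific.  Thresholds default to each table's stored
    negative-control upper threshold.
    """
    merged = scores_a.merge(scores_b, on="target_gene", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no overlapping genes between the two score sets")
    if threshold_a is None:
        threshold_a = scores_a.attrs["thresholds"].upper
    if threshold_b is None:
        threshold_b = scores_b.attrs["thresholds"].upper
    above_a = merged["z_a"] > threshold_a
    above_b = merged["z_b"] > threshold_b
    merged["effect_class"] = np.select(
        [above_a & above_b, above_a, above_b],
        ["shared_effect", "a_specific", "b_specific"],
        default="none",
    )
    merged["group"] = merged["target_gene"].map(groups or {}).fillna("")
    return merged
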