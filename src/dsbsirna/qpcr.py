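"""Relative qPCR quantification: 2^-ddCt folds and splicing efficiency.

Ct tables are long-format DataFrames with columns ``sample``, ``amplicon``,
``condition``, ``replicate``, ``ct``.  Amplicon classes follow the
splicing-assay design: an intron-exon junction amplicon detects unspliced
pre-mRNA, an exon-exon junction amplicon detects spliced message, and an
exon-internal amplicon reports the total transcript and serves as the
normalizer.  Amplification efficiency is fixed at 2 (one doubling per
cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "amplicon", "condition", "replicate", "ct"]

AMPLICON_PRE = "intron_exon_junction"
AMPLICON_SPLICED = "exon_exon_junction"
AMPLICON_TOTAL = "exon_internal"


@dataclass
class DdctResult:
    fold_change: float       # mean across replicates of 2^-ddCt
    ddct: float              # mean ddCt (cycles)
    n: int
    sd: float                # SD of the replicate fold changes
    per_replicate_folds: tuple[float, ...]
    p_value: float | None = None  # two-sided t-test of ddCt vs 0 (n >= 2)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _mean_ct_by_replicate(meas: pd.DataFrame, amplicon: str) -> pd.Series:
    sub = meas[meas["amplicon"] == amplicon]
    if sub.empty:
        raise ValueError(f"no Ct measurements for amplicon {amplicon!r}")
    return sub.groupby("replicate")["ct"].mean()


def ddct(
    test: pd.DataFrame,
    control: pd.DataFrame,
    target_amplicon: str,
    ref_amplicon: str = AMPLICON_TOTAL,
) -> DdctResult:
    """Relative quantification by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) within each condition; ddCt =
    dCt(test) - dCt(control); fold = 2^-ddCt.  Replicates are matched by
    index where both conditions share it, otherwise each test replicate is
    compared against the control mean dCt; the replicate-wise folds are
    then summarized as mean +/- SD.
    """
    dct_test = _mean_ct_by_replicate(test, target_amplicon) - _mean_ct_by_replicate(
        test, ref_amplicon
    )
    dct_ctrl = _mean_ct_by_replicate(control, target_amplicon) - _mean_ct_by_replicate(
        control, ref_amplicon
    )
    shared = dct_test.index.intersection(dct_ctrl.index)
    if len(shared) == len(dct_test):
        dd = (dct_test.loc[shared] - dct_ctrl.loc[shared]).to_numpy()
    else:
        dd = (dct_test - dct_ctrl.mean()).to_numpy()
    folds = 2.0 ** (-dd)
    p = None
    if len(dd) >= 2 and np.ptp(dd) > 0:
        p = float(stats.ttest_1samp(dd, 0.0).pvalue)
    return DdctResult(
        fold_change=float(folds.mean()),
        ddct=float(dd.mean()),
        n=len(dd),
        sd=float(folds.std(ddof=1)) if len(dd) > 1 else 0.0,
        per_replicate_folds=tuple(float(f) for f in folds),
        p_value=p,
    )


def splicing_efficiency(
    meas: pd.DataFrame, locus: str, condition: str
) -> pd.DataFrame:
    """Per-amplicon levels relative to the exon-internal (total) amplicon.

    For every pre-mRNA (intron-exon junction) amplicon: ``rel =
    2^-(Ct_amplicon - Ct_total)`` per replicate, likewise for every
    spliced (exon-exon junction) amplicon; the exon-internal amplicon by
    construction has rel = 1.  Amplicon identity may carry a suffix
    (``intron_exon_junction:intron2``) to address individual introns.
    """
    sub = meas[(meas["sample"] == locus) & (meas["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no measurements for locus {locus!r}, condition {condition!r}")
    total_amps = [a for a in sub["amplicon"].unique() if a.split(":")[0] == AMPLICON_TOTAL]
    if not total_amps:
        raise ValueError(f"exon-internal amplicon missing for {locus!r}/{condition!r}")
    ct_total = _mean_ct_by_replicate(sub, total_amps[0])
    rows = []
    for amp in sorted(sub["amplicon"].unique()):
        base = amp.split(":")[0]
        if base == AMPLICON_TOTAL:
            continue
        kind = "pre_mrna_rel" if base == AMPLICON_PRE else "spliced_rel"
        ct_amp = _mean_ct_by_replicate(sub, amp)
        shared = ct_amp.index.intersection(ct_total.index)
        rel = 2.0 ** (-(ct_amp.loc[shared] - ct_total.loc[shared])).to_numpy()
        rows.append(
            {
                "locus": locus,
                "condition": condition,
                "amplicon": amp,
                "quantity": kind,
                "rel_level": float(rel.mean()),
                "sd": float(rel.std(ddof=1)) if len(rel) > 1 else 0.0,
                "n": len(rel),
            }
        )
    return pd.DataFrame(rows)


def cut_uncut_ratio(
    cut: pd.DataFrame,
    uncut: pd.DataFrame,
    amplicons: Sequence[str],
    ref_amplicon: str = AMPLICON_TOTAL,
) -> pd.DataFrame:
    """Cut/uncut fold change per amplicon, normalized to the exon-internal
    amplicon; displays only the DNA-break-induced changes.

    Each amplicon's fold is ddct(cut, uncut); the two-sided t-test is on
    the replicate ddCt values against zero (reported as None for n < 2 or
    zero spread).
    """
    rows = []
    for amp in amplicons:
        res = ddct(cut, uncut, amp, ref_amplicon)
        rows.append(
            {
                "amplicon": amp,
                "fold_change": res.fold_change,
                "sd": res.sd,
                "n": res.n,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
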