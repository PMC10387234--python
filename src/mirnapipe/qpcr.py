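"""Relative quantification of qPCR validation assays by the ddCt method.

Each sample contributes a target Ct and a reference Ct (a 5sRNA-style
endogenous control).  Per sample, dCt = target_ct - ref_ct; ddCt subtracts
the mean dCt of a calibrator group (healthy controls by default), and the
relative expression is 2^(-ddCt), assuming perfect amplification
efficiency.  Group comparisons use an ordinary one-way ANOVA on the
per-sample log2 fold values, the scale on which such validations are
usually summarised (mean +/- SEM).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

__all__ = [
    "read_ct_table",
    "delta_delta_ct",
    "group_summary",
    "group_anova",
]

_CT_COLUMNS = ["sample_id", "group", "target_ct", "ref_ct"]


def read_ct_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _CT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    return frame[_CT_COLUMNS]


def delta_delta_ct(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample fold change and log2 fold relative to a calibrator group.

    Adds columns dct, ddct, fold (= 2^-ddct) and log2_fold (= -ddct); the
    calibrator group's mean log2 fold is zero by construction.
    """
    frame = records[_CT_COLUMNS].copy()
    bad = frame[frame["target_ct"].isna() | frame["ref_ct"].isna()]
    if len(bad):
        raise ValueError(
            f"missing Ct value(s) for sample(s) {list(bad['sample_id'])}"
        )
    if not (frame["group"] == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    frame["dct"] = frame["target_ct"] - frame["ref_ct"]
    calibrator_mean = frame.loc[
        frame["group"] == calibrator_group, "dct"
    ].mean()
    frame["ddct"] = frame["dct"] - calibrator_mean
    frame["fold"] = np.exp2(-frame["ddct"])
    frame["log2_fold"] = -frame["ddct"]
    return frame


def group_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of log2 fold per group."""
    g = folds.groupby("group")["log2_fold"]
    out = pd.DataFrame(
        {"n": g.size(), "mean_log2_fold": g.mean(), "sem_log2_fold": g.sem()}
    )
    return out.reset_index()


def group_anova(groups: Mapping[str, np.ndarray] | pd.DataFrame) -> tuple[float, float]:
    """Ordinary one-way ANOVA on per-sample log2 fold values.

    Accepts a group -> values mapping or a frame with (group, log2_fold)
    columns.  Every group needs at least two samples.  Input that is one
    constant value everywhere has no variance on either side of the F ratio
    and is reported as F = 0, p = 1.
    """
    if isinstance(groups, pd.DataFrame):
        arrays = {
            str(g): sub["log2_fold"].to_numpy(dtype=float)
            for g, sub in groups.groupby("group")
        }
    else:
        arrays = {str(g): np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for name, values in arrays.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than two samples")
    all_values = np.concatenate(list(arrays.values()))
    if np.ptp(all_values) == 0:
        return 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = f_oneway(*arrays.values())
    f = float(stat.statistic)
    p = float(stat.pvalue)
    if not np.isfinite(f):  # zero within-group variance, unequal means
        return float("inf"), 0.0
    return f, p
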