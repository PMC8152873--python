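"""Trial filtering, epoch aggregation, learning scores and outlier screen.

The analysis pipeline for ASRT reaction-time data: drop the per-block
warm-up trials and the structurally confounded triplet categories
(trills a-b-a and repetitions a-a-a, which carry preexisting response
tendencies), collapse blocks of five into epochs, take per-participant
median RTs and accuracies separately for high- and low-probability
triplets, and derive learning scores (low minus high for RT, high minus
low for accuracy, so positive always means learning).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sequence import HIGH, LOW, NEITHER

__all__ = [
    "assign_epoch",
    "filter_trials",
    "summarize_epochs",
    "learning_scores",
    "standardized_scores",
    "epoch_performance",
    "outlier_screen",
]

#: blocks per epoch; 25 task blocks collapse into epochs 1..5
BLOCKS_PER_EPOCH = 5
MAX_BLOCK = 25
#: leading trials of every block excluded from analysis (5 warm-up
#: trials, and the first valid triplet closes only at trial 8)
N_EXCLUDED_LEAD = 7

_REQUIRED = ("participant", "block", "trial", "triplet_label", "triplet_category",
             "correct", "rt_ms")


def assign_epoch(block_index):
    """Map block index 1..25 to epoch 1..5 (five consecutive blocks each)."""
    b = np.asarray(block_index)
    if np.any((b < 1) | (b > MAX_BLOCK)):
        bad = b[(b < 1) | (b > MAX_BLOCK)]
        raise ValueError(f"block index out of range 1..{MAX_BLOCK}: {np.atleast_1d(bad)[0]}")
    epoch = (b - 1) // BLOCKS_PER_EPOCH + 1
    return int(epoch) if np.isscalar(block_index) else epoch


def filter_trials(
    records: pd.DataFrame, include_incorrect_rt: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial-level exclusion rules; return (rt_set, acc_set).

    Both sets drop, per block, the first 7 trials, every trill and
    repetition, and trials without a defined triplet label.  The RT set
    additionally keeps only correct responses unless
    ``include_incorrect_rt`` (a documented analysis variant); the
    accuracy set always retains incorrect trials.
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"records lack required columns: {missing}")
    keep = (
        (records["trial"] > N_EXCLUDED_LEAD)
        & records["triplet_label"].isin([HIGH, LOW])
        & (records["triplet_category"] == NEITHER)
    )
    acc_set = records.loc[keep].copy()
    if include_incorrect_rt:
        rt_set = acc_set.copy()
    else:
        rt_set = acc_set.loc[acc_set["correct"].astype(bool)].copy()
    return rt_set, acc_set


def _with_epoch(df: pd.DataFrame) -> pd.DataFrame:
    if "epoch" not in df.columns:
        df = df.copy()
        df["epoch"] = assign_epoch(df["block"].to_numpy())
    return df


def summarize_epochs(rt_set: pd.DataFrame, acc_set: pd.DataFrame) -> pd.DataFrame:
    """Per participant x epoch medians, accuracies and trial counts.

    Median RT per triplet label comes from the RT set; accuracy
    (proportion of correct first responses) per label from the accuracy
    set.  Cells with no trials yield NaN and ``complete == False`` —
    missingness is flagged, never imputed.
    """
    rt_set, acc_set = _with_epoch(rt_set), _with_epoch(acc_set)
    idx = ["participant", "epoch"]

    med = rt_set.pivot_table(index=idx, columns="triplet_label", values="rt_ms",
                             aggfunc="median", observed=True)
    cnt = rt_set.pivot_table(index=idx, columns="triplet_label", values="rt_ms",
                             aggfunc="count", observed=True)
    acc = acc_set.pivot_table(index=idx, columns="triplet_label", values="correct",
                              aggfunc="mean", observed=True)

    out = pd.DataFrame(index=med.index.union(acc.index))
    for frame, name in ((med, "median_rt"), (acc, "acc")):
        for label in (HIGH, LOW):
            col = frame[label] if label in frame.columns else np.nan
            out[f"{name}_{label}"] = col
    for label in (HIGH, LOW):
        col = cnt[label] if label in cnt.columns else np.nan
        out[f"n_{label}"] = col
    out["complete"] = out[["median_rt_high", "median_rt_low",
                           "acc_high", "acc_low"]].notna().all(axis=1)
    out = out.reset_index()

    if "group" in acc_set.columns:
        gmap = acc_set.groupby("participant", observed=True)["group"].first()
        out.insert(1, "group", out["participant"].map(gmap))
    return out


def learning_scores(summary: pd.DataFrame) -> pd.DataFrame:
    """Attach rt_score and acc_score to an epoch summary.

    rt_score = median RT(low) - median RT(high) in ms; acc_score =
    accuracy(high) - accuracy(low); positive values indicate learning on
    both scales.
    """
    needed = ["median_rt_high", "median_rt_low", "acc_high", "acc_low"]
    missing = [c for c in needed if c not in summary.columns]
    if missing:
        raise ValueError(f"summary lacks required columns: {missing}")
    out = summary.copy()
    out["rt_score"] = out["median_rt_low"] - out["median_rt_high"]
    out["acc_score"] = out["acc_high"] - out["acc_low"]
    return out


def standardized_scores(
    rt_set: pd.DataFrame, acc_set: pd.DataFrame, method: str = "zdiff"
) -> pd.DataFrame:
    """Learning scores standardized against each participant-epoch baseline.

    Controls for group differences in average speed/accuracy so that
    learning can be compared across regimes with different baselines.

    ``zdiff`` (default): z-transform the RT-set trials within each
    participant x epoch and score mean z(low) - mean z(high); accuracy
    scores are divided by the participant-epoch mean accuracy.  Invariant
    to affine rescaling of a participant's RTs.  ``ratio``: RT score as a
    percentage of the participant-epoch overall median RT.

    Zero-variance cells yield NaN (flagged missing).
    """
    if method not in ("zdiff", "ratio"):
        raise ValueError(f"unknown standardization method {method!r}")
    rt_set, acc_set = _with_epoch(rt_set), _with_epoch(acc_set)
    idx = ["participant", "epoch"]

    if method == "zdiff":
        g = rt_set.groupby(idx, observed=True)["rt_ms"]
        mu = g.transform("mean")
        sd = g.transform("std")
        z = (rt_set["rt_ms"] - mu) / sd.where(sd > 0)
        zi = rt_set[idx + ["triplet_label"]].assign(z=z)
        zm = zi.pivot_table(index=idx, columns="triplet_label", values="z",
                            aggfunc="mean", observed=True)
        std_rt = zm.get(LOW, np.nan) - zm.get(HIGH, np.nan)
    else:
        med_all = rt_set.groupby(idx, observed=True)["rt_ms"].median()
        per = rt_set.pivot_table(index=idx, columns="triplet_label", values="rt_ms",
                                 aggfunc="median", observed=True)
        rt_score = per.get(LOW, np.nan) - per.get(HIGH, np.nan)
        std_rt = 100.0 * rt_score / med_all.where(med_all > 0)

    accp = acc_set.pivot_table(index=idx, columns="triplet_label", values="correct",
                               aggfunc="mean", observed=True)
    mean_acc = acc_set.groupby(idx, observed=True)["correct"].mean()
    std_acc = (accp.get(HIGH, np.nan) - accp.get(LOW, np.nan)) / mean_acc.where(mean_acc > 0)

    out = pd.DataFrame({"std_rt_score": std_rt, "std_acc_score": std_acc}).reset_index()
    if "group" in acc_set.columns:
        gmap = acc_set.groupby("participant", observed=True)["group"].first()
        out.insert(1, "group", out["participant"].map(gmap))
    return out


def epoch_performance(rt_set: pd.DataFrame, acc_set: pd.DataFrame) -> pd.DataFrame:
    """Overall per participant x epoch performance (median RT, accuracy).

    The input of the cohort-level outlier screen: performance pooled over
    triplet labels.
    """
    rt_set, acc_set = _with_epoch(rt_set), _with_epoch(acc_set)
    idx = ["participant", "epoch"]
    med = rt_set.groupby(idx, observed=True)["rt_ms"].median().rename("median_rt")
    acc = acc_set.groupby(idx, observed=True)["correct"].mean().rename("accuracy")
    out = pd.concat([med, acc], axis=1).reset_index()
    if "group" in acc_set.columns:
        gmap = acc_set.groupby("participant", observed=True)["group"].first()
        out.insert(1, "group", out["participant"].map(gmap))
    return out


def outlier_screen(
    performance: pd.DataFrame,
    metrics: tuple[str, ...] = ("median_rt", "accuracy"),
    sd_threshold: float = 2.0,
    epoch_fraction: float = 0.5,
) -> list:
    """Participants deviant from their group in most epochs.

    A participant is excluded when, for any chosen metric, their
    per-epoch value falls outside the group mean +/- ``sd_threshold`` SD
    in strictly more than ``epoch_fraction`` of the epochs evaluated.
    Requires a ``group`` column and at least 3 participants per group
    (the group SD is meaningless below that).
    """
    if "group" not in performance.columns:
        raise ValueError("outlier screen needs a 'group' column")
    counts = performance.groupby("group", observed=True)["participant"].nunique()
    if (counts < 3).any():
        small = counts[counts < 3].index[0]
        raise ValueError(f"group {small!r} has fewer than 3 participants")

    n_epochs = performance["epoch"].nunique()
    excluded: set = set()
    for metric in metrics:
        if metric not in performance.columns:
            raise ValueError(f"unknown screening metric {metric!r}")
        g = performance.groupby(["group", "epoch"], observed=True)[metric]
        mu = g.transform("mean")
        sd = g.transform("std")
        deviant = (performance[metric] - mu).abs() > sd_threshold * sd
        n_dev = deviant.groupby(performance["participant"], observed=True).sum()
        excluded |= set(n_dev[n_dev > epoch_fraction * n_epochs].index)
    return sorted(excluded)
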