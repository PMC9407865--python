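"""Relative expression (2^-ddCt) and dual-luciferase relative activity.

qPCR folds follow the Livak convention: per-sample dCt = Ct_target -
Ct_reference, ddCt = dCt - mean dCt of the calibrator group, fold =
2^-ddCt. The calibrator's group fold is exactly 1 by construction;
per-sample calibrator folds scatter around 1. Statistical tests are run
on the dCt/ddCt (log) scale, where normality is more plausible, and
displayed as folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .assoc import anova_tukey

__all__ = ["ExprResult", "LucResult", "ddct", "luciferase_relative"]


@dataclass
class ExprResult:
    calibrator: str
    per_sample: pd.DataFrame  # sample_id, group, dct, ddct, fold
    group_stats: pd.DataFrame  # group, n, mean_fold, sem_fold
    comparisons: tuple[tuple[str, str, float], ...]  # (g1, g2, p)


@dataclass
class LucResult:
    control: str
    per_well: pd.DataFrame  # construct, ratio, relative_activity
    group_stats: pd.DataFrame  # construct, n, mean_activity, sem_activity
    comparisons: tuple[tuple[str, str, float], ...]


def _pair_p_log(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance t-test; degenerate zero-variance guard."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(ttest_ind(a, b).pvalue)


def ddct(table: pd.DataFrame, calibrator: str) -> ExprResult:
    """2^-ddCt analysis of a Ct table against a calibrator group.

    Group comparisons use one-way ANOVA + Tukey on dCt when three or
    more groups are present, a two-sided t-test for two.
    """
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if table[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value")
    groups = list(dict.fromkeys(table["group"]))
    if calibrator not in groups:
        raise ValueError(f"calibrator group {calibrator!r} absent")

    df = table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    cal_mean = df.loc[df["group"] == calibrator, "dct"].mean()
    df["ddct"] = df["dct"] - cal_mean
    df["fold"] = 2.0 ** (-df["ddct"])

    stats = []
    for g in groups:
        sub = df[df["group"] == g]
        # group fold from the group's mean ddCt (geometric convention):
        # the calibrator lands on exactly 1
        mean_fold = float(2.0 ** (-sub["ddct"].mean()))
        stats.append(
            {
                "group": g,
                "n": len(sub),
                "mean_fold": mean_fold,
                "sem_fold": float(sub["fold"].std(ddof=1) / np.sqrt(len(sub)))
                if len(sub) > 1
                else np.nan,
            }
        )

    comparisons = []
    if len(groups) >= 3:
        res = anova_tukey(df, "dct", group_col="group")
        comparisons = [(g1, g2, p) for g1, g2, _, p in res.tukey]
    else:
        a, b = groups
        p = _pair_p_log(
            df.loc[df["group"] == a, "dct"].to_numpy(),
            df.loc[df["group"] == b, "dct"].to_numpy(),
        )
        comparisons = [(a, b, p)]
    return ExprResult(
        calibrator=calibrator,
        per_sample=df[["sample_id", "group", "dct", "ddct", "fold"]],
        group_stats=pd.DataFrame(stats),
        comparisons=tuple(comparisons),
    )


def luciferase_relative(table: pd.DataFrame, control: str) -> LucResult:
    """Relative promoter activity from firefly/renilla well readings.

    Per-well ratio = firefly / renilla; relative activity normalizes to
    the control construct's mean ratio (control mean = 1 exactly).
    Pairwise construct comparisons are two-sided t-tests on log ratios.
    """
    required = {"construct", "firefly", "renilla"}
    if not required.issubset(table.columns):
        raise ValueError(f"luciferase table needs columns {sorted(required)}")
    if (table["renilla"] <= 0).any():
        raise ValueError("renilla readings must be positive")
    constructs = list(dict.fromkeys(table["construct"]))
    if control not in constructs:
        raise ValueError(f"control construct {control!r} absent")

    df = table.copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    if (df["ratio"] <= 0).any():
        raise ValueError("non-positive firefly/renilla ratio")
    control_mean = df.loc[df["construct"] == control, "ratio"].mean()
    df["relative_activity"] = df["ratio"] / control_mean

    stats = []
    for c in constructs:
        sub = df[df["construct"] == c]
        stats.append(
            {
                "construct": c,
                "n": len(sub),
                "mean_activity": float(sub["relative_activity"].mean()),
                "sem_activity": float(
                    sub["relative_activity"].std(ddof=1) / np.sqrt(len(sub))
                )
                if len(sub) > 1
                else np.nan,
            }
        )

    comparisons = []
    for a, b in combinations(constructs, 2):
        pa = np.log2(df.loc[df["construct"] == a, "ratio"].to_numpy())
        pb = np.log2(df.loc[df["construct"] == b, "ratio"].to_numpy())
        comparisons.append((a, b, _pair_p_log(pa, pb)))
    return LucResult(
        control=control,
        per_well=df[["construct", "ratio", "relative_activity"]],
        group_stats=pd.DataFrame(stats),
        comparisons=tuple(comparisons),
    )
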