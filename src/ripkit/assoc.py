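"""Genotype-phenotype association: one-way ANOVA with Tukey HSD.

Groups are the three insertion genotypes. The F statistic is the
between/within mean-square ratio; pairwise comparisons use the
studentized range with the pooled within-group variance
(Tukey-Kramer for unbalanced groups). Group separation is displayed
with compact letters at two alpha levels — lowercase for 0.05,
uppercase for 0.01 — the convention of breed-association tables.

Dispersion columns ("±") are standard errors of the mean, not SDs; a
config switch on the display restores the SD reading.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "AssocResult",
    "adjust_age_100kg",
    "anova_tukey",
    "summary_table",
    "assign_letters",
]


@dataclass
class AssocResult:
    trait: str
    groups: tuple[str, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    sem: tuple[float, ...]
    f_stat: float
    anova_p: float
    df_between: int
    df_within: int
    tukey: tuple[tuple[str, str, float, float], ...]  # (g1, g2, diff, p_adj)
    letters_05: dict[str, str]
    letters_01: dict[str, str]


def adjust_age_100kg(
    age_days: float, weight_kg: float, c: float = 1.0
) -> float:
    """Adjust a recorded age to the 100-kg-weight scale.

    National genetic-evaluation schemes publish breed-specific adjustment
    formulas; this packaged default is an explicit linear extrapolation
    stand-in,

        adjusted = age + (100 - weight) * (age / weight) * c,

    with ``c`` configurable (``c = 0`` disables the adjustment). Any
    report produced from it states which adjustment was applied.
    """
    if age_days <= 0 or weight_kg <= 0:
        raise ValueError("age and weight must be positive")
    return age_days + (100.0 - weight_kg) * (age_days / weight_kg) * c


def assign_letters(
    groups: Sequence[str],
    pairwise_p: dict[tuple[str, str], float],
    alpha: float,
    alphabet: str = string.ascii_lowercase,
) -> dict[str, str]:
    """Compact letter display: groups sharing no letter differ at ``alpha``.

    Letters label the maximal cliques of the "not significantly
    different" graph, ordered by each clique's first group in the given
    group order (which the caller fixes by descending mean, making the
    display invariant under relabeling).
    """
    k = len(groups)
    idx = {g: i for i, g in enumerate(groups)}

    def ns(a: str, b: str) -> bool:
        return pairwise_p[tuple(sorted((a, b), key=idx.get))] >= alpha

    cliques = []
    for size in range(k, 0, -1):
        for combo in combinations(groups, size):
            if all(ns(a, b) for a, b in combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    cliques.sort(key=lambda c: min(idx[g] for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip(alphabet, cliques):
        for g in clique:
            letters[g] += letter
    return letters


def anova_tukey(
    table: pd.DataFrame, trait: str, group_col: str = "genotype"
) -> AssocResult:
    """One-way ANOVA with Tukey(-Kramer) HSD over genotype groups.

    Requires >= 2 groups with >= 2 observations each; groups are ordered
    by descending mean for display purposes.
    """
    if trait not in table.columns:
        raise ValueError(f"trait {trait!r} not in table")
    grouped = {
        str(g): np.asarray(vals[trait], dtype=float)
        for g, vals in table.groupby(group_col, sort=False)
    }
    if len(grouped) < 2:
        raise ValueError("at least two genotype groups required")
    for g, vals in grouped.items():
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    order = sorted(grouped, key=lambda g: -grouped[g].mean())
    data = [grouped[g] for g in order]
    ns_ = np.array([d.size for d in data])
    means = np.array([d.mean() for d in data])
    sds = np.array([d.std(ddof=1) for d in data])
    k, n_total = len(data), int(ns_.sum())
    grand = np.concatenate(data).mean()

    ss_between = float((ns_ * (means - grand) ** 2).sum())
    ss_within = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    df_b, df_w = k - 1, n_total - k
    msb, msw = ss_between / df_b, ss_within / df_w
    f_stat = msb / msw
    anova_p = float(f_dist.sf(f_stat, df_b, df_w))

    tukey = []
    pairwise_p = {}
    for (i, gi), (j, gj) in combinations(enumerate(order), 2):
        diff = means[i] - means[j]
        se = np.sqrt(msw / 2.0 * (1.0 / ns_[i] + 1.0 / ns_[j]))  # Tukey-Kramer
        q = abs(diff) / se
        p_adj = float(np.clip(studentized_range.sf(q, k, df_w), 0.0, 1.0))
        tukey.append((gi, gj, float(diff), p_adj))
        pairwise_p[(gi, gj)] = p_adj

    letters_05 = assign_letters(order, pairwise_p, 0.05, string.ascii_lowercase)
    letters_01 = assign_letters(order, pairwise_p, 0.01, string.ascii_uppercase)
    return AssocResult(
        trait=trait,
        groups=tuple(order),
        n=tuple(int(x) for x in ns_),
        mean=tuple(float(x) for x in means),
        sd=tuple(float(x) for x in sds),
        sem=tuple(float(s / np.sqrt(n)) for s, n in zip(sds, ns_)),
        f_stat=float(f_stat),
        anova_p=anova_p,
        df_between=df_b,
        df_within=df_w,
        tukey=tuple(tukey),
        letters_05=letters_05,
        letters_01=letters_01,
    )


def _round2(x: float) -> str:
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summary_table(result: AssocResult, dispersion: str = "sem") -> pd.DataFrame:
    """Report rows: ``mean ± sem`` (or sd) with significance letters.

    Superscripts are omitted entirely when every group shares the same
    letter at that alpha level. Rounding is half-up to 2 decimals.
    """
    if dispersion not in ("sem", "sd"):
        raise ValueError("dispersion must be 'sem' or 'sd'")
    disp = result.sem if dispersion == "sem" else result.sd
    show05 = len(set(result.letters_05.values())) > 1
    show01 = len(set(result.letters_01.values())) > 1
    rows = []
    for g, n, m, d in zip(result.groups, result.n, result.mean, disp):
        letters = ""
        if show05:
            letters += result.letters_05[g]
        if show01:
            letters += result.letters_01[g]
        value = f"{_round2(m)} ± {_round2(d)}"
        if letters:
            value += f" {letters}"
        rows.append({"genotype": g, "n": n, result.trait: value})
    return pd.DataFrame(rows)
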