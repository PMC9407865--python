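"""Per-breed population-genetic summaries of a biallelic insertion locus.

Allele and genotype frequencies come straight from counts (never from
rounded printed percentages), the Hardy-Weinberg test is a Pearson
chi-square with df = 1 and no continuity correction — the convention of
the classic Popgene program — and marker informativeness is the
polymorphic information content

    PIC = 1 - sum_i P_i^2 - sum_{i<j} 2 P_i^2 P_j^2

whose biallelic maximum is 0.375 at P = 0.5. An exact HWE test
(Wigginton-style full enumeration of heterozygote counts) is available
behind a flag but is not the default.
"""

from __future__ import annotations

from math import isclose
from typing import Sequence

import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .model import GenotypeCounts, PopGenResult

__all__ = [
    "allele_frequencies",
    "hwe_test",
    "hwe_exact_test",
    "pic",
    "popgen_result",
    "popgen_table",
]


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """(p_ins, p_del) from genotype counts, full precision."""
    total = counts.total
    p_ins = (2 * counts.n_ins_ins + counts.n_ins_del) / (2 * total)
    return p_ins, 1.0 - p_ins


def hwe_test(counts: GenotypeCounts) -> tuple[float, int, float, bool]:
    """Pearson chi-square HWE test: (chi2, df, p, monomorphic).

    Observed genotype counts against expectations (p^2, 2pq, q^2) * N,
    df = 1, no continuity correction. A monomorphic sample (one allele
    absent) returns chi2 = 0, p = 1 with the monomorphic flag set.
    """
    p, q = allele_frequencies(counts)
    n = counts.total
    if p == 0.0 or q == 0.0:
        return 0.0, 1, 1.0, True
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(counts.as_tuple, expected)
    )
    return chi2, 1, float(chi2_dist.sf(chi2, 1)), False


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact HWE p-value: sum of heterozygote-count probabilities <= observed's.

    Conditional on allele counts, P(n_het) follows the standard
    hypergeometric-like distribution; the p-value sums the probabilities
    of all heterozygote counts no more likely than the observed one.
    """
    import math

    n = counts.total
    n_a = 2 * counts.n_ins_ins + counts.n_ins_del
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)

    def log_weight(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2)
        )

    hets = list(range(rare % 2, rare + 1, 2))
    logs = [log_weight(h) for h in hets]
    mx = max(logs)
    probs = [math.exp(lw - mx) for lw in logs]
    total = sum(probs)
    p_obs = probs[hets.index(counts.n_ins_del)]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-12)) / total)


def pic(freqs: Sequence[float]) -> float:
    """Polymorphic information content of an m-allele marker."""
    if any(f < 0 for f in freqs):
        raise ValueError("allele frequencies must be non-negative")
    if not isclose(sum(freqs), 1.0, abs_tol=1e-9):
        raise ValueError("allele frequencies must sum to 1")
    m = len(freqs)
    value = 1.0 - sum(f * f for f in freqs)
    for i in range(m - 1):
        for j in range(i + 1, m):
            value -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return value


def popgen_result(counts: GenotypeCounts) -> PopGenResult:
    """Full per-breed summary for one locus."""
    p, q = allele_frequencies(counts)
    chi2, df, pval, mono = hwe_test(counts)
    n = counts.total
    return PopGenResult(
        breed=counts.breed,
        n=n,
        p_ins=p,
        p_del=q,
        geno_freq=tuple(c / n for c in counts.as_tuple),
        hwe_chi2=chi2,
        hwe_df=df,
        hwe_p=pval,
        pic=pic((p, q)) if not mono else 0.0,
        monomorphic=mono,
    )


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.2f}"


def _fmt_hwe(res: PopGenResult) -> str:
    if res.monomorphic:
        return "—"
    if res.hwe_p < 0.01:
        return "<0.01"
    return f"{res.hwe_p:.2f}"


def _polymorphism_note(pic_value: float) -> str:
    if pic_value < 0.25:
        return "low polymorphism"
    if pic_value <= 0.5:
        return "moderate polymorphism"
    return "high polymorphism"


def popgen_table(rows: Sequence[tuple[str, GenotypeCounts]]) -> pd.DataFrame:
    """Report table: one row per (locus, breed) in the report dialect.

    Genotype and allele frequencies as 2-decimal percentages, HWE p
    printed ``<0.01`` below 0.01 (``—`` for monomorphic samples), PIC to
    3 decimals with a low/moderate classification note.
    """
    if not rows:
        raise ValueError("at least one (locus, counts) row required")
    out = []
    for locus, counts in rows:
        res = popgen_result(counts)
        out.append(
            {
                "locus": locus,
                "breed": res.breed,
                "n": res.n,
                "freq_ins_ins": _fmt_pct(res.geno_freq[0]),
                "freq_ins_del": _fmt_pct(res.geno_freq[1]),
                "freq_del_del": _fmt_pct(res.geno_freq[2]),
                "freq_ins": _fmt_pct(res.p_ins),
                "freq_del": _fmt_pct(res.p_del),
                "hwe": _fmt_hwe(res),
                "pic": f"{res.pic:.3f}",
                "note": _polymorphism_note(res.pic),
            }
        )
    return pd.DataFrame(out)
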