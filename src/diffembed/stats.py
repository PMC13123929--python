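"""Exact overlap and enrichment statistics for candidate gene lists.

Fisher's exact test on 2x2 overlap tables with the conditional
maximum-likelihood (CMLE) odds ratio — the estimate reported by R's
``fisher.test`` — plus one-sided hypergeometric gene-set enrichment and
Benjamini–Hochberg adjustment.

The CMLE solves E_psi[A] = a where A follows Fisher's noncentral
hypergeometric distribution on the table's support conditional on both
margins; the two-sided p-value sums the point probabilities of all tables
(at psi = 1) no more probable than the observed one.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "OverlapTestResult",
    "build_overlap_table",
    "cmle_odds_ratio",
    "fisher_exact",
    "hypergeometric_enrichment",
    "bh_adjust",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 overlap table: a = in both sets, b = first only, c = second only,
    d = neither; the background universe has a+b+c+d elements."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclasses.dataclass(frozen=True)
class OverlapTestResult:
    table: ContingencyTable2x2
    sample_or: float
    cmle_or: float  # may be 0, inf, or nan (degenerate margins)
    p_two_sided: float
    or_defined: bool = True


def build_overlap_table(
    set_a: Iterable[str], set_b: Iterable[str], background: Iterable[str]
) -> ContingencyTable2x2:
    """Cross-tabulate membership of two gene sets over a background universe."""
    bg = set(background)
    A, B = set(set_a), set(set_b)
    for name, s in (("first", A), ("second", B)):
        outside = s - bg
        if outside:
            raise ValueError(
                f"{name} set has elements outside the background: {sorted(outside)[:5]}"
            )
    a = len(A & B)
    return ContingencyTable2x2(a=a, b=len(A) - a, c=len(B) - a,
                               d=len(bg) - len(A) - len(B) + a)


def _support(table: ContingencyTable2x2) -> np.ndarray:
    m1 = table.a + table.b
    n1 = table.a + table.c
    lo = max(0, n1 - (table.c + table.d))
    hi = min(n1, m1)
    return np.arange(lo, hi + 1)


def _log_binom_weights(table: ContingencyTable2x2, support: np.ndarray) -> np.ndarray:
    m1, m2 = table.a + table.b, table.c + table.d
    n1 = table.a + table.c
    return (special.gammaln(m1 + 1) - special.gammaln(support + 1)
            - special.gammaln(m1 - support + 1)
            + special.gammaln(m2 + 1) - special.gammaln(n1 - support + 1)
            - special.gammaln(m2 - (n1 - support) + 1))


def cmle_odds_ratio(table: ContingencyTable2x2) -> float:
    """Conditional-MLE odds ratio of a 2x2 table.

    Maximises the Fisher noncentral hypergeometric likelihood in the odds
    parameter, equivalently solving E_psi[A] = a; solved by bracketed root
    finding on log(psi) with geometrically widened brackets. Returns 0 or
    inf when the observed count sits at the support boundary, nan when the
    support is a single point (a zero margin).
    """
    support = _support(table)
    if support.size == 1:
        return math.nan
    if table.a == support[0]:
        return 0.0
    if table.a == support[-1]:
        return math.inf

    logw = _log_binom_weights(table, support)

    def mean_minus_a(log_psi: float) -> float:
        logp = logw + support * log_psi
        logp -= logp.max()
        p = np.exp(logp)
        return float((support * p).sum() / p.sum()) - table.a

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if mean_minus_a(lo) < 0:
            break
        lo *= 2.0
    for _ in range(200):
        if mean_minus_a(hi) > 0:
            break
        hi *= 2.0
    root = optimize.brentq(mean_minus_a, lo, hi, xtol=1e-12, rtol=1e-14)
    return float(np.exp(root))


def fisher_exact(table: ContingencyTable2x2) -> OverlapTestResult:
    """Two-sided Fisher exact test with sample and CMLE odds ratios.

    The p-value follows the point-probability summation convention (sum of
    hypergeometric probabilities <= that of the observed table), matching
    R's ``fisher.test``. Degenerate tables (a zero margin) return p = 1 with
    the odds ratio flagged undefined.
    """
    support = _support(table)
    if support.size == 1:
        return OverlapTestResult(table=table, sample_or=table.sample_odds_ratio,
                                 cmle_or=math.nan, p_two_sided=1.0, or_defined=False)
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    cmle = cmle_odds_ratio(table)
    return OverlapTestResult(
        table=table,
        sample_or=table.sample_odds_ratio,
        cmle_or=cmle,
        p_two_sided=float(p),
        or_defined=math.isfinite(cmle),
    )


def hypergeometric_enrichment(
    candidates: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """One-sided upper-tail hypergeometric enrichment per named gene set.

    For each set: overlap count, fold enrichment
    (a/|candidates|) / (|set|/|background|), raw p = P[X >= a] for
    X ~ Hypergeom(|background|, |set|, |candidates|), and (by default) a
    BH-adjusted p column.
    """
    bg = set(background)
    cand = set(candidates)
    if not cand:
        raise ValueError("candidate set is empty")
    if cand - bg:
        raise ValueError(
            f"candidates outside the background: {sorted(cand - bg)[:5]}"
        )
    rows = []
    for name, members in gene_sets.items():
        s = set(members)
        if s - bg:
            raise ValueError(
                f"gene set {name!r} has elements outside the background: "
                f"{sorted(s - bg)[:5]}"
            )
        a = len(cand & s)
        fold = (a / len(cand)) / (len(s) / len(bg)) if s else math.nan
        p = float(sps.hypergeom.sf(a - 1, len(bg), len(s), len(cand)))
        rows.append((name, a, len(s), fold, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                     "fold_enrichment", "p_value"])
    if adjust and len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return df


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
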