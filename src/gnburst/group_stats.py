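"""Pooled burst-property distributions and the group comparison battery.

Burst properties of all (subsampled) bursting neurons in a group are pooled
into a single empirical cumulative distribution per property and compared
between groups with two-sample Kolmogorov–Smirnov tests at a stringent
α = 0.001 criterion.  Pattern proportions (how many neurons of a group are
bursting / irregular / tonic / quiet) are compared pairwise with two-sided
Fisher's exact tests at α = 0.05.  No multiple-testing correction is
applied; the KS criterion itself is the guard.

KS p-values are exact when n_a·n_b ≤ 10,000 and asymptotic otherwise —
pooled samples here typically hold hundreds of bursts, where the
asymptotic two-sample formula is standard.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .burst_analysis import BURST_PROPERTIES, BurstSet, collect_burst_properties
from .pattern_classifier import Pattern

__all__ = [
    "GroupDistribution",
    "KSComparisonResult",
    "PatternContingency",
    "pool_group",
    "ks_compare",
    "fisher_exact_two_sided",
    "pattern_proportion_test",
    "run_full_comparison_suite",
]

logger = logging.getLogger(__name__)

EXACT_KS_MAX_PRODUCT = 10_000


@dataclass(frozen=True)
class GroupDistribution:
    """Pooled values of one burst property for one group, with its ECDF."""

    group_key: tuple[str, str]
    property: str
    values: np.ndarray
    n_neurons: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    def ecdf(self, x: np.ndarray | float) -> np.ndarray | float:
        """Fraction of pooled values ≤ x (right-continuous step function)."""
        sorted_v = np.sort(self.values)
        return np.searchsorted(sorted_v, x, side="right") / sorted_v.size


@dataclass(frozen=True)
class KSComparisonResult:
    d_statistic: float
    p_value: float
    n_a: int
    n_b: int
    alpha: float = 0.001

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class PatternContingency:
    """2×2 table: rows = groups, columns = (pattern present, pattern absent)."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float = float("nan")
    p_value: float = float("nan")
    zero_margin: bool = False


def pool_group(
    neurons: list[BurstSet], property: str, group_key: tuple[str, str] = ("", "")
) -> GroupDistribution:
    """Concatenate one property across a group's (subsampled) burst sets."""
    if property not in BURST_PROPERTIES:
        raise ValueError(f"unknown property {property!r}")
    chunks = [collect_burst_properties(bs)[property] for bs in neurons]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        raise ValueError(f"no bursting cells contribute {property!r} in group {group_key}")
    return GroupDistribution(
        group_key=group_key,
        property=property,
        values=np.concatenate(chunks),
        n_neurons=len(neurons),
    )


def ks_compare(
    a: GroupDistribution, b: GroupDistribution, alpha: float = 0.001
) -> KSComparisonResult:
    """Two-sample KS test between two pooled distributions."""
    if a.property != b.property:
        raise ValueError("cannot compare distributions of different properties")
    n_a, n_b = a.values.size, b.values.size
    method = "exact" if n_a * n_b <= EXACT_KS_MAX_PRODUCT else "asymp"
    res = stats.ks_2samp(a.values, b.values, method=method)
    return KSComparisonResult(
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=n_a,
        n_b=n_b,
        alpha=alpha,
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for a 2×2 table by hypergeometric enumeration.

    Exact rational arithmetic: sums the conditional probabilities of every
    table (with the observed margins) whose probability does not exceed the
    observed table's.  Point-probability ties are therefore handled exactly,
    with no floating-point guard factor.
    """
    from fractions import Fraction
    from math import comb

    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    obs = weights[a]
    total = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(total, denom))


def pattern_proportion_test(table: PatternContingency) -> PatternContingency:
    """Two-sided Fisher's exact test on a 2×2 pattern-proportion table.

    A zero margin (a row or column summing to zero) makes the test vacuous;
    p = 1 by convention and the result is flagged.
    """
    t = np.asarray(table.table, dtype=int)
    if np.any(t < 0):
        raise ValueError("cell counts must be nonnegative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    zero_margin = bool(np.any(row_sums == 0) or np.any(col_sums == 0))
    a, b = (int(x) for x in t[0])
    c, d = (int(x) for x in t[1])
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    p = 1.0 if zero_margin else fisher_exact_two_sided(a, b, c, d)
    return PatternContingency(
        table=table.table, odds_ratio=odds, p_value=float(p), zero_margin=zero_margin
    )


def run_full_comparison_suite(
    burst_sets: dict[tuple[str, str], list[BurstSet]],
    pattern_labels: dict[tuple[str, str], list[Pattern]],
    ks_alpha: float = 0.001,
    proportion_alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """All pairwise group comparisons: KS per burst property, Fisher per pattern.

    Parameters
    ----------
    burst_sets
        Per group, the subsampled burst sets of its *bursting* neurons.
    pattern_labels
        Per group, one pattern label per recorded neuron (all neurons, not
        just bursting ones).

    Returns the KS comparison table, the Fisher pattern-proportion table,
    and the per-group pattern-count table.  Groups with no bursting cells
    are skipped from the KS grid with a logged warning.
    """
    groups = sorted(set(burst_sets) | set(pattern_labels))

    ks_rows = []
    pooled: dict[tuple[tuple[str, str], str], GroupDistribution] = {}
    for g in groups:
        sets = burst_sets.get(g, [])
        for prop in BURST_PROPERTIES:
            try:
                pooled[(g, prop)] = pool_group(sets, prop, group_key=g)
            except ValueError:
                logger.warning("group %s has no bursting cells for %s; skipped", g, prop)
    for ga, gb in itertools.combinations(groups, 2):
        for prop in BURST_PROPERTIES:
            da, db = pooled.get((ga, prop)), pooled.get((gb, prop))
            if da is None or db is None:
                continue
            res = ks_compare(da, db, alpha=ks_alpha)
            ks_rows.append(
                {
                    "property": prop,
                    "group_a": "/".join(ga),
                    "group_b": "/".join(gb),
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "D": res.d_statistic,
                    "p": res.p_value,
                    "significant": res.significant,
                }
            )
    ks_df = pd.DataFrame(
        ks_rows,
        columns=["property", "group_a", "group_b", "n_a", "n_b", "D", "p", "significant"],
    )

    count_rows = []
    for g in groups:
        labels = pattern_labels.get(g, [])
        row = {"group": "/".join(g), "n_neurons": len(labels)}
        for pat in Pattern:
            row[pat.value] = sum(1 for lab in labels if lab == pat)
        count_rows.append(row)
    counts_df = pd.DataFrame(count_rows)

    fisher_rows = []
    for ga, gb in itertools.combinations(groups, 2):
        la = pattern_labels.get(ga, [])
        lb = pattern_labels.get(gb, [])
        if not la or not lb:
            continue
        for pat in Pattern:
            ka = sum(1 for lab in la if lab == pat)
            kb = sum(1 for lab in lb if lab == pat)
            tab = PatternContingency(
                table=((ka, len(la) - ka), (kb, len(lb) - kb))
            )
            filled = pattern_proportion_test(tab)
            fisher_rows.append(
                {
                    "pattern": pat.value,
                    "group_a": "/".join(ga),
                    "group_b": "/".join(gb),
                    "a_with": ka,
                    "a_without": len(la) - ka,
                    "b_with": kb,
                    "b_without": len(lb) - kb,
                    "odds_ratio": filled.odds_ratio,
                    "p": filled.p_value,
                    "significant": filled.p_value < proportion_alpha,
                    "zero_margin": filled.zero_margin,
                }
            )
    fisher_df = pd.DataFrame(
        fisher_rows,
        columns=[
            "pattern",
            "group_a",
            "group_b",
            "a_with",
            "a_without",
            "b_with",
            "b_without",
            "odds_ratio",
            "p",
            "significant",
            "zero_margin",
        ],
    )

    return {"ks": ks_df, "patterns": counts_df, "fisher": fisher_df}
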