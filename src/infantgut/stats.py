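"""Cluster characterization statistics.

Pairwise Mann-Whitney U tests with Bonferroni correction, compact letter
displays summarizing which clusters differ, and Tukey-style box-plot
summaries.  Tests are two-sided throughout.  The Bonferroni family is the set
of cluster pairs within one variable (so 3 tests for 3 clusters), which is
configurable via the ``m`` argument of :func:`bonferroni`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "BoxSummary",
    "mann_whitney_u",
    "bonferroni",
    "letter_display",
    "compare_clusters",
    "box_summary",
]

#: largest pooled size for which the exact null enumeration is used
EXACT_LIMIT = 12


@dataclass
class GroupComparison:
    variable: str
    group1: Hashable
    group2: Hashable
    n1: int
    n2: int
    U: float
    p: float
    p_adj: float
    significant: bool
    method: str  # "exact" or "normal"
    testable: bool = True


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the first sample: #(x > y) pairs + half the tied pairs."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U: counts[u] over the C(n1+n2, n1) labelings.

    Standard counting recurrence for tie-free data:
    N(m, n, u) = N(m-1, n, u-n) + N(m, n-1, u), N(0, n, .) = N(m, 0, .) = delta_0.
    """
    max_u = n1 * n2
    table: dict[tuple[int, int], np.ndarray] = {}
    for m in range(n1 + 1):
        for n in range(n2 + 1):
            arr = np.zeros(max_u + 1)
            if m == 0 or n == 0:
                arr[0] = 1.0
            else:
                arr[n:] += table[(m - 1, n)][: max_u + 1 - n]
                arr += table[(m, n - 1)]
            table[(m, n)] = arr
    return table[(n1, n2)]


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    counts = _exact_u_counts(n1, n2)
    total = counts.sum()
    mean = n1 * n2 / 2.0
    dev = abs(u - mean)
    us = np.arange(len(counts))
    p = counts[np.abs(us - mean) >= dev - 1e-9].sum() / total
    return float(min(p, 1.0))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test; returns (U for x, p, method used).

    ``mode="exact"`` enumerates the null U distribution (tie-free data only);
    ``mode="normal"`` uses the normal approximation with tie and continuity
    corrections; ``mode="auto"`` picks exact when n1+n2 <= 12 and no value is
    shared across the two samples, normal otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    u = _u_statistic(x, y)
    cross_ties = bool(set(x.tolist()) & set(y.tolist()))
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= EXACT_LIMIT and not cross_ties) else "normal"
    if mode == "exact":
        if cross_ties:
            mode = "normal"  # exact enumeration undefined with cross-group ties
        else:
            return u, _exact_two_sided_p(u, x.size, y.size), "exact"
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue), "normal"


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p); m defaults to len(p)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def letter_display(
    groups: Sequence[Hashable],
    significant: Mapping[frozenset, bool],
) -> dict[Hashable, str]:
    """Compact letter display by insert-and-absorb.

    Groups that are *not* significantly different share at least one letter;
    significantly different groups share none.  Starts from one letter
    covering every group, splits it for each significant pair, then absorbs
    redundant letters, yielding a minimal display.  Groups are processed in
    the given label order and letters are named a, b, c, ... in order of
    creation.
    """
    groups = list(groups)
    sig: dict[frozenset, bool] = {}
    for pair, flag in significant.items():
        pair = frozenset(pair)
        if len(pair) != 2:
            raise ValueError(f"pair {set(pair)} is not two distinct groups")
        if pair in sig and sig[pair] != bool(flag):
            raise ValueError(f"conflicting significance for pair {set(pair)}")
        sig[pair] = bool(flag)

    letters: list[set[Hashable]] = [set(groups)]
    for g1, g2 in itertools.combinations(groups, 2):
        if not sig.get(frozenset((g1, g2)), False):
            continue
        new_letters: list[set[Hashable]] = []
        for letter in letters:
            if g1 in letter and g2 in letter:
                new_letters.append(letter - {g1})
                new_letters.append(letter - {g2})
            else:
                new_letters.append(letter)
        # absorb: drop empty letters and any strictly contained in another
        nonempty = [c for c in new_letters if c]
        letters = []
        for cand in nonempty:
            if any(cand < other for other in nonempty):
                continue
            if cand not in letters:
                letters.append(cand)
    # canonical naming: letters ordered by their earliest group in label order
    pos = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda s: sorted(pos[g] for g in s))
    names = "abcdefghijklmnopqrstuvwxyz"
    if len(letters) > len(names):
        raise ValueError("more than 26 letters required")
    out: dict[Hashable, str] = {}
    for g in groups:
        out[g] = "".join(names[i] for i, letter in enumerate(letters) if g in letter)
    if any(not v for v in out.values()):
        raise RuntimeError("letter display left a group without letters")
    return out


def compare_clusters(
    values: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    mode: str = "auto",
) -> tuple[list[GroupComparison], dict[str, dict[Hashable, str]]]:
    """All pairwise cluster comparisons for each variable, with letters.

    ``values`` is samples × variables; ``labels`` maps the same samples to
    cluster labels.  For each variable, every unordered cluster pair gets a
    two-sided Mann-Whitney U test; the Bonferroni family size is the number
    of pairs within that variable.  Missing values are dropped per pair; a
    pair whose group empties after removal is flagged untestable (never
    silently dropped).

    Returns the comparison records and, per variable, the compact letter
    display computed from adjusted significance at ``alpha`` (untestable
    pairs count as non-significant for the display).
    """
    labels = labels.loc[values.index]
    clusters = sorted(labels.dropna().unique(), key=str)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    pairs = list(itertools.combinations(clusters, 2))
    m = len(pairs)
    comparisons: list[GroupComparison] = []
    letter_maps: dict[str, dict[Hashable, str]] = {}
    for var in values.columns:
        per_var: list[GroupComparison] = []
        for g1, g2 in pairs:
            x = values.loc[labels == g1, var].dropna().to_numpy()
            y = values.loc[labels == g2, var].dropna().to_numpy()
            if x.size == 0 or y.size == 0:
                per_var.append(
                    GroupComparison(var, g1, g2, x.size, y.size, math.nan,
                                    math.nan, math.nan, False, "none", testable=False)
                )
                continue
            u, p, method = mann_whitney_u(x, y, mode=mode)
            p_adj = bonferroni([p], m=m)[0]
            per_var.append(
                GroupComparison(var, g1, g2, x.size, y.size, u, p, p_adj,
                                p_adj < alpha, method)
            )
        sig = {
            frozenset((c.group1, c.group2)): c.significant
            for c in per_var
            if c.testable
        }
        letter_maps[var] = letter_display(clusters, sig)
        comparisons.extend(per_var)
    return comparisons, letter_maps


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tidy TSV-ready table of comparison results."""
    return pd.DataFrame(
        [
            {
                "variable": c.variable,
                "group1": c.group1,
                "group2": c.group2,
                "n1": c.n1,
                "n2": c.n2,
                "U": c.U,
                "p": c.p,
                "p_adj": c.p_adj,
                "significant": c.significant,
                "method": c.method,
                "testable": c.testable,
            }
            for c in comparisons
        ]
    )


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Tukey box-plot summary: type-7 quartiles, whiskers at 1.5 IQR.

    Whiskers sit at the most extreme data points within 1.5 interquartile
    ranges of the quartiles; values strictly beyond are outliers.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # numpy default = type-7
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_low, whisker_high = float(inside.min()), float(inside.max())
    outliers = sorted(v[(v < whisker_low) | (v > whisker_high)].tolist())
    return BoxSummary(float(med), float(q1), float(q3), whisker_low, whisker_high, outliers)
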