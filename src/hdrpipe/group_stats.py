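"""Nonparametric group comparisons over per-individual percentages.

The analysis convention mirrors standard practice for small, non-normal
editing-efficiency cohorts: D'Agostino-Pearson omnibus normality first,
then Kruskal-Wallis with Dunn's post-hoc test (Bonferroni-adjusted,
two-sided z on pooled tie-corrected ranks) for three or more groups, and
Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired, e.g. per-fish 5'
vs 3' junction percentages) for two.  Exact small-sample p-values are used
where tie-free enumeration is feasible; the thresholds are declared
constants, not heuristics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: exact Mann-Whitney enumeration is used when n*m is at most this and tie-free
MANN_WHITNEY_EXACT_MAX_NM = 10_000
#: exact signed-rank enumeration for at most this many non-zero pairs, tie-free
WILCOXON_EXACT_MAX_N = 25
#: minimum sample size for the D'Agostino-Pearson omnibus test
DAGOSTINO_MIN_N = 8


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    note: str = ""

    @property
    def valid(self) -> bool:
        return not math.isnan(self.p_value)


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupResult:
    """Omnibus + post-hoc output for one family of group comparisons."""

    test: str
    group_labels: tuple[str, ...]
    group_ns: tuple[int, ...]
    statistic: float
    p_value: float
    pairwise: tuple[PairwiseComparison, ...] = ()
    letters: dict[str, str] = field(default_factory=dict)


def dagostino_pearson(values) -> TestResult:
    """D'Agostino-Pearson K^2 omnibus normality test (chi-square, 2 df)."""
    x = np.asarray(values, dtype=float)
    if len(x) < DAGOSTINO_MIN_N:
        return TestResult("dagostino_pearson", math.nan, math.nan, (len(x),),
                          note=f"insufficient n (< {DAGOSTINO_MIN_N})")
    if np.ptp(x) == 0:
        return TestResult("dagostino_pearson", math.nan, math.nan, (len(x),),
                          note="degenerate: all values identical")
    k2, p = stats.normaltest(x)
    return TestResult("dagostino_pearson", float(k2), float(p), (len(x),))


def kruskal_wallis(groups: list) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("kruskal_wallis needs at least two non-empty groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0, tuple(map(len, arrays)),
                          note="all values identical")
    h, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), tuple(map(len, arrays)))


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U; exact by enumeration when tie-free and
    n*m <= 10,000, else normal approximation with tie correction."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return TestResult("mann_whitney", len(x) * len(y) / 2.0, 1.0,
                          (len(x), len(y)), note="all values identical")
    method = "exact" if (not ties and len(x) * len(y) <= MANN_WHITNEY_EXACT_MAX_NM) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      (len(x), len(y)), note=method)


def wilcoxon_paired(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank on paired values; zero differences
    are dropped (classic convention), exact for <= 25 tie-free non-zero
    pairs, else normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired test needs equal-length inputs")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        return TestResult("wilcoxon_paired", 0.0, 1.0, (len(x),),
                          note="degenerate: all differences zero")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (not ties and len(d) <= WILCOXON_EXACT_MAX_N) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return TestResult("wilcoxon_paired", float(res.statistic), float(res.pvalue),
                      (len(x),), note=f"{method}, {len(d)} non-zero pairs")


def dunn_posthoc(
    groups: list, labels: list[str] | None = None, alpha: float = 0.05
) -> tuple[tuple[PairwiseComparison, ...], dict[str, str]]:
    """Dunn's multiple-comparison test on pooled tie-corrected ranks with
    Bonferroni family-wise adjustment, plus a compact letter display."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    ns = np.array([len(a) for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term on the pooled ranks
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for n in ns:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    n_pairs = k * (k - 1) // 2
    comparisons = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_unit * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs)
        comparisons.append(PairwiseComparison(
            (labels[i], labels[j]), float(z), float(p_raw), float(p_adj),
            significant=p_adj < alpha))
    letters = compact_letter_display(
        labels, {c.pair for c in comparisons if c.significant})
    return tuple(comparisons), letters


def compact_letter_display(
    labels: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Assign lowercase letters so two groups share a letter iff they are
    *not* significantly different (insert-and-absorb algorithm)."""
    sig = {frozenset(p) for p in significant_pairs}
    letter_sets: list[set[str]] = [set(labels)]
    for pair in sig:
        a, b = tuple(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                letter_sets.extend([s - {a}, s - {b}])
    # absorb subsets
    letter_sets = [s for s in letter_sets if s]
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for t in letter_sets)
                   and s not in letter_sets[:i]]
    letter_sets.sort(key=lambda s: min(labels.index(x) for x in s))
    out: dict[str, list[str]] = {lab: [] for lab in labels}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", letter_sets):
        for lab in s:
            out[lab].append(letter)
    return {lab: "".join(sorted(v)) for lab, v in out.items()}


def compare_groups(
    values_by_group: dict[str, list], alpha: float = 0.05, paired: bool = False
) -> GroupResult:
    """Standard comparison flow: Kruskal-Wallis + Dunn for three or more
    groups; Mann-Whitney (or paired Wilcoxon) for two."""
    labels = list(values_by_group)
    groups = [values_by_group[k] for k in labels]
    ns = tuple(len(g) for g in groups)
    if len(groups) >= 3:
        omni = kruskal_wallis(groups)
        pairwise, letters = dunn_posthoc(groups, labels, alpha)
        return GroupResult("kruskal_wallis+dunn", tuple(labels), ns,
                           omni.statistic, omni.p_value, pairwise, letters)
    if len(groups) != 2:
        raise ValueError("need at least two groups")
    if paired:
        res = wilcoxon_paired(groups[0], groups[1])
    else:
        res = mann_whitney(groups[0], groups[1])
    sig = res.p_value < alpha
    letters = {labels[0]: "a", labels[1]: "b" if sig else "a"}
    return GroupResult(res.test, tuple(labels), ns, res.statistic, res.p_value,
                       letters=letters)
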