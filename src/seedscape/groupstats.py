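"""Nonparametric treatment comparison with Bonferroni-adapted contrasts.

The scheme mirrors the classical SPSS-style workflow for small germination
trials: an omnibus test chosen by design (two related samples → Wilcoxon
signed ranks; two unrelated → Mann–Whitney U; several related → Friedman;
several unrelated → Kruskal–Wallis H), followed by all pairwise two-sample
contrasts judged at the Bonferroni-adapted risk level α_B = α/k (k = number
of contrasts in the family), and a compact letter display in which groups
sharing a letter are exactly the pairs not significantly different.

Small samples get exact permutation p-values: mid-ranks with tie-corrected
statistics throughout, full enumeration whenever the arrangement count is
below a configurable threshold, and the usual large-sample approximations
beyond it.  All tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedSamples",
    "ContrastPlan",
    "ComparisonResult",
    "omnibus_test",
    "bonferroni_contrasts",
    "letter_display",
    "significance_from_letters",
    "kendall_trend",
    "compare_groups",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "friedman",
]

#: Enumerations up to this many arrangements are evaluated exactly.
MAX_EXACT_ARRANGEMENTS = 200_000

_EPS = 1e-12


@dataclass(frozen=True)
class GroupedSamples:
    """Labelled observation groups with their comparison design.

    ``design`` is ``"related"`` (matched units, equal group sizes required)
    or ``"unrelated"`` (independent groups).
    """

    labels: tuple[str, ...]
    samples: tuple[tuple[float, ...], ...]
    design: str = "unrelated"

    def __post_init__(self) -> None:
        if self.design not in ("related", "unrelated"):
            raise ValueError(f"design must be 'related' or 'unrelated', got {self.design!r}")
        if len(self.labels) != len(self.samples):
            raise ValueError("labels and samples must align")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 groups to compare")
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(
            self, "samples", tuple(tuple(float(v) for v in s) for s in self.samples)
        )
        if any(len(s) == 0 for s in self.samples):
            raise ValueError("every group needs at least one observation")
        if self.design == "related":
            sizes = {len(s) for s in self.samples}
            if len(sizes) != 1:
                raise ValueError("related design requires equal, aligned group sizes")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, value: str, group: str, design: str = "unrelated"
    ) -> "GroupedSamples":
        sub = df[[group, value]].dropna()
        labels, samples = [], []
        for lab, g in sub.groupby(group, sort=False):
            labels.append(str(lab))
            samples.append(tuple(g[value].astype(float)))
        return cls(tuple(labels), tuple(samples), design)


@dataclass(frozen=True)
class ContrastPlan:
    """Bonferroni adaptation of the risk level: α_B = α / k."""

    alpha: float = 0.05
    k_comparisons: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.k_comparisons < 1:
            raise ValueError("k_comparisons must be >= 1")

    @property
    def alpha_adjusted(self) -> float:
        return self.alpha / self.k_comparisons


@dataclass
class ComparisonResult:
    omnibus_name: str
    omnibus_statistic: float
    omnibus_p: float
    plan: ContrastPlan
    pairwise: pd.DataFrame
    letters: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# two-sample tests with exact small-sample enumeration
# ---------------------------------------------------------------------------


def _two_sided_from_symmetric(values: np.ndarray, obs: float, center: float) -> float:
    """P(|T - center| >= |obs - center|) over an enumerated null distribution."""
    dev = abs(obs - center)
    return float(np.mean(np.abs(values - center) >= dev - _EPS))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    max_exact: int = MAX_EXACT_ARRANGEMENTS,
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    Exact p by full enumeration of group assignments when C(n+m, n) is
    feasible (scipy's exact recurrence when the data are tie-free, a direct
    mid-rank enumeration otherwise); tie-corrected normal approximation
    with continuity correction beyond.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < n + m
    n_arr = math.comb(n + m, n)
    if n_arr <= max_exact:
        if not ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            return float(res.statistic), float(res.pvalue)
        ranks = stats.rankdata(pooled)
        obs = ranks[:n].sum()
        center = n * (n + m + 1) / 2.0
        sums = np.array(
            [ranks[list(idx)].sum() for idx in itertools.combinations(range(n + m), n)]
        )
        p = _two_sided_from_symmetric(sums, obs, center)
        u = obs - n * (n + 1) / 2.0
        return float(u), p
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    max_exact: int = MAX_EXACT_ARRANGEMENTS,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-ranks test for paired samples; (W+, p).

    Zero differences are dropped (Wilcoxon's convention).  Exact p by
    enumerating the 2^n sign assignments of the |difference| mid-ranks when
    feasible, normal approximation otherwise.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    center = n * (n + 1) / 4.0
    if 2**n <= max_exact:
        sums = np.zeros(1)
        for r in ranks:  # distribution of W+ under random signs
            sums = np.concatenate([sums, sums + r])
        return float(obs), _two_sided_from_symmetric(sums, obs, center)
    res = stats.wilcoxon(np.asarray(x, float), np.asarray(y, float), method="approx")
    return float(res.statistic), float(res.pvalue)


def _kw_statistic(rank_sums: np.ndarray, sizes: np.ndarray, n_total: int, tie_term: float) -> float:
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(rank_sums**2 / sizes) - 3 * (n_total + 1)
    return h / tie_term if tie_term > 0 else float("nan")


def kruskal_wallis(
    samples: Sequence[Sequence[float]],
    max_exact: int = MAX_EXACT_ARRANGEMENTS,
) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; (H, p).

    Exact p enumerates all distinct assignments of the pooled mid-ranks to
    the group sizes when the multinomial count is feasible; chi-squared
    approximation (k − 1 df) otherwise.
    """
    arrays = [np.asarray(s, float) for s in samples]
    sizes = np.array([len(a) for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    bounds = np.cumsum(sizes)[:-1]
    obs_sums = np.array([g.sum() for g in np.split(ranks, bounds)])
    h_obs = _kw_statistic(obs_sums, sizes, n_total, tie_term)

    n_arr = math.factorial(n_total)
    for s in sizes:
        n_arr //= math.factorial(s)
    if n_arr > max_exact or not np.isfinite(h_obs):
        if not np.isfinite(h_obs):
            return float("nan"), 1.0  # all observations identical
        return float(h_obs), float(stats.chi2.sf(h_obs, len(sizes) - 1))

    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], gi: int, sums: list[float]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            sums.append(ranks[list(remaining)].sum())
            h = _kw_statistic(np.array(sums), sizes, n_total, tie_term)
            total += 1
            if h >= h_obs - _EPS:
                count += 1
            sums.pop()
            return
        for idx in itertools.combinations(remaining, int(sizes[gi])):
            rest = tuple(i for i in remaining if i not in set(idx))
            sums.append(ranks[list(idx)].sum())
            recurse(rest, gi + 1, sums)
            sums.pop()

    recurse(tuple(range(n_total)), 0, [])
    return float(h_obs), count / total


def friedman(
    samples: Sequence[Sequence[float]],
    max_exact: int = MAX_EXACT_ARRANGEMENTS,
) -> tuple[float, float]:
    """Friedman test for k related samples over n aligned blocks; (chi2_r, p).

    Rows of the implicit block × treatment table are ranked with mid-ranks;
    exact p enumerates the (k!)^n within-block permutations when feasible,
    chi-squared approximation (k − 1 df) otherwise.
    """
    data = np.asarray(samples, float)  # k groups x n blocks
    k, n = data.shape
    blocks = data.T  # n x k
    rank_rows = np.array([stats.rankdata(row) for row in blocks])

    def statistic(rr: np.ndarray) -> float:
        # tie-corrected Friedman chi-square (as in scipy.stats.friedmanchisquare)
        col_sums = rr.sum(axis=0)
        ssbn = np.sum(col_sums**2)
        c = 1.0
        ties = 0.0
        for row in rr:
            _, cnt = np.unique(row, return_counts=True)
            ties += np.sum(cnt**3 - cnt)
        c = 1.0 - ties / (n * (k**3 - k))
        if c == 0:
            return float("nan")
        return (12.0 / (n * k * (k + 1)) * ssbn - 3 * n * (k + 1)) / c

    chi_obs = statistic(rank_rows)
    if not np.isfinite(chi_obs):
        return float("nan"), 1.0
    n_arr = math.factorial(k) ** n
    if n_arr > max_exact:
        return float(chi_obs), float(stats.chi2.sf(chi_obs, k - 1))

    perms_per_block = [
        [np.array(p) for p in itertools.permutations(row)] for row in rank_rows
    ]
    count = 0
    total = 0
    for combo in itertools.product(*perms_per_block):
        chi = statistic(np.array(combo))
        total += 1
        if chi >= chi_obs - _EPS:
            count += 1
    return float(chi_obs), count / total


# ---------------------------------------------------------------------------
# dispatch, contrasts, letters
# ---------------------------------------------------------------------------


def omnibus_test(
    samples: GroupedSamples, max_exact: int = MAX_EXACT_ARRANGEMENTS
) -> tuple[str, float, float]:
    """Design-dispatched omnibus test; returns (test name, statistic, p)."""
    k = len(samples.labels)
    if samples.design == "related":
        if k == 2:
            stat, p = wilcoxon_signed_rank(samples.samples[0], samples.samples[1], max_exact)
            return "wilcoxon-signed-ranks", stat, p
        stat, p = friedman(samples.samples, max_exact)
        return "friedman", stat, p
    if k == 2:
        stat, p = mann_whitney(samples.samples[0], samples.samples[1], max_exact)
        return "mann-whitney-u", stat, p
    stat, p = kruskal_wallis(samples.samples, max_exact)
    return "kruskal-wallis-h", stat, p


def bonferroni_contrasts(
    samples: GroupedSamples,
    alpha: float = 0.05,
    max_exact: int = MAX_EXACT_ARRANGEMENTS,
) -> tuple[ContrastPlan, pd.DataFrame]:
    """All pairwise contrasts at the Bonferroni-adapted level α_B = α/k.

    k is the number of pairs actually tested in this family.  Pairs whose
    pooled values are all identical are degenerate: p = 1, flagged.
    """
    labels = samples.labels
    pairs = list(itertools.combinations(range(len(labels)), 2))
    plan = ContrastPlan(alpha=alpha, k_comparisons=len(pairs))
    test_name = (
        "wilcoxon-signed-ranks" if samples.design == "related" else "mann-whitney-u"
    )
    rows = []
    for i, j in pairs:
        a, b = samples.samples[i], samples.samples[j]
        degenerate = len(set(a) | set(b)) == 1
        if degenerate:
            stat, p = float("nan"), 1.0
        elif samples.design == "related":
            stat, p = wilcoxon_signed_rank(a, b, max_exact)
        else:
            stat, p = mann_whitney(a, b, max_exact)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "test": test_name,
                "statistic": stat,
                "p_value": p,
                "significant": bool(p < plan.alpha_adjusted),
                "degenerate": degenerate,
            }
        )
    return plan, pd.DataFrame(rows)


def _letter_sequence(n: int) -> list[str]:
    letters = list(string.ascii_lowercase)
    if n > 26:
        letters += [a + b for a in string.ascii_lowercase for b in string.ascii_lowercase]
    return letters[:n]


def letter_display(
    groups: Sequence[str], pairwise: pd.DataFrame
) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Two groups share at least one letter exactly when their pair is *not*
    significant; letter sets are minimized by absorbing subsets, and the
    result is deterministic in the input group order.  The pairwise frame
    must cover every unordered pair once with a boolean ``significant``
    column; an asymmetric/incomplete matrix is rejected.
    """
    groups = [str(g) for g in groups]
    order = {g: i for i, g in enumerate(groups)}
    sig: dict[frozenset, bool] = {}
    for r in pairwise.itertuples(index=False):
        a, b = str(r.group_a), str(r.group_b)
        if a not in order or b not in order or a == b:
            raise ValueError(f"pairwise row ({a}, {b}) does not match the group list")
        key = frozenset((a, b))
        if key in sig and sig[key] != bool(r.significant):
            raise ValueError(f"inconsistent significance for pair ({a}, {b})")
        sig[key] = bool(r.significant)
    expected = {frozenset(p) for p in itertools.combinations(groups, 2)}
    if set(sig) != expected:
        raise ValueError("pairwise table must cover every unordered pair exactly")

    columns: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if not sig[frozenset((a, b))]:
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop duplicates and any column strictly contained in another
        columns = []
        for col in new_columns:
            if col and not any(col < other for other in new_columns) and col not in columns:
                columns.append(col)

    columns.sort(key=lambda col: min(order[g] for g in col))
    letters = _letter_sequence(len(columns))
    out = {g: "" for g in groups}
    for letter, col in zip(letters, columns):
        for g in sorted(col, key=order.get):
            out[g] += letter
    if any(not v for v in out.values()):
        raise AssertionError("letter display left a group unlettered")
    return out


def significance_from_letters(letters: dict[str, str]) -> dict[frozenset, bool]:
    """Reconstruct the pairwise significance matrix from a letter display."""
    return {
        frozenset((a, b)): set(letters[a]).isdisjoint(letters[b])
        for a, b in itertools.combinations(letters, 2)
    }


def kendall_trend(
    x: Sequence[float], y: Sequence[float], exact_n: int = 10
) -> tuple[float, float]:
    """Kendall tau-b rank correlation with tie correction; (tau, p).

    Exact p for n <= ``exact_n`` (tie-free data), normal approximation
    beyond.  A constant series leaves tau undefined (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("kendall_trend needs >= 3 aligned pairs")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return float("nan"), float("nan")
    method = "exact" if (
        len(x) <= exact_n
        and len(np.unique(x)) == len(x)
        and len(np.unique(y)) == len(y)
    ) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    samples: GroupedSamples,
    alpha: float = 0.05,
    max_exact: int = MAX_EXACT_ARRANGEMENTS,
) -> ComparisonResult:
    """Omnibus test + Bonferroni contrasts + compact letter display."""
    name, stat, p = omnibus_test(samples, max_exact)
    plan, pairwise = bonferroni_contrasts(samples, alpha, max_exact)
    letters = letter_display(samples.labels, pairwise)
    return ComparisonResult(
        omnibus_name=name,
        omnibus_statistic=stat,
        omnibus_p=p,
        plan=plan,
        pairwise=pairwise,
        letters=letters,
    )
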