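"""Independent brute-force reference implementations used only by tests.

These deliberately take the naive route — per-seed event lists, full
permutation enumeration — so they share no code path with the package.
"""

from __future__ import annotations

import itertools
import statistics

import numpy as np
from scipy.stats import rankdata


def naive_indices(total_seeds: int, duration: int, counts: list[int]) -> dict:
    """All ten indices computed from the flat list of per-seed germination days."""
    days = [d for d, c in enumerate(counts, start=1) for _ in range(c)]
    g = len(days)
    out = {
        "fgp": 100.0 * g / total_seeds,
        "gri": sum(100.0 / total_seeds / d for d in days),
        "gi": float(sum(duration - d + 1 for d in days)),
    }
    if g == 0:
        out.update(mgt=None, mgr=None, fdg=None, ldg=None, t50=None,
                   st2=None, cvt=None, cvg=None)
        return out
    mgt = sum(days) / g
    out["mgt"] = mgt
    out["mgr"] = 1.0 / mgt
    out["fdg"] = min(days)
    out["ldg"] = max(days)
    out["cvg"] = 100.0 * g / sum(days)
    # T50 = linear interpolation of the cumulative-count step at (g+1)/2
    event_days = sorted(set(days))
    cum = np.cumsum([days.count(d) for d in event_days])
    out["t50"] = float(np.interp((g + 1) / 2.0, cum, event_days))
    if g >= 2:
        st2 = statistics.variance(days)
        out["st2"] = st2
        out["cvt"] = 100.0 * st2**0.5 / mgt
    else:
        out["st2"] = None
        out["cvt"] = None
    return out


def _two_sided(values: np.ndarray, obs: float, center: float) -> float:
    return float(np.mean(np.abs(values - center) >= abs(obs - center) - 1e-12))


def perm_mannwhitney_p(x, y) -> float:
    """Exact two-sided Mann–Whitney p by enumerating every group assignment."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n = len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n].sum()
    center = n * (len(pooled) + 1) / 2.0
    sums = np.array([sum(ranks[i] for i in idx)
                     for idx in itertools.combinations(range(len(pooled)), n)])
    return _two_sided(sums, obs, center)


def perm_wilcoxon_p(x, y) -> float:
    """Exact two-sided signed-ranks p by enumerating every sign vector."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    center = n * (n + 1) / 4.0
    sums = np.array([sum(r for r, s in zip(ranks, signs) if s > 0)
                     for signs in itertools.product((1, -1), repeat=n)])
    return _two_sided(sums, obs, center)


def _kw_h(groups) -> float:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum(sizes)[:-1]
    h = 12.0 / (n * (n + 1)) * sum(
        s.sum() ** 2 / len(s) for s in np.split(ranks, bounds)
    ) - 3 * (n + 1)
    _, cnt = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(cnt**3 - cnt) / (n**3 - n)
    return h / tie


def perm_kruskal_p(samples) -> float:
    """Exact Kruskal–Wallis p by enumerating every ordering of the pooled values."""
    sizes = [len(s) for s in samples]
    pooled = list(np.concatenate([np.asarray(s, float) for s in samples]))
    h_obs = _kw_h([np.asarray(s, float) for s in samples])
    count = total = 0
    bounds = np.cumsum(sizes)[:-1]
    for perm in itertools.permutations(pooled):
        groups = np.split(np.array(perm), bounds)
        total += 1
        if _kw_h(groups) >= h_obs - 1e-12:
            count += 1
    return count / total


def _friedman_chi(blocks: np.ndarray) -> float:
    n, k = blocks.shape
    rr = np.array([rankdata(row) for row in blocks])
    ssbn = np.sum(rr.sum(axis=0) ** 2)
    ties = sum(np.sum(cnt**3 - cnt)
               for _, cnt in (np.unique(row, return_counts=True) for row in rr))
    c = 1.0 - ties / (n * (k**3 - k))
    return (12.0 / (n * k * (k + 1)) * ssbn - 3 * n * (k + 1)) / c


def perm_friedman_p(samples) -> float:
    """Exact Friedman p by enumerating every within-block permutation."""
    data = np.asarray(samples, float)  # k x n
    blocks = data.T
    chi_obs = _friedman_chi(blocks)
    count = total = 0
    for combo in itertools.product(*(itertools.permutations(row) for row in blocks)):
        total += 1
        if _friedman_chi(np.array(combo)) >= chi_obs - 1e-12:
            count += 1
    return count / total
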