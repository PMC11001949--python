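"""The ten per-dish germination statistics.

Capacity (FGP), time (MGT, FDG, LDG, T50), rate (MGR, CVG, GRI, GI) and
homogeneity (CVt) indices computed from a daily-count schedule.  Notation:
``n_i`` seeds newly germinated on day ``t_i``, ``k`` trial days, ``N``
seeds sown per dish.

Indices that are undefined for an input — every time-based index when no
seed germinated, the timing dispersion when fewer than two did — are
returned as ``None`` and carried as missing values (never silent zeros)
so that replicate means are not biased; FGP, GRI and GI are genuinely
zero in that case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .schedule import CutTestSummary, GerminationSchedule

__all__ = [
    "GerminationIndices",
    "final_germination_percentage",
    "mean_germination_time",
    "mean_germination_rate",
    "germination_span",
    "median_germination_time",
    "germination_time_dispersion",
    "coefficient_of_velocity",
    "germination_rate_index",
    "germination_index",
    "compute_all_indices",
    "summarize_cut_test",
    "indices_frame",
    "treatment_summary",
]


@dataclass(frozen=True)
class GerminationIndices:
    """All ten indices for one dish; ``None`` marks an undefined index."""

    dish_id: str
    treatment_id: str
    fgp: float                      # final germination percentage, %
    mgt: Optional[float]            # mean germination time, days
    mgr: Optional[float]            # mean germination rate = 1/MGT, day^-1
    fdg: Optional[int]              # first day of germination
    ldg: Optional[int]              # last day of germination
    t50: Optional[float]            # median germination time, days
    st2: Optional[float]            # variance of germination time, days^2
    cvt: Optional[float]            # coefficient of variation of MGT, %
    cvg: Optional[float]            # coefficient of velocity = 100 * MGR
    gri: float                      # germination rate index, %/day
    gi: float                       # day-weighted germination index

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def final_germination_percentage(s: GerminationSchedule) -> float:
    """FGP = 100 * (sum n_i) / N."""
    return 100.0 * s.total_germinated / s.total_seeds


def mean_germination_time(s: GerminationSchedule) -> Optional[float]:
    """MGT = sum(n_i t_i) / sum(n_i); None when nothing germinated."""
    g = s.total_germinated
    if g == 0:
        return None
    return sum(c * d for d, c in s.events().items()) / g


def mean_germination_rate(s: GerminationSchedule) -> Optional[float]:
    """MGR = 1 / MGT."""
    mgt = mean_germination_time(s)
    return None if mgt is None else 1.0 / mgt


def germination_span(s: GerminationSchedule) -> tuple[Optional[int], Optional[int]]:
    """(FDG, LDG): first and last day with a germination event."""
    days = s.event_days
    if not days:
        return None, None
    return days[0], days[-1]


def median_germination_time(s: GerminationSchedule) -> Optional[float]:
    """Interpolated day by which half the germinated seeds have germinated.

    With N the final number of germinated seeds and cumulative counts c_i
    at the event days t_i, the half-count target is (N + 1)/2; the bracket
    (c_i, c_j) at adjacent event days is interpolated linearly:

        T50 = t_i + ((N + 1)/2 - c_i) * (t_j - t_i) / (c_j - c_i)

    Degenerate cases: a cumulative count hitting the target exactly returns
    its day; when germination occurs on a single day (or the first event day
    already reaches the target), that day is returned — the continuity limit
    of the interpolation.
    """
    events = s.events()
    if not events:
        return None
    days = sorted(events)
    total = s.total_germinated
    target = (total + 1) / 2.0
    cum = 0
    prev_day: Optional[int] = None
    prev_cum = 0
    for day in days:
        cum += events[day]
        if cum == target:
            return float(day)
        if cum > target:
            if prev_day is None:
                return float(day)
            return prev_day + (target - prev_cum) * (day - prev_day) / (cum - prev_cum)
        prev_day, prev_cum = day, cum
    return float(days[-1])  # unreachable for valid input; defensive


def germination_time_dispersion(
    s: GerminationSchedule,
) -> tuple[Optional[float], Optional[float]]:
    """(s_t^2, CVt): timing variance and its coefficient of variation.

    s_t^2 = sum n_i (t_i - MGT)^2 / (sum n_i - 1); CVt = 100 * s_t / MGT.
    Undefined below two germinations.
    """
    g = s.total_germinated
    if g < 2:
        return None, None
    mgt = mean_germination_time(s)
    st2 = sum(c * (d - mgt) ** 2 for d, c in s.events().items()) / (g - 1)
    return st2, 100.0 * math.sqrt(st2) / mgt


def coefficient_of_velocity(s: GerminationSchedule) -> Optional[float]:
    """CVG = 100 * sum(n_i) / sum(n_i t_i); identically 100 * MGR."""
    g = s.total_germinated
    if g == 0:
        return None
    return 100.0 * g / sum(c * d for d, c in s.events().items())


def germination_rate_index(s: GerminationSchedule, cumulative: bool = False) -> float:
    """GRI = sum over days of G_d / d, in %/day.

    G_d is by default the *daily* germination percentage on day d
    (100 * n_d / N, the Esechie convention, finite-additive over events);
    ``cumulative=True`` switches to the cumulative-percentage reading.
    Zero when nothing germinated.
    """
    if cumulative:
        cum = 0
        total = 0.0
        for day, c in enumerate(s.daily_counts, start=1):
            cum += c
            total += 100.0 * cum / s.total_seeds / day
        return total
    return sum(100.0 * c / s.total_seeds / d for d, c in s.events().items())


def germination_index(s: GerminationSchedule) -> float:
    """GI = sum (k - d + 1) * n_d: early germinations weighted most.

    Generalizes the 60-day weighting (60 * n_1 + 59 * n_2 + ... + 1 * n_60)
    to trials of any duration k.
    """
    k = s.duration_days
    return float(sum((k - d + 1) * c for d, c in s.events().items()))


def compute_all_indices(s: GerminationSchedule) -> GerminationIndices:
    """All ten indices for one dish, with undefined markers propagated."""
    fdg, ldg = germination_span(s)
    st2, cvt = germination_time_dispersion(s)
    return GerminationIndices(
        dish_id=s.dish_id,
        treatment_id=s.treatment_id,
        fgp=final_germination_percentage(s),
        mgt=mean_germination_time(s),
        mgr=mean_germination_rate(s),
        fdg=fdg,
        ldg=ldg,
        t50=median_germination_time(s),
        st2=st2,
        cvt=cvt,
        cvg=coefficient_of_velocity(s),
        gri=germination_rate_index(s),
        gi=germination_index(s),
    )


def summarize_cut_test(c: CutTestSummary) -> dict:
    """Percent breakdown of the cut test over the seeds dissected."""
    return {
        "dish_id": c.dish_id,
        "n_viable": c.n_viable,
        "n_empty": c.n_empty,
        "n_dead": c.n_dead,
        "pct_viable": c.pct_viable,
        "pct_empty": c.pct_empty,
        "pct_dead": c.pct_dead,
    }


_INDEX_COLUMNS = ["fgp", "mgt", "mgr", "fdg", "ldg", "t50", "st2", "cvt", "cvg", "gri", "gi"]


def indices_frame(schedules: Iterable[GerminationSchedule]) -> pd.DataFrame:
    """One row of indices per dish; undefined indices become NaN."""
    rows = [compute_all_indices(s).as_dict() for s in schedules]
    df = pd.DataFrame(rows, columns=["dish_id", "treatment_id"] + _INDEX_COLUMNS)
    return df.astype({c: float for c in _INDEX_COLUMNS})


def treatment_summary(
    indices: pd.DataFrame, table2_style: bool = False
) -> pd.DataFrame:
    """Mean and SD of every index per treatment, across replicate dishes.

    Undefined (NaN) per-dish values are excluded from the means rather than
    treated as zeros.  With ``table2_style`` the frame is formatted as
    ``mean ± sd`` strings at the customary printed precision (1 d.p. for
    percentages and days, 3 d.p. for MGR).
    """
    cols = [c for c in _INDEX_COLUMNS if c in indices.columns]
    g = indices.groupby("treatment_id", sort=False)[cols]
    mean = g.mean()
    sd = g.std(ddof=1)
    if not table2_style:
        out = pd.concat({"mean": mean, "sd": sd}, axis=1)
        out.columns = [f"{idx}_{stat}" for stat, idx in out.columns]
        return out.reset_index()

    def fmt(index: str, m: float, s: float) -> str:
        if np.isnan(m):
            return "NA"
        dp = 3 if index == "mgr" else 1
        return f"{m:.{dp}f} ± {s:.{dp}f}" if not np.isnan(s) else f"{m:.{dp}f}"

    styled = pd.DataFrame(
        {c: [fmt(c, mean.loc[t, c], sd.loc[t, c]) for t in mean.index] for c in cols},
        index=mean.index,
    )
    return styled.reset_index()
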