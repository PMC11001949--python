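"""Seeded generators for germination trials, climate series and land-cover tables.

Every generator is a pure function of (config, seed): identical inputs
give identical outputs.  Defaults emulate the study design the analysis
modules expect — four treatments with four replicate dishes of 20 achenes
scored daily over 60 days, germination fractions between 14 and 32% with
onset around day 25–32; a 90-year annual climate series with piecewise
linear window trends; and a ~42,400 ha territory partitioned among CLC
classes whose shares drift between survey years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import CutTestSummary, GerminationSchedule
from .landcover import ESA_CLASSES

__all__ = [
    "TreatmentParams",
    "GerminationSimConfig",
    "ClimateSegment",
    "ClimateSimConfig",
    "LandcoverSimConfig",
    "default_germination_config",
    "default_climate_config",
    "default_landcover_config",
    "simulate_germination_experiment",
    "simulate_climate",
    "simulate_landcover",
]


@dataclass(frozen=True)
class TreatmentParams:
    """Germination law for one treatment.

    p_germ is the probability a seed germinates within the trial; the
    germination day of a germinating seed is drawn from a normal law with
    mean ``mu_day`` and sd ``sigma_day`` truncated to [1, duration] and
    rounded half-up to whole days (``law="lognormal"`` switches to a
    lognormal with matching median/spread).
    """

    p_germ: float
    mu_day: float
    sigma_day: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_germ <= 1:
            raise ValueError(f"p_germ must be in [0, 1], got {self.p_germ}")
        if self.sigma_day < 0:
            raise ValueError("sigma_day must be >= 0")


@dataclass(frozen=True)
class GerminationSimConfig:
    treatments: dict[str, TreatmentParams]
    n_seeds: int = 20
    n_replicates: int = 4
    duration_days: int = 60
    empty_seed_fraction: float = 0.80   # of non-germinating seeds
    dead_seed_fraction: float = 0.15    # of non-germinating seeds
    law: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.empty_seed_fraction < 0 or self.dead_seed_fraction < 0:
            raise ValueError("cut-test fractions must be non-negative")
        if self.empty_seed_fraction + self.dead_seed_fraction > 1 + 1e-9:
            raise ValueError("empty + dead fractions exceed 1")
        if self.law not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown germination-day law {self.law!r}")
        for name, t in self.treatments.items():
            if not 1 <= t.mu_day <= self.duration_days:
                raise ValueError(
                    f"treatment {name!r}: mu_day {t.mu_day} outside [1, {self.duration_days}]"
                )


def default_germination_config() -> GerminationSimConfig:
    """The four-treatment study design: GA3 on blotting paper or agar at 10/15 degC."""
    return GerminationSimConfig(
        treatments={
            "GA3_paper_10C": TreatmentParams(p_germ=0.17, mu_day=30.3, sigma_day=4.5),
            "GA3_paper_15C": TreatmentParams(p_germ=0.14, mu_day=36.0, sigma_day=5.7),
            "GA3_agar_10C": TreatmentParams(p_germ=0.32, mu_day=32.5, sigma_day=5.1),
            "GA3_agar_15C": TreatmentParams(p_germ=0.23, mu_day=34.4, sigma_day=3.6),
        }
    )


def _draw_days(
    rng: np.random.Generator, n: int, t: TreatmentParams, duration: int, law: str
) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    if t.sigma_day == 0:
        raw = np.full(n, t.mu_day)
    elif law == "truncnorm":
        a = (1 - t.mu_day) / t.sigma_day
        b = (duration - t.mu_day) / t.sigma_day
        raw = stats.truncnorm.rvs(a, b, loc=t.mu_day, scale=t.sigma_day, size=n, random_state=rng)
    else:  # lognormal with median mu_day and log-sd sigma/mu (small-cv match)
        raw = np.exp(rng.normal(np.log(t.mu_day), t.sigma_day / t.mu_day, size=n))
        raw = np.clip(raw, 1, duration)
    days = np.floor(raw + 0.5).astype(int)  # round half-up to whole days
    return np.clip(days, 1, duration)


def simulate_germination_experiment(
    config: GerminationSimConfig, seed: int
) -> tuple[list[GerminationSchedule], list[CutTestSummary]]:
    """Simulate every dish of the experiment; reproducible given the seed.

    Each seed germinates independently with its treatment's p_germ; the
    germination day follows the configured law; non-germinating seeds are
    partitioned empty / dead / viable-ungerminated by the configured
    cut-test fractions.
    """
    rng = np.random.default_rng(seed)
    schedules: list[GerminationSchedule] = []
    cut_tests: list[CutTestSummary] = []
    for name, t in config.treatments.items():
        for rep in range(1, config.n_replicates + 1):
            dish_id = f"{name}_r{rep}"
            n_germ = rng.binomial(config.n_seeds, t.p_germ)
            days = _draw_days(rng, n_germ, t, config.duration_days, config.law)
            counts = np.bincount(days, minlength=config.duration_days + 1)[1:]
            schedules.append(
                GerminationSchedule(
                    dish_id=dish_id,
                    treatment_id=name,
                    total_seeds=config.n_seeds,
                    duration_days=config.duration_days,
                    daily_counts=tuple(int(c) for c in counts),
                )
            )
            n_rest = config.n_seeds - n_germ
            if n_rest > 0:
                viable_frac = 1.0 - config.empty_seed_fraction - config.dead_seed_fraction
                empty, dead, viable = rng.multinomial(
                    n_rest,
                    [config.empty_seed_fraction, config.dead_seed_fraction, max(viable_frac, 0.0)],
                )
                cut_tests.append(CutTestSummary(dish_id, int(viable), int(empty), int(dead)))
    return schedules, cut_tests


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateSegment:
    """Linear mean of one variable from (start_year, start_value) to (end_year, end_value)."""

    start_year: int
    end_year: int
    start_value: float
    end_value: float

    def mean_at(self, year: int) -> float:
        f = (year - self.start_year) / (self.end_year - self.start_year)
        return self.start_value + f * (self.end_value - self.start_value)


@dataclass(frozen=True)
class ClimateSimConfig:
    temp_segments: tuple[ClimateSegment, ...]
    rain_segments: tuple[ClimateSegment, ...]
    temp_noise_sd: float = 0.3      # degC
    rain_noise_sd: float = 100.0    # mm

    def __post_init__(self) -> None:
        for segs in (self.temp_segments, self.rain_segments):
            ordered = sorted(segs, key=lambda s: s.start_year)
            for a, b in zip(ordered, ordered[1:]):
                if b.start_year <= a.end_year:
                    raise ValueError(
                        f"overlapping climate segments: {a.start_year}-{a.end_year} "
                        f"and {b.start_year}-{b.end_year}"
                    )


def default_climate_config() -> ClimateSimConfig:
    """Piecewise trends shaped like the study area's 90-year station record.

    Temperature: 15.4→15.2 degC over 1931–1960, 15.1→16.2 over 1961–1990,
    16.2→15.2 over 1991–2020 (window deltas −0.2, +1.1, −1.0 degC, overall
    rise ≈ +0.5).  Rainfall: 1050→850, 950→800, 880→1050 mm.
    """
    return ClimateSimConfig(
        temp_segments=(
            ClimateSegment(1931, 1960, 15.4, 15.2),
            ClimateSegment(1961, 1990, 15.1, 16.2),
            ClimateSegment(1991, 2020, 16.2, 15.2),
        ),
        rain_segments=(
            ClimateSegment(1931, 1960, 1050.0, 850.0),
            ClimateSegment(1961, 1990, 950.0, 800.0),
            ClimateSegment(1991, 2020, 880.0, 1050.0),
        ),
    )


def simulate_climate(config: ClimateSimConfig, seed: int) -> pd.DataFrame:
    """Annual (year, temp_c, rain_mm) series: piecewise mean + Gaussian noise."""
    rng = np.random.default_rng(seed)
    years = range(
        min(s.start_year for s in config.temp_segments + config.rain_segments),
        max(s.end_year for s in config.temp_segments + config.rain_segments) + 1,
    )

    def mean_for(segs: Sequence[ClimateSegment], year: int) -> float:
        for s in segs:
            if s.start_year <= year <= s.end_year:
                return s.mean_at(year)
        return np.nan

    rows = []
    for year in years:
        t_mean = mean_for(config.temp_segments, year)
        r_mean = mean_for(config.rain_segments, year)
        t = t_mean + rng.normal(0, config.temp_noise_sd) if np.isfinite(t_mean) else np.nan
        r = r_mean + rng.normal(0, config.rain_noise_sd) if np.isfinite(r_mean) else np.nan
        rows.append({"year": year, "temp_c": t, "rain_mm": max(r, 0.0) if np.isfinite(r) else r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# land cover / ESA shares
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandcoverSimConfig:
    """Share-drift model for class-area tables on a fixed territory.

    ``transfers`` moves share points from one class to another between
    consecutive survey years: a list (per period) of (from_class,
    to_class, pp) triples.  Shares are clipped at zero and renormalized to
    100, then scaled to ``total_area_ha``.  ESA shares evolve the same way
    over the eight sensitivity classes.
    """

    classes: tuple[str, ...]
    initial_shares: tuple[float, ...]
    years: tuple[int, ...]
    transfers: tuple[tuple[tuple[str, str, float], ...], ...] = ()
    total_area_ha: float = 42_400.0
    noise_sd_pp: float = 0.0
    esa_initial_shares: Optional[tuple[float, ...]] = None
    esa_transfers: tuple[tuple[tuple[str, str, float], ...], ...] = ()

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.initial_shares):
            raise ValueError("classes and initial_shares must align")
        if abs(sum(self.initial_shares) - 100.0) > 1e-6:
            raise ValueError("initial shares must sum to 100")
        if self.transfers and len(self.transfers) != len(self.years) - 1:
            raise ValueError("need one transfer list per consecutive-year period")
        if self.esa_transfers and len(self.esa_transfers) != len(self.years) - 1:
            raise ValueError("need one ESA transfer list per consecutive-year period")


def default_landcover_config() -> LandcoverSimConfig:
    """A compact agricultural→forest succession over six survey years."""
    return LandcoverSimConfig(
        classes=("1.1.2", "2.1.1", "2.2.2", "2.4.3", "3.1.1", "3.2.1"),
        initial_shares=(1.5, 30.0, 22.0, 10.0, 20.0, 16.5),
        years=(1958, 1990, 2000, 2006, 2012, 2018),
        transfers=(
            (("2.1.1", "3.1.1", 10.0),),
            (("2.2.2", "2.4.3", 5.0),),
            (("2.1.1", "3.2.1", 5.0),),
            (("2.2.2", "2.4.3", 10.0),),
            (("2.1.1", "3.1.1", 5.0),),
        ),
    )


def _drift(
    shares: dict[str, float],
    moves: Sequence[tuple[str, str, float]],
    rng: np.random.Generator,
    noise_sd: float,
) -> dict[str, float]:
    out = dict(shares)
    for src, dst, pp in moves:
        out[src] -= pp
        out[dst] += pp
    if noise_sd > 0:
        for c in out:
            out[c] += rng.normal(0, noise_sd)
    clipped = {c: max(v, 0.0) for c, v in out.items()}
    total = sum(clipped.values())
    return {c: 100.0 * v / total for c, v in clipped.items()}


def simulate_landcover(
    config: LandcoverSimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(LandCoverTable, EsaShareTable) frames evolved by the drift model."""
    rng = np.random.default_rng(seed)
    shares = dict(zip(config.classes, config.initial_shares))
    rows = []
    for i, year in enumerate(config.years):
        if i > 0:
            moves = config.transfers[i - 1] if config.transfers else ()
            shares = _drift(shares, moves, rng, config.noise_sd_pp)
        for c in config.classes:
            rows.append(
                {
                    "class_code": c,
                    "class_name": c,
                    "year": year,
                    "area_ha": config.total_area_ha * shares[c] / 100.0,
                }
            )
    landcover = pd.DataFrame(rows)

    esa_shares = config.esa_initial_shares
    if esa_shares is None:
        esa_shares = (40.0, 20.0, 10.0, 10.0, 5.0, 5.0, 5.0, 5.0)
    esa = dict(zip(ESA_CLASSES, esa_shares))
    esa_rows = []
    for i, year in enumerate(config.years):
        if i > 0:
            moves = config.esa_transfers[i - 1] if config.esa_transfers else ()
            esa = _drift(esa, moves, rng, config.noise_sd_pp)
        for c in ESA_CLASSES:
            esa_rows.append({"esa_class": c, "year": year, "share_percent": esa[c]})
    return landcover, pd.DataFrame(esa_rows)
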