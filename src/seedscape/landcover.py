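"""Multi-temporal land-cover composition and change accounting.

Operates on class-by-year area tables (CORINE Land Cover level-III codes,
areas in hectares), optionally crosswalked from an older classification
(e.g. the 1958 CNR-TCI soil-use map).  Percentage composition uses the
sum of *non-missing* areas of that year as denominator — "n.a." areas are
tracked, never silently counted as zero — and rounding to 1 d.p. happens
only at the presentation layer.  Also summarizes desertification
sensitivity (ESA) class shares: not affected, potential, fragile 1–3,
critical 1–3.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandcoverValidationError",
    "ESA_CLASSES",
    "DEFAULT_AFFECTED_CLASSES",
    "validate_landcover",
    "apply_crosswalk",
    "composition",
    "rollup_level1",
    "change_matrix",
    "validate_esa",
    "esa_summary",
    "read_landcover_csv",
    "read_crosswalk_csv",
    "read_esa_csv",
]

CLC_LEVEL1 = {"1": "urban", "2": "agricultural", "3": "forest_semi_natural",
              "4": "wetlands", "5": "water"}

ESA_CLASSES = (
    "not affected", "potential",
    "fragile 1", "fragile 2", "fragile 3",
    "critical 1", "critical 2", "critical 3",
)

#: Classes counted as "affected land" by default: every fragile + critical class.
DEFAULT_AFFECTED_CLASSES = tuple(c for c in ESA_CLASSES if c not in ("not affected", "potential"))


class LandcoverValidationError(ValueError):
    pass


def validate_landcover(df: pd.DataFrame) -> pd.DataFrame:
    required = {"class_code", "class_name", "year", "area_ha"}
    if not required.issubset(df.columns):
        raise LandcoverValidationError(
            f"land-cover frame missing columns: {sorted(required - set(df.columns))}"
        )
    dup = df.duplicated(subset=["class_code", "year"])
    if dup.any():
        bad = df.loc[dup, ["class_code", "year"]].to_records(index=False).tolist()
        raise LandcoverValidationError(f"duplicate (class_code, year) records: {bad}")
    areas = df["area_ha"].dropna()
    if (areas < 0).any():
        raise LandcoverValidationError("areas must be non-negative")
    for year, g in df.groupby("year"):
        if g["area_ha"].dropna().empty:
            raise LandcoverValidationError(f"year {year} has no non-missing areas")
    return df


def _is_clc_code(code: str) -> bool:
    parts = str(code).split(".")
    return (
        len(parts) == 3
        and all(p.isdigit() for p in parts)
        and parts[0] in CLC_LEVEL1
    )


def apply_crosswalk(df: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Re-key class codes through a source-label → CLC-code crosswalk.

    Many-to-one mappings sum areas per (CLC code, year); total area is
    conserved (checked to 0.01 ha).  Labels absent from the map are an
    error listing every offender.
    """
    validate_landcover(df)
    unmapped = sorted(set(df["class_code"].astype(str)) - set(map(str, mapping)))
    if unmapped:
        raise LandcoverValidationError(f"classes missing from crosswalk: {unmapped}")
    out = df.copy()
    out["class_code"] = out["class_code"].astype(str).map({str(k): str(v) for k, v in mapping.items()})
    merged = (
        out.groupby(["class_code", "year"], as_index=False)
        .agg(class_name=("class_name", "first"), area_ha=("area_ha", lambda a: a.sum(min_count=1)))
    )
    before = df["area_ha"].sum(skipna=True)
    after = merged["area_ha"].sum(skipna=True)
    if abs(before - after) > 0.01:
        raise LandcoverValidationError(
            f"crosswalk failed area conservation: {before} -> {after} ha"
        )
    return merged[["class_code", "class_name", "year", "area_ha"]]


def composition(df: pd.DataFrame, year: int) -> pd.DataFrame:
    """Per-class percentage shares for one year.

    share = 100 * area / (sum of non-missing areas that year).  Classes
    with a missing area get a missing share (flagged), not zero.
    """
    validate_landcover(df)
    sub = df[df["year"] == year]
    if sub.empty:
        raise LandcoverValidationError(f"year {year} not present in table")
    total = sub["area_ha"].sum(skipna=True)
    if total <= 0:
        raise LandcoverValidationError(f"year {year} has non-positive total area")
    out = sub.copy()
    out["share_pct"] = 100.0 * out["area_ha"] / total
    out["missing"] = out["area_ha"].isna()
    return out[["class_code", "class_name", "area_ha", "share_pct", "missing"]].reset_index(drop=True)


def rollup_level1(
    df: pd.DataFrame, year: int, rounded_shares: bool = False
) -> pd.Series:
    """Percentage shares aggregated to CLC level-1 groups (leading digit).

    With ``rounded_shares`` the level-III shares are first rounded to
    1 d.p. and then summed — the convention of printed composition tables,
    where the group total is the sum of the printed class percentages.
    Non-CLC codes are rejected; crosswalk first.
    """
    comp = composition(df, year)
    bad = [c for c in comp["class_code"].astype(str) if not _is_clc_code(c)]
    if bad:
        raise LandcoverValidationError(
            f"non-CLC class codes (apply a crosswalk first): {sorted(set(bad))}"
        )
    shares = comp["share_pct"].round(1) if rounded_shares else comp["share_pct"]
    level1 = comp["class_code"].astype(str).str.split(".").str[0]
    out = shares.groupby(level1).sum()
    out.index = [f"{code} ({CLC_LEVEL1[code]})" for code in out.index]
    return out


def change_matrix(df: pd.DataFrame, year_a: int, year_b: int) -> pd.DataFrame:
    """Per-class deltas between two years, in hectares and share points.

    A class missing ("n.a.") or absent in one year contributes from a zero
    baseline and is flagged; the antisymmetry change(a,b) == -change(b,a)
    holds elementwise on the deltas.
    """
    if year_a == year_b:
        raise LandcoverValidationError("change_matrix needs two distinct years")
    ca = composition(df, year_a).set_index("class_code")
    cb = composition(df, year_b).set_index("class_code")
    codes = sorted(set(ca.index) | set(cb.index))
    rows = []
    for code in codes:
        a_area = ca["area_ha"].get(code, np.nan)
        b_area = cb["area_ha"].get(code, np.nan)
        a_share = ca["share_pct"].get(code, np.nan)
        b_share = cb["share_pct"].get(code, np.nan)
        flagged = bool(np.isnan(a_area) or np.isnan(b_area))
        rows.append(
            {
                "class_code": code,
                "class_name": (
                    ca["class_name"].get(code) if code in ca.index else cb["class_name"].get(code)
                ),
                "area_a_ha": a_area,
                "area_b_ha": b_area,
                "delta_ha": np.nan_to_num(b_area) - np.nan_to_num(a_area),
                "share_a_pct": a_share,
                "share_b_pct": b_share,
                "delta_pp": np.nan_to_num(b_share) - np.nan_to_num(a_share),
                "missing_data": flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ESA desertification-sensitivity shares
# ---------------------------------------------------------------------------


def validate_esa(df: pd.DataFrame, tol: float = 0.5) -> list[str]:
    """Invariant check for an ESA share table; returns warning strings."""
    required = {"esa_class", "year", "share_percent"}
    if not required.issubset(df.columns):
        raise LandcoverValidationError(
            f"ESA frame missing columns: {sorted(required - set(df.columns))}"
        )
    unknown = sorted(set(df["esa_class"].astype(str)) - set(ESA_CLASSES))
    if unknown:
        raise LandcoverValidationError(f"unknown ESA classes: {unknown}")
    warnings = []
    for year, g in df.groupby("year"):
        s = g["share_percent"].sum(skipna=True)
        if abs(s - 100.0) > tol:
            warnings.append(f"year {year}: shares sum to {s:.2f}, not 100")
    return warnings


def esa_summary(
    df: pd.DataFrame,
    affected_classes: Sequence[str] = DEFAULT_AFFECTED_CLASSES,
    renormalize: bool = False,
) -> dict:
    """Desertification class-share deltas plus the affected-land aggregate.

    Returns per-class share deltas between consecutive years, the
    aggregate share of ``affected_classes`` (default: every fragile and
    critical class) per year, and its first-to-last change.  Shares not
    summing to 100 raise a warning entry; ``renormalize`` rescales each
    year to exactly 100 before summarizing.
    """
    warnings = validate_esa(df)
    work = df.copy()
    if renormalize:
        totals = work.groupby("year")["share_percent"].transform("sum")
        work["share_percent"] = 100.0 * work["share_percent"] / totals
    years = sorted(work["year"].unique())
    if len(years) < 2:
        raise LandcoverValidationError("ESA summary needs at least two years")
    wide = work.pivot_table(index="esa_class", columns="year", values="share_percent", aggfunc="sum")
    deltas = {}
    for y0, y1 in zip(years, years[1:]):
        d = (wide.get(y1) - wide.get(y0)).dropna()
        deltas[(y0, y1)] = d.to_dict()
    affected = {
        int(y): float(wide.loc[wide.index.isin(affected_classes), y].sum(skipna=True))
        for y in years
    }
    return {
        "years": [int(y) for y in years],
        "per_class_deltas": deltas,
        "affected_share_by_year": affected,
        "affected_delta": affected[int(years[-1])] - affected[int(years[0])],
        "warnings": warnings,
    }


def read_landcover_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", "n.a.", "n.a"])
    return validate_landcover(df)


def read_crosswalk_csv(path) -> dict[str, str]:
    df = pd.read_csv(path)
    required = {"source_label", "clc_code"}
    if not required.issubset(df.columns):
        raise LandcoverValidationError(
            f"crosswalk CSV missing columns: {sorted(required - set(df.columns))}"
        )
    return dict(zip(df["source_label"].astype(str), df["clc_code"].astype(str)))


def read_esa_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", "n.a.", "n.a"])
    validate_esa(df)
    return df
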