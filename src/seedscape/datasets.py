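"""Packaged reference tables for the Nebrodi study territory.

Two small published summary tables ship with the package so the analysis
modules can be exercised end-to-end without external data: the
per-treatment germination-index summary (mean ± sd over four replicate
dishes for the four GA3 treatments) and the class-by-year land-cover area
table (CNR-TCI 1958 crosswalked to CLC level III, then CLC surveys
1990–2018, in hectares, with "NA" where a class was not mapped).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .landcover import validate_landcover

__all__ = ["load_germination_summary", "load_nebrodi_landcover"]


def _data_path(name: str):
    return resources.files("seedscape").joinpath("data", name)


def load_germination_summary() -> pd.DataFrame:
    """Per-treatment germination index summary (mean/sd columns per index)."""
    with resources.as_file(_data_path("nebrodi_germination_summary.csv")) as p:
        return pd.read_csv(p)


def load_nebrodi_landcover() -> pd.DataFrame:
    """Class-by-year land-cover areas (ha) for the study territory, 1958–2018."""
    with resources.as_file(_data_path("nebrodi_landcover_1958_2018.csv")) as p:
        df = pd.read_csv(p, na_values=["NA"])
    return validate_landcover(df)
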