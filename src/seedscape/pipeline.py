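"""End-to-end pipeline: indices → comparisons → climate → land cover.

Ties the analysis stages into one reproducible run over the CSV dialects
the modules consume (comma-separated, UTF-8, header row, "NA" for
missing).  Every run writes a manifest recording the package version, the
seed, the configuration echo and per-stage row counts; validation
failures abort with an error naming the offending file and rule.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .climate import DEFAULT_WINDOWS, read_climate_csv, summarize_windows
from .groupstats import GroupedSamples, compare_groups
from .indices import indices_frame, summarize_cut_test, treatment_summary, _INDEX_COLUMNS
from .landcover import (
    apply_crosswalk,
    change_matrix,
    composition,
    esa_summary,
    read_crosswalk_csv,
    read_esa_csv,
    read_landcover_csv,
)
from .schedule import read_cut_tests, read_schedules

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_inputs"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: Path
    schedules_csv: Optional[Path] = None
    dishes_csv: Optional[Path] = None
    cut_test_csv: Optional[Path] = None
    climate_csv: Optional[Path] = None
    landcover_csv: Optional[Path] = None
    crosswalk_csv: Optional[Path] = None
    esa_csv: Optional[Path] = None
    alpha: float = 0.05
    design: str = "unrelated"
    windows: Sequence[tuple[int, int]] = field(default_factory=lambda: list(DEFAULT_WINDOWS))
    compare_indices: Sequence[str] = field(default_factory=lambda: list(_INDEX_COLUMNS))
    seed: int = 0
    allow_cumulative: bool = False

    def input_paths(self) -> dict[str, Path]:
        names = (
            "schedules_csv", "dishes_csv", "cut_test_csv",
            "climate_csv", "landcover_csv", "crosswalk_csv", "esa_csv",
        )
        return {n: Path(p) for n in names if (p := getattr(self, n)) is not None}


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Dry-run validation of every configured input; returns failure records."""
    failures: list[dict] = []

    def check(name: str, fn) -> None:
        try:
            fn()
        except Exception as exc:  # report, don't raise
            failures.append({"input": name, "error": str(exc)})

    paths = config.input_paths()
    for name, p in paths.items():
        if not p.exists():
            failures.append({"input": name, "error": f"file not found: {p}"})
    if failures:
        return failures
    if config.schedules_csv and config.dishes_csv:
        check("schedules_csv", lambda: read_schedules(
            config.schedules_csv, config.dishes_csv, config.allow_cumulative))
    if config.cut_test_csv:
        check("cut_test_csv", lambda: read_cut_tests(config.cut_test_csv))
    if config.climate_csv:
        check("climate_csv", lambda: read_climate_csv(config.climate_csv))
    if config.landcover_csv:
        check("landcover_csv", lambda: read_landcover_csv(config.landcover_csv))
    if config.esa_csv:
        check("esa_csv", lambda: read_esa_csv(config.esa_csv))
    return failures


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns (and writes) the manifest."""
    failures = validate_inputs(config)
    if failures:
        msgs = "; ".join(f"{f['input']}: {f['error']}" for f in failures)
        raise PipelineError(f"input validation failed — {msgs}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    idx_df = None
    if config.schedules_csv and config.dishes_csv:
        schedules = read_schedules(
            config.schedules_csv, config.dishes_csv, config.allow_cumulative
        )
        idx_df = indices_frame(schedules)
        idx_df.to_csv(out / "indices.csv", index=False, na_rep="NA")
        treatment_summary(idx_df).to_csv(out / "treatment_summary.csv", index=False, na_rep="NA")
        stages["indices"] = {"rows": len(idx_df), "dishes": len(schedules)}

        if idx_df["treatment_id"].nunique() >= 2:
            comp_rows = []
            letter_rows = []
            for index_name in config.compare_indices:
                sub = idx_df[["treatment_id", index_name]].dropna()
                counts = sub.groupby("treatment_id").size()
                if len(counts) < 2 or (counts < 2).any():
                    continue
                samples = GroupedSamples.from_frame(
                    sub, value=index_name, group="treatment_id", design=config.design
                )
                try:
                    res = compare_groups(samples, alpha=config.alpha)
                except ValueError:
                    continue
                comp_rows.append(
                    {
                        "index": index_name,
                        "omnibus_test": res.omnibus_name,
                        "statistic": res.omnibus_statistic,
                        "p_value": res.omnibus_p,
                        "alpha": res.plan.alpha,
                        "k_comparisons": res.plan.k_comparisons,
                        "alpha_adjusted": res.plan.alpha_adjusted,
                    }
                )
                for grp, let in res.letters.items():
                    letter_rows.append({"index": index_name, "treatment_id": grp, "letters": let})
                res.pairwise.assign(index=index_name).to_csv(
                    out / f"pairwise_{index_name}.csv", index=False
                )
            pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
            pd.DataFrame(letter_rows).to_csv(out / "letters.csv", index=False)
            stages["compare"] = {"rows": len(comp_rows)}

    if config.cut_test_csv:
        cuts = [summarize_cut_test(c) for c in read_cut_tests(config.cut_test_csv)]
        pd.DataFrame(cuts).to_csv(out / "cut_test_summary.csv", index=False)
        stages["cut_test"] = {"rows": len(cuts)}

    if config.climate_csv:
        series = read_climate_csv(config.climate_csv)
        trends = summarize_windows(series, config.windows)
        trends.to_csv(out / "climate_windows.csv", index=False, na_rep="NA")
        stages["climate"] = {"rows": len(trends)}

    if config.landcover_csv:
        lc = read_landcover_csv(config.landcover_csv)
        if config.crosswalk_csv:
            lc = apply_crosswalk(lc, read_crosswalk_csv(config.crosswalk_csv))
        comp_frames = []
        for year in sorted(lc["year"].unique()):
            c = composition(lc, year)
            c.insert(0, "year", year)
            comp_frames.append(c)
        pd.concat(comp_frames).to_csv(out / "landcover_composition.csv", index=False, na_rep="NA")
        years = sorted(lc["year"].unique())
        change_frames = []
        for a, b in zip(years, years[1:]):
            ch = change_matrix(lc, a, b)
            ch.insert(0, "period", f"{a}-{b}")
            change_frames.append(ch)
        if change_frames:
            pd.concat(change_frames).to_csv(out / "landcover_change.csv", index=False, na_rep="NA")
        stages["landcover"] = {"years": [int(y) for y in years]}

    if config.esa_csv:
        esa = read_esa_csv(config.esa_csv)
        summary = esa_summary(esa)
        summary["per_class_deltas"] = {
            f"{a}-{b}": d for (a, b), d in summary["per_class_deltas"].items()
        }
        (out / "esa_summary.json").write_text(json.dumps(summary, indent=2))
        stages["esa"] = {"years": summary["years"]}

    manifest = {
        "package": "seedscape",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "alpha": config.alpha,
        "design": config.design,
        "windows": [list(w) for w in config.windows],
        "inputs": {k: str(v) for k, v in config.input_paths().items()},
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
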