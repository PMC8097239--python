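"""Pipeline orchestration: simulate → tabulate → fit → panel, with manifests.

Every run writes its outputs as tidy CSV plus a JSON manifest recording
the configuration snapshot, seeds, input/output checksums, stage timings
and package version.  Checksums of deterministic stages reproduce under
the same manifest; timings and timestamps are excluded from the
reproducibility comparison (`RunManifest.matches`).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import EmptyInputError, OpenIntervalError
from .models import compare_models
from .panel import fertility_vs_interval, panel_correlations, repeat_survey_trends
from .survey_io import load_country_panel, read_survey_csv
from .tabulate import (
    age_parity_table,
    composition_by_interval,
    mean_open_interval,
    tabulate_distribution,
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    stages: list[str]
    config: dict
    seeds: dict
    inputs: dict = field(default_factory=dict)     # path -> sha256
    outputs: dict = field(default_factory=dict)    # path -> sha256
    timings_s: dict = field(default_factory=dict)
    package_version: str = __version__

    def add_input(self, path: Path) -> None:
        self.inputs[Path(path).name] = _sha256(path)

    def add_output(self, path: Path) -> None:
        self.outputs[Path(path).name] = _sha256(path)

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    def matches(self, other: "RunManifest") -> bool:
        """Reproducibility comparison: everything except wall-clock timings."""
        a, b = asdict(self), asdict(other)
        a.pop("timings_s"), b.pop("timings_s")
        return a == b


class _StageTimer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.timings_s[self.stage] = round(time.perf_counter() - self.t0, 3)
        if exc is not None and isinstance(exc, OpenIntervalError):
            raise OpenIntervalError(f"stage {self.stage!r} failed: {exc}") from exc
        return False


def run_survey_analysis(survey_csv: str | Path, out_dir: str | Path,
                        label: str = "survey", seed: int | None = None,
                        ) -> tuple[dict, RunManifest]:
    """Tabulate, decompose and fit one survey; write all stage outputs.

    Returns ``(results, manifest)`` where results holds the in-memory
    distribution, compositions, age–parity table and model comparison.
    """
    survey_csv, out_dir = Path(survey_csv), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        stages=["read", "tabulate", "compose", "age_parity", "fit"],
        config={"survey_csv": str(survey_csv), "label": label},
        seeds={"seed": seed},
    )
    manifest.add_input(survey_csv)
    results: dict = {}

    with _StageTimer(manifest, "read"):
        records, rejections = read_survey_csv(survey_csv)
        if len(rejections):
            rej_path = out_dir / "rejections.csv"
            rejections.to_csv(rej_path, index=False)
            manifest.add_output(rej_path)

    with _StageTimer(manifest, "tabulate"):
        dist = tabulate_distribution(records, label)
        path = out_dir / "distribution.csv"
        dist.to_frame().to_csv(path, index=False)
        manifest.add_output(path)
        results["distribution"] = dist
        results["mean_interval"] = mean_open_interval(records)

    with _StageTimer(manifest, "compose"):
        for axis in ("age", "parity"):
            comp = composition_by_interval(records, axis)
            path = out_dir / f"composition_{axis}.csv"
            tidy = (
                comp.shares.reset_index()
                .melt(id_vars="category", var_name="interval_year",
                      value_name="share_pct")
            )
            tidy.to_csv(path, index=False)
            manifest.add_output(path)
            results[f"composition_{axis}"] = comp

    with _StageTimer(manifest, "age_parity"):
        apt = age_parity_table(records)
        path = out_dir / "age_parity.csv"
        out = apt.table.copy()
        out["mean_parity"] = apt.row_means
        out["n"] = apt.row_counts
        out.to_csv(path, index_label="age_group")
        manifest.add_output(path)
        results["age_parity"] = apt

    with _StageTimer(manifest, "fit"):
        comparison = compare_models(dist)
        path = out_dir / "fits.csv"
        comparison.to_frame().to_csv(path, index=False)
        manifest.add_output(path)
        results["fits"] = comparison

    manifest.write(out_dir / "manifest.json")
    return results, manifest


def run_panel_analysis(surveys: pd.DataFrame | None, out_dir: str | Path,
                       use_fixture: bool = False, seed: int | None = None,
                       ) -> tuple[dict, RunManifest]:
    """Cross-survey correlations and trends.

    With ``use_fixture=True`` the packaged 75-country panel is analysed;
    otherwise ``surveys`` must carry one row per survey with columns
    ``survey_label, country, mid_year, a, b, tfr, gfr`` and optionally
    ``mean_interval, first_interval_pct, ceb``.  Correlations need at
    least 3 surveys; with 2 they are skipped (noted) and trends still run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        stages=["load", "correlate", "trends"],
        config={"use_fixture": use_fixture},
        seeds={"seed": seed},
    )
    results: dict = {}

    with _StageTimer(manifest, "load"):
        panel = load_country_panel() if use_fixture else surveys
        if panel is None or panel.empty:
            raise EmptyInputError("no surveys to analyse")

    with _StageTimer(manifest, "correlate"):
        if len(panel) >= 3:
            assoc = panel_correlations(panel)
            if "mean_interval" in panel.columns:
                fert = fertility_vs_interval(panel)
                assoc.pairs.extend(fert.pairs)
                assoc.notes.extend(fert.notes)
            path = out_dir / "correlations.csv"
            assoc.to_frame().to_csv(path, index=False)
            manifest.add_output(path)
            results["correlations"] = assoc
        else:
            results["correlations"] = None
            manifest.config["note"] = "correlations skipped: fewer than 3 surveys"

    with _StageTimer(manifest, "trends"):
        needed = {"country", "mid_year", "first_interval_pct", "tfr", "mean_interval"}
        if needed.issubset(panel.columns):
            trends, summary, notes = repeat_survey_trends(panel)
            path = out_dir / "trends.csv"
            pd.DataFrame([asdict(t) for t in trends]).to_csv(path, index=False)
            manifest.add_output(path)
            results["trends"], results["trend_summary"] = trends, summary
        else:
            results["trends"] = None

    manifest.write(out_dir / "manifest.json")
    return results, manifest
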