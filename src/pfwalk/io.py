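"""Dataset readers/writers, run outputs, and empirical-CDF comparison.

Run outputs (one directory per run): ``anm_samples.csv`` with one row per
simulated subject, ``summary.json`` with quantiles / proportions / a 1-year
ANM histogram, ``quantile_trajectories.csv`` with the expected decay curves
for the retained supply quantiles, ``decay_curve.csv`` for curve-only runs,
and ``manifest.json`` echoing the config, seed and file inventory so a run
can be reproduced exactly on the same version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .population import (
    PopulationResult,
    simulate_population,
    schedule_survival,
)
from .first_passage import survival

__all__ = [
    "ECDFTable",
    "compare_ecdf",
    "run_population_command",
    "curve_command",
    "write_manifest",
]

_HIST_RANGE = (20.0, 80.0)  # 1-year, left-closed ANM histogram bins


@dataclass
class ECDFTable:
    """Empirical ANM CDF: (age_years, cumulative_proportion) rows, ascending
    ages, proportions non-decreasing within [0, 1]."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = {"age_years", "cumulative_proportion"}
        if not cols.issubset(self.data.columns):
            raise ValueError(f"ECDF table needs columns {sorted(cols)}")
        ages = self.data["age_years"].to_numpy(dtype=float)
        props = self.data["cumulative_proportion"].to_numpy(dtype=float)
        if len(ages) == 0:
            raise ValueError("ECDF table is empty")
        if np.any(np.diff(ages) < 0):
            raise ValueError("ages must be ascending")
        if np.any(np.diff(props) < -1e-12):
            raise ValueError("cumulative proportions must be non-decreasing")
        if props.min() < 0 or props.max() > 1 + 1e-12:
            raise ValueError("cumulative proportions must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path) -> "ECDFTable":
        return cls(pd.read_csv(path))

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_years"].to_numpy(dtype=float)

    @property
    def proportions(self) -> np.ndarray:
        return self.data["cumulative_proportion"].to_numpy(dtype=float)


def compare_ecdf(anm_samples, table: ECDFTable) -> tuple[float, float]:
    """Sup over the table's ages of |model ECDF - empirical proportion|,
    returned with the age at which the supremum is attained.

    Censored (non-finite) samples count as events beyond every tabulated age.
    """
    anm = np.asarray(anm_samples, dtype=float)
    if anm.size == 0:
        raise ValueError("need at least one ANM sample")
    finite = np.sort(anm[np.isfinite(anm)])
    model = np.searchsorted(finite, table.ages, side="right") / anm.size
    diff = np.abs(model - table.proportions)
    i = int(np.argmax(diff))
    return float(diff[i]), float(table.ages[i])


def _anm_frame(result: PopulationResult) -> pd.DataFrame:
    anm = result.anm_samples
    return pd.DataFrame(
        {
            "subject_id": np.arange(anm.size),
            "anm_years": np.round(anm, 6),
            "censored": (~np.isfinite(anm)).astype(int),
        }
    )


def _histogram(result: PopulationResult) -> dict:
    finite = result.anm_samples[np.isfinite(result.anm_samples)]
    edges = np.arange(_HIST_RANGE[0], _HIST_RANGE[1] + 1.0)
    counts, _ = np.histogram(finite, bins=edges)
    return {
        "bin_left_edges": edges[:-1].tolist(),
        "bin_width_years": 1.0,
        "counts": counts.tolist(),
        "n_below_range": int(np.sum(finite < _HIST_RANGE[0])),
        "n_above_range": int(np.sum(finite >= _HIST_RANGE[1])),
    }


def write_manifest(out_dir: Path, config: RunConfig, files: list[str]) -> Path:
    manifest = {
        "software": "pfwalk",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "outputs": sorted(files),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def run_population_command(config: RunConfig) -> dict:
    """Run a population simulation from a config and write all outputs.

    Returns a dict mapping output names to paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = simulate_population(
        n_subjects=config.n_subjects,
        dist=config.supply_distribution(),
        base_schedule=config.drift_schedule(),
        c=config.c,
        interventions=config.intervention_events(),
        params=config.continuous_params(),
        threshold=config.threshold,
        method=config.method,
        seed=config.seed,
        max_age=config.max_age,
    )

    files: dict = {}
    samples_path = out_dir / "anm_samples.csv"
    _anm_frame(result).to_csv(samples_path, index=False)
    files["anm_samples"] = samples_path

    summary = result.summary()
    summary["histogram"] = _histogram(result)
    summary["n_negative_drift"] = result.n_negative_drift
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    files["summary"] = summary_path

    if result.quantile_trajectories is not None:
        qt = result.quantile_trajectories
        frame = pd.DataFrame({"age_years": qt["ages"]})
        for name in ("q01", "q05", "q25", "q50", "q75", "q95", "q99"):
            frame[name] = qt["expected"][name]
        qt_path = out_dir / "quantile_trajectories.csv"
        frame.to_csv(qt_path, index=False)
        files["quantile_trajectories"] = qt_path

    files["manifest"] = write_manifest(
        out_dir, config, [p.name for p in files.values()]
    )
    return files


def curve_command(config: RunConfig, age_max: float = 100.0) -> Path:
    """Write the expected decay curve (monthly, 0..age_max years) to
    ``decay_curve.csv`` in the run's output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ages = np.arange(int(round(age_max * 12)) + 1) / 12.0
    schedule = config.drift_schedule()
    params = config.continuous_params()
    N = config.supply_distribution().median()
    if schedule.is_constant:
        s = survival(ages, params.with_drift(schedule.values[0]))
    else:
        s_full = schedule_survival(params, schedule, 1.0, max_age=age_max)
        s = s_full[:: 4]  # internal 1/48-yr grid -> monthly
    frame = pd.DataFrame(
        {"age_years": ages, "expected_count": N * np.asarray(s)[: ages.size]}
    )
    path = out_dir / "decay_curve.csv"
    frame.to_csv(path, index=False)
    write_manifest(out_dir, config, [path.name])
    return path
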