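"""End-to-end pipeline orchestration and actogram-matrix export.

The pipeline takes one or more recordings (simulated, epoch-count files, or
raw accelerometer files), screens them, fits the extended cosine model,
computes the nonparametric metrics, and — when a participant covariate table
is supplied — runs the residualized association scan. Every intermediate
artifact is written to disk so stages are independently rerunnable, and a
manifest records parameters, seed, and per-stage row counts. No stage ever
imputes: the number of observed epochs can only shrink between stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import association_scan
from .cosinor import fit_extended_cosine
from .nonparametric import DEFAULT_IV_TAUS, compute_nonparametric_metrics
from .screening import (
    DEFAULT_MIN_RUN_MINUTES,
    DEFAULT_SLEEP_WINDOW_HOURS,
    detect_nonwear,
    estimate_main_sleep_period,
    screen_recording,
)
from .series import EpochCountSeries, read_counts_csv, write_counts_csv
from .simulate import SimulationConfig, simulate_epoch_series

__all__ = ["PipelineConfig", "run_pipeline", "export_actogram_matrix", "write_actogram_csv"]

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"participants", "screening", "cosinor", "metrics", "association", "seed", "out_dir"},
    "participants": {"counts_files", "simulate"},
    "participants.simulate": {"n", "overrides", "per_participant"},
    "screening": {"min_nonwear_run_minutes", "sleep_window_hours", "count_threshold"},
    "cosinor": {"seed", "n_restarts"},
    "metrics": {"taus_minutes"},
    "association": {"table", "confounders", "outcomes", "extra_predictors", "iv_family"},
}


class PipelineConfig(dict):
    """Validated pipeline configuration (plain nested dict + schema check)."""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(cfg)

    def __init__(self, cfg: dict):
        _validate_keys(cfg, "")
        super().__init__(cfg)


def _validate_keys(node, prefix: str) -> None:
    allowed = _SCHEMA.get(prefix)
    if allowed is None or not isinstance(node, dict):
        return
    for key in node:
        if key not in allowed:
            dotted = f"{prefix}.{key}".lstrip(".")
            raise ValueError(f"unknown pipeline config key: {dotted!r}")
        child = f"{prefix}.{key}".lstrip(".")
        if child in _SCHEMA:
            _validate_keys(node[key], child)


def _param_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_participants(cfg: PipelineConfig, seed: int) -> dict[str, EpochCountSeries]:
    part = cfg.get("participants", {})
    out: dict[str, EpochCountSeries] = {}
    if "counts_files" in part:
        for path in part["counts_files"]:
            out[Path(path).stem] = read_counts_csv(path)
    if "simulate" in part:
        sim = part["simulate"]
        n = int(sim.get("n", 1))
        overrides = dict(sim.get("overrides", {}))
        per = sim.get("per_participant", {})
        for i in range(n):
            kwargs = dict(overrides)
            for key, values in per.items():
                kwargs[key] = values[i]
            kwargs.setdefault("seed", seed + i)
            if "nonwear_gaps" in kwargs:
                kwargs["nonwear_gaps"] = [tuple(g) for g in kwargs["nonwear_gaps"]]
            series, _ = simulate_epoch_series(SimulationConfig(**kwargs))
            out[f"sim{i:03d}"] = series
    if not out:
        raise ValueError("pipeline config defines no participants")
    return out


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    scr = cfg.get("screening", {})
    stages: list[dict] = []

    participants = _load_participants(cfg, seed)
    stages.append({"stage": "load", "n_participants": len(participants)})

    metric_rows = []
    excluded = []
    for pid, series in sorted(participants.items()):
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        write_counts_csv(series, pdir / "counts.csv")
        mask = detect_nonwear(
            series,
            min_run_minutes=scr.get("min_nonwear_run_minutes", DEFAULT_MIN_RUN_MINUTES),
            count_threshold=scr.get("count_threshold"),
        )
        sleep_window = estimate_main_sleep_period(
            series, window_hours=scr.get("sleep_window_hours", DEFAULT_SLEEP_WINDOW_HOURS), mask=mask
        )
        result = screen_recording(series, mask, sleep_window)
        result.report.to_json(pdir / "screening.json")
        write_counts_csv(result.censored, pdir / "censored.csv")
        n_obs_before = int(result.censored.observed.sum())
        if not result.report.adequate:
            logger.info(
                "excluding %s: longest valid run %d days < 3",
                pid,
                result.report.longest_consecutive_valid_run,
            )
            excluded.append(
                {"participant": pid, "reason": "fewer than 3 consecutive valid days"}
            )
            continue
        fit = fit_extended_cosine(result.censored, seed=cfg.get("cosinor", {}).get("seed", seed))
        with open(pdir / "cosinor.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        taus = cfg.get("metrics", {}).get("taus_minutes", list(DEFAULT_IV_TAUS))
        metrics = compute_nonparametric_metrics(result.censored, taus_minutes=taus)
        assert int(result.censored.observed.sum()) == n_obs_before  # no imputation
        with open(pdir / "metrics.json", "w") as fh:
            json.dump(metrics.to_dict(), fh, indent=2)
        row = {
            "participant_id": pid,
            "pseudo_f": fit.pseudo_F,
            "up_mesor": fit.up_mesor_h,
            "down_mesor": fit.down_mesor_h,
            "acrophase": fit.acrophase_h,
            "interdaily_stability": metrics.IS,
            "relative_amplitude": metrics.RA,
            "recording_length": result.report.worn_days_real,
        }
        for tau, val in metrics.IV_by_tau.items():
            row[f"iv_{tau}"] = val
        metric_rows.append(row)

    cohort = pd.DataFrame(metric_rows)
    cohort.to_csv(out / "rhythm_metrics.csv", index=False)
    stages.append(
        {"stage": "metrics", "n_included": len(metric_rows), "n_excluded": len(excluded)}
    )

    assoc_cfg = cfg.get("association")
    if assoc_cfg:
        table = pd.read_csv(assoc_cfg["table"])
        merged = table.merge(cohort, on="participant_id", how="inner")
        iv_cols = [c for c in merged.columns if c.startswith("iv_")]
        predictors = (
            ["pseudo_f", "interdaily_stability", "relative_amplitude", "up_mesor", "down_mesor"]
            + list(assoc_cfg.get("extra_predictors", []))
            + iv_cols
        )
        results = association_scan(
            merged,
            confounders=list(assoc_cfg["confounders"]),
            outcomes=list(assoc_cfg["outcomes"]),
            predictors=[p for p in predictors if p in merged.columns],
            bh_families={"iv": iv_cols} if iv_cols else None,
        )
        results.to_csv(out / "association_results.csv", index=False)
        stages.append({"stage": "association", "n_rows": len(results)})

    manifest = {
        "version": __version__,
        "seed": seed,
        "param_hash": _param_hash(dict(cfg)),
        "stages": stages,
        "excluded": excluded,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def export_actogram_matrix(series: EpochCountSeries, double_plot: bool = False) -> np.ndarray:
    """Days-by-clock-bins raster of counts (NaN marks missing / uncovered).

    With ``double_plot`` each row spans 48 h: row r repeats day r followed by
    day r+1, the conventional double-plotted actogram layout.
    """
    if series.n_epochs == 0:
        raise ValueError("empty series")
    H = series.epochs_per_day
    day_keys = series.day_keys()
    days = pd.DatetimeIndex(sorted(set(day_keys)))
    mat = np.full((len(days), H), np.nan)
    bins = series.tod_bins()
    for r, day in enumerate(days):
        sel = np.asarray(day_keys == day)
        mat[r, bins[sel]] = series.counts[sel]
    if not double_plot:
        return mat
    nxt = np.vstack([mat[1:], np.full((1, H), np.nan)])
    return np.hstack([mat, nxt])


def write_actogram_csv(matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix).to_csv(path, index=False, header=False, na_rep="nan")
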