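"""Readers, writers and run configuration.

CSV is the canonical interchange format (calibrated FCS exports are assumed
to have been converted to CSV upstream): control files carry a single
``fluorescence`` column; time courses are long-format with ``time_h`` and
``fluorescence`` columns.  All values round-trip at full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .flow import ControlFixtureSpec, TimeCourseDataset
from .inference import Posterior, PredictionBand, UniformPriorBox
from .model import ExperimentConstants, MediaTrajectory, PARAM_NAMES, TrajectorySet
from . import presets

_FULL = "%.17g"


def _read_numeric_csv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = vals
    return df


def read_fluorescence_csv(path):
    """Read a control file (-> ndarray) or a time course (-> TimeCourseDataset)."""
    header = pd.read_csv(path, nrows=0).columns
    if "time_h" in header:
        df = _read_numeric_csv(path, ["time_h", "fluorescence"])
        samples = {
            float(t): g["fluorescence"].to_numpy() for t, g in df.groupby("time_h", sort=True)
        }
        return TimeCourseDataset(samples)
    df = _read_numeric_csv(path, ["fluorescence"])
    return df["fluorescence"].to_numpy()


def write_control_csv(values, path) -> None:
    pd.DataFrame({"fluorescence": np.asarray(values, dtype=float)}).to_csv(
        path, index=False, float_format=_FULL
    )


def write_timecourse_csv(ds: TimeCourseDataset, path) -> None:
    frames = [
        pd.DataFrame({"time_h": t, "fluorescence": ds.samples[t]}) for t in ds.times
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FULL)


def write_trajectories_csv(traj: TrajectorySet, path) -> None:
    """Tidy per-cell trajectory export: cell_id, time_h, P."""
    n, T = traj.P.shape
    pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n), T),
            "time_h": np.tile(traj.times, n),
            "P": traj.P.ravel(),
        }
    ).to_csv(path, index=False, float_format=_FULL)


def write_media_csv(media: MediaTrajectory, path) -> None:
    pd.DataFrame(
        {"time_h": media.times, "ubar": media.ubar, "cumint": media.cumint}
    ).to_csv(path, index=False, float_format=_FULL)


def write_posterior_csv(post: Posterior, path) -> None:
    df = pd.DataFrame(post.thetas, columns=list(PARAM_NAMES))
    df["weight"] = post.weights
    df["distance"] = post.distances
    df.to_csv(path, index=False, float_format=_FULL)


def read_posterior_csv(path) -> Posterior:
    df = _read_numeric_csv(path, list(PARAM_NAMES) + ["weight", "distance"])
    return Posterior(
        df[list(PARAM_NAMES)].to_numpy(),
        df["weight"].to_numpy(),
        df["distance"].to_numpy(),
        threshold_history=[],
    )


def write_band_csv(band: PredictionBand, path) -> None:
    pd.DataFrame(
        {
            "grid": band.grid,
            "lower": band.lower,
            "median": band.median,
            "upper": band.upper,
        }
    ).to_csv(path, index=False, float_format=_FULL)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """Fully resolved default run configuration as a plain dict."""
    c = presets.DEFAULT_CONSTANTS
    f = presets.DEFAULT_CONTROL_SPEC
    return {
        "constants": {"C": c.C, "S": c.S, "V": c.V, "u0": c.u0},
        "prior": {k: list(v) for k, v in presets.DEFAULT_PRIOR_BOUNDS.items()},
        "abc": {
            "n_particles": 1000,
            "n_cells": None,
            "target_threshold": None,
            "target_noise_multiple": 1.25,
            "n_prior_predictive": 500,
            "max_generations": 25,
            "distance": "ad",
        },
        "design": {
            "candidates": list(presets.DESIGN_CANDIDATES),
            "k": 6,
            "n_pre": 2000,
            "j_reps": 5,
            "cv": 0.1,
            "n_accept": 200,
            "n_cells": 1000,
        },
        "fixture": asdict(f),
        "seed": 0,
    }


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, new: dict) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def constants_from_config(cfg: dict) -> ExperimentConstants:
    return ExperimentConstants(**cfg["constants"])


def prior_from_config(cfg: dict) -> UniformPriorBox:
    return UniformPriorBox(**{k: tuple(v) for k, v in cfg["prior"].items()})


def fixture_spec_from_config(cfg: dict) -> ControlFixtureSpec:
    return ControlFixtureSpec(**cfg["fixture"])


def write_run_metadata(outdir, cfg: dict, extra: dict | None = None) -> Path:
    """Write the resolved config, its hash and the seed next to run outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.get("seed"),
    }
    if extra:
        payload.update(extra)
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
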