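"""Configuration-driven pipeline runner.

A YAML/dict config names a sequence of steps (``simulate``, ``coloc3dt``,
``fixed-coloc``, ``profile``, ``kinetics``); the runner validates the
schema, executes the steps, writes outputs atomically, and records a run
manifest (parameter values, package version, input checksums) so any run
can be reproduced. Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import aggregate_traces, analyze_movie
from .containers import Movie
from .errors import ConfigError
from .fixedcell import IntensityProfile, Roi2D, coloc_percent_fixed, profile_overlap_percent
from .io import read_movie, sha256_of, write_movie
from .kinetics import mean_trace, normalize_to_nebd
from .segment import ColocParams
from .simulate import SyntheticParams, generate_movie, write_ground_truth

__all__ = ["run_pipeline", "load_config"]

_TASKS: dict[str, Callable] = {}


def _task(name: str):
    def deco(fn):
        _TASKS[name] = fn
        return fn
    return deco


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _require(step: dict, field: str, step_idx: int) -> Any:
    if field not in step:
        raise ConfigError(f"steps[{step_idx}]: missing required field '{field}'")
    return step[field]


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _build_params(cls, mapping: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigError(f"{where}: unknown parameter(s) {sorted(unknown)}")
    fixed = dict(mapping)
    if "shape" in fixed and fixed["shape"] is not None:
        fixed["shape"] = tuple(fixed["shape"])
    return cls(**fixed)


@_task("simulate")
def _run_simulate(step: dict, i: int, out_dir: Path, seed: int | None, manifest: dict) -> None:
    params_map = dict(step.get("params", {}))
    if seed is not None and "seed" not in params_map:
        params_map["seed"] = seed
    params = _build_params(SyntheticParams, params_map, f"steps[{i}].params")
    movie, truth = generate_movie(params)
    out = out_dir / _require(step, "out", i)
    write_movie(movie, out)
    write_ground_truth(truth, out.with_suffix("").with_suffix(".truth.json"))
    manifest["outputs"].append(str(out))


@_task("coloc3dt")
def _run_coloc3dt(step: dict, i: int, out_dir: Path, seed: int | None, manifest: dict) -> None:
    movie_path = out_dir / _require(step, "movie", i)
    marker = _require(step, "marker", i)
    signal = _require(step, "signal", i)
    nebd = step.get("nebd_frame")
    params = _build_params(ColocParams, dict(step.get("params", {})), f"steps[{i}].params")
    manifest["inputs"][str(movie_path)] = sha256_of(movie_path)
    movie: Movie = read_movie(movie_path, nebd_frame=nebd)
    trace = analyze_movie(
        movie, marker_channel=marker, signal_channel=signal,
        nebd_frame=nebd, params=params, cell_id=step.get("cell_id", movie_path.stem),
    )
    out = out_dir / _require(step, "out", i)
    _atomic_write_df(trace.to_frame(), out)
    manifest["outputs"].append(str(out))
    if "aggregate_out" in step:
        agg = aggregate_traces([trace])
        agg_out = out_dir / step["aggregate_out"]
        _atomic_write_df(agg.to_frame(), agg_out)
        manifest["outputs"].append(str(agg_out))


@_task("fixed-coloc")
def _run_fixed(step: dict, i: int, out_dir: Path, seed: int | None, manifest: dict) -> None:
    import tifffile

    image_path = out_dir / _require(step, "image", i)
    manifest["inputs"][str(image_path)] = sha256_of(image_path)
    img = np.asarray(tifffile.imread(image_path), dtype=float)
    if img.ndim != 3 or img.shape[0] < 2:
        raise ConfigError(f"steps[{i}]: image must be a (C>=2, Y, X) TIFF; got shape {img.shape}")
    roi = None
    if "roi" in step:
        roi_spec = json.loads((out_dir / step["roi"]).read_text())
        roi = Roi2D(
            origin=tuple(roi_spec["origin"]),
            height=int(roi_spec["height"]),
            width=int(roi_spec["width"]),
            pixel_size=float(roi_spec.get("pixel_size", 1.0)),
        )
    res = coloc_percent_fixed(
        img[0], img[1], roi, denominator=step.get("denominator", "reference")
    )
    out = out_dir / _require(step, "out", i)
    _atomic_write_df(pd.DataFrame([dataclasses.asdict(res)]), out)
    manifest["outputs"].append(str(out))


@_task("profile")
def _run_profile(step: dict, i: int, out_dir: Path, seed: int | None, manifest: dict) -> None:
    csv_path = out_dir / _require(step, "csv", i)
    manifest["inputs"][str(csv_path)] = sha256_of(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("position_um", "intensity_a", "intensity_b"):
        if col not in df.columns:
            raise ConfigError(f"steps[{i}]: profile CSV missing column '{col}'")
    subtract = bool(step.get("subtract_baseline", True))
    a = IntensityProfile.from_raw(df["position_um"], df["intensity_a"], subtract)
    b = IntensityProfile.from_raw(df["position_um"], df["intensity_b"], subtract)
    pct = profile_overlap_percent(a, b)
    out = out_dir / _require(step, "out", i)
    _atomic_write_df(
        pd.DataFrame(
            [{"overlap_percent": pct, "roi_length_um": a.roi_length,
              "baseline_a": a.baseline, "baseline_b": b.baseline}]
        ),
        out,
    )
    manifest["outputs"].append(str(out))


@_task("kinetics")
def _run_kinetics(step: dict, i: int, out_dir: Path, seed: int | None, manifest: dict) -> None:
    csv_path = out_dir / _require(step, "traces", i)
    manifest["inputs"][str(csv_path)] = sha256_of(csv_path)
    df = pd.read_csv(csv_path)
    nebd_col = step.get("nebd_col", "nebd_frame")
    for col in ("cell_id", "frame", "raw", nebd_col):
        if col not in df.columns:
            raise ConfigError(f"steps[{i}]: traces CSV missing column '{col}'")
    interval = float(step.get("frame_interval", 1.0))
    traces = []
    for cell, sub in df.sort_values("frame").groupby("cell_id"):
        traces.append(
            normalize_to_nebd(
                sub["raw"].to_numpy(), int(sub[nebd_col].iloc[0]), interval, cell_id=str(cell)
            )
        )
    out = out_dir / _require(step, "out", i)
    _atomic_write_df(mean_trace(traces), out)
    manifest["outputs"].append(str(out))


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Validate and execute a pipeline configuration.

    ``config`` is a dict or a path to a YAML file with optional ``seed``
    and ``out_dir`` keys and a required ``steps`` list; each step carries
    a ``task`` name plus task-specific fields. Returns the run manifest
    (also written to ``<out_dir>/manifest.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    steps = config.get("steps")
    if not isinstance(steps, list) or not steps:
        raise ConfigError("config: 'steps' must be a non-empty list")
    seed = config.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise ConfigError("config: 'seed' must be an integer")
    out_path = Path(out_dir if out_dir is not None else config.get("out_dir", "."))
    out_path.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {},
        "outputs": [],
    }
    for i, step in enumerate(steps):
        if not isinstance(step, dict):
            raise ConfigError(f"steps[{i}]: each step must be a mapping")
        task = _require(step, "task", i)
        if task not in _TASKS:
            raise ConfigError(
                f"steps[{i}].task: unknown task {task!r}; expected one of {sorted(_TASKS)}"
            )
        _TASKS[task](step, i, out_path, seed, manifest)

    (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
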