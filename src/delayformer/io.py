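"""Dataset and configuration I/O.

Two on-disk series formats are supported:

* the de-facto forecasting-benchmark CSV dialect — a leading ``date``
  timestamp column followed by one numeric column per channel — so public
  benchmark files drop in unmodified;
* a binary archive (``.npz`` matrix + JSON sidecar with channel names,
  sampling interval and provenance) for simulator output, avoiding the need
  to fabricate calendar timestamps for synthetic data.

Missing values are a hard error in both directions: the forecaster assumes
complete, regularly sampled observations and performs no imputation.

:func:`load_config` reads a YAML/JSON run configuration with strict unknown-
key rejection and eager geometry cross-checks (W >= L, patch divisibility).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .embedding import PatchSpec
from .series import MultivariateSeries

__all__ = [
    "DatasetSpec",
    "RunConfig",
    "read_tsf_csv",
    "write_tsf_csv",
    "save_archive",
    "load_archive",
    "load_config",
]


@dataclass
class DatasetSpec:
    """Where a dataset lives and how to slice it."""

    path: str
    dialect: str = "tsf_csv"  # or "archive"
    channels: Sequence[str] | None = None
    n_train: int | None = None
    n_val: int | None = None
    n_test: int | None = None

    def __post_init__(self) -> None:
        if self.dialect not in ("tsf_csv", "archive"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    def load(self) -> MultivariateSeries:
        if self.dialect == "tsf_csv":
            return read_tsf_csv(self.path, channels=self.channels)
        series = load_archive(self.path)
        if self.channels:
            series = series.select_channels(list(self.channels))
        return series


def read_tsf_csv(
    path: str | Path, channels: Sequence[str] | None = None
) -> MultivariateSeries:
    """Read the benchmark CSV dialect (leading ``date`` column, numeric channels)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a date column plus at least one channel")
    if df.columns[0].strip().lower() != "date":
        raise ValueError(f"{path}: first column must be named 'date', got {df.columns[0]!r}")
    data = df.iloc[:, 1:]
    bad = data.columns[~data.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        # distinguish missing from non-numeric for the error message
        cells = []
        for col in bad:
            nul = pd.to_numeric(data[col], errors="coerce").isna()
            rows = list(np.flatnonzero(nul.to_numpy())[:5])
            cells.append(f"{col}: rows {rows}")
        raise ValueError(f"{path}: missing or non-numeric values in {'; '.join(cells)}")
    values = data.to_numpy(dtype=np.float64)
    series = MultivariateSeries(
        values,
        channel_names=[str(c) for c in data.columns],
        provenance=f"read_tsf_csv({path})",
    )
    if channels:
        series = series.select_channels(list(channels))
    return series


def write_tsf_csv(series: MultivariateSeries, path: str | Path) -> None:
    """Write the benchmark CSV dialect with synthetic integer-hour timestamps."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stamps = pd.date_range("2000-01-01", periods=series.n_samples, freq="h")
    df = pd.DataFrame(series.values, columns=series.channel_names)
    df.insert(0, "date", stamps)
    df.to_csv(path, index=False)


def save_archive(series: MultivariateSeries, path: str | Path) -> None:
    """Binary matrix (.npz) + JSON sidecar (channel names, dt, provenance)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), values=series.values)
    sidecar = {
        "channel_names": series.channel_names,
        "dt_sample": series.dt_sample,
        "provenance": series.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_archive(path: str | Path) -> MultivariateSeries:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        values = data["values"]
    return MultivariateSeries(
        values,
        channel_names=sidecar["channel_names"],
        dt_sample=sidecar.get("dt_sample", 1.0),
        provenance=sidecar.get("provenance", f"load_archive({path})"),
    )


# ----------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Fully resolved configuration of one run (simulate/train/evaluate).

    Sections mirror the library configs; every value has a documented
    default, so an empty file is a valid config.  Unknown keys are rejected
    with their exact path, and the embedding geometry is cross-checked at
    load time.
    """

    seed: int = 0
    out_dir: str = "runs/run"
    lorenz: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


_SECTION_KEYS = {
    "lorenz": {
        "n_subsystems", "sigma0", "rho", "beta", "gamma", "time_varying",
        "sigma_drift_rate", "noise_sigma", "dt", "steps_per_sample",
        "n_samples", "y_equation_variant", "boundary", "seed",
    },
    "model": {
        "W", "H", "N", "L", "p1", "p2", "D", "n_layers", "n_heads",
        "ff_dim", "dropout", "decoder_mode", "norm_style", "dtype",
    },
    "train": {
        "learning_rate", "batch_size", "max_epochs", "early_stop_patience",
        "seed", "normalization", "finetune_fraction", "eval_batch_size",
    },
    "experiment": {
        "W", "H", "L", "p1", "p2", "n_train", "n_val", "n_test",
        "train_stride", "eval_stride", "noise_sigma", "noise_seed",
        "n_channels", "normalization", "D", "n_layers", "n_heads",
        "ff_dim", "dropout", "decoder_mode",
    },
    "evaluation": {"seeds", "sigma_list", "sizes", "dims"},
}


def load_config(path: str | Path) -> RunConfig:
    """Load + validate a YAML/JSON run config, filling documented defaults."""
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known_top = {"seed", "out_dir", *_SECTION_KEYS}
    for key in raw:
        if key not in known_top:
            raise ValueError(f"{path}: unknown key '{key}'")
    for section, allowed in _SECTION_KEYS.items():
        sub = raw.get(section, {})
        if sub is None:
            sub = {}
        if not isinstance(sub, dict):
            raise ValueError(f"{path}: section '{section}' must be a mapping")
        for key in sub:
            if key not in allowed:
                raise ValueError(f"{path}: unknown key '{section}.{key}'")
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "runs/run")),
        lorenz=dict(raw.get("lorenz") or {}),
        model=dict(raw.get("model") or {}),
        train=dict(raw.get("train") or {}),
        experiment=dict(raw.get("experiment") or {}),
        evaluation=dict(raw.get("evaluation") or {}),
    )
    _check_geometry(cfg, path)
    return cfg


def _check_geometry(cfg: RunConfig, path: Path) -> None:
    geo = {**cfg.model, **cfg.experiment}
    W = int(geo.get("W", 96))
    H = int(geo.get("H", 96))
    L = int(geo.get("L", 49))
    p1 = int(geo.get("p1", 6))
    p2 = int(geo.get("p2", 7))
    if not 1 <= L <= W:
        raise ValueError(f"{path}: model.L={L} must satisfy 1 <= L <= W={W}")
    if H < 1:
        raise ValueError(f"{path}: model.H must be >= 1")
    try:
        PatchSpec(p1, p2).validate(L, W - L + 1)
    except ValueError as err:
        raise ValueError(f"{path}: model patch geometry invalid: {err}") from None
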