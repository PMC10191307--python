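"""File formats: epoch tables, R-peak trains, run configuration.

Epoch tables are CSV/TSV with an explicit header (subject_id,
epoch_index, clock_s, activity, hrm, hrsd, stage); stage labels are
stored as scheme strings, missing values as empty fields. R-peak trains
are one timestamp (seconds) per line. Run configuration is YAML with a
strict schema (unknown keys rejected).
"""

from __future__ import annotations

import hashlib
from dataclasses import fields as _dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import EpochSeries, RPeakTrain, upsample_activity
from .stages import Hypnogram, StageScheme, scheme
from .training import TrainConfig

TABLE_COLUMNS = ["subject_id", "epoch_index", "clock_s", "activity",
                 "hrm", "hrsd", "stage"]


def write_epoch_table(series_list: list[EpochSeries] | EpochSeries, path,
                      sep: str = ",") -> None:
    if isinstance(series_list, EpochSeries):
        series_list = [series_list]
    frames = []
    for s in series_list:
        stage = s.stage.to_labels() if s.stage is not None else [""] * len(s)
        frames.append(pd.DataFrame({
            "subject_id": s.subject_id,
            "epoch_index": np.arange(len(s)),
            "clock_s": s.clock,
            "activity": s.activity,
            "hrm": s.hrm,
            "hrsd": s.hrsd,
            "stage": stage,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_epoch_table(path, scheme_: str | StageScheme | None = None,
                     activity_60s: bool = False, sep: str = ",",
                     epoch_s: float = 30.0) -> list[EpochSeries]:
    """Read one or more subject-nights from an epoch table.

    ``activity_60s`` marks tables whose rows are 60-s epochs (coarser
    actigraphy devices); every channel is then upsampled to 30-s
    resolution by adjacent replication, doubling the series length, with
    the clock rebuilt at 30-s steps. Stage labels, when present, are
    validated against ``scheme_``.
    """
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "stage": str},
                     keep_default_na=True)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch table {path} lacks columns {missing}")
    out = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("epoch_index")
        idx = g["epoch_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            bad = int(np.flatnonzero(np.diff(idx) != 1)[0]) + 1 if idx.size > 1 else 0
            raise ValueError(f"subject {sid!r}: epoch_index not contiguous "
                             f"near row {bad}")
        activity = g["activity"].to_numpy(dtype=np.float64)
        hrm = g["hrm"].to_numpy(dtype=np.float64)
        hrsd = g["hrsd"].to_numpy(dtype=np.float64)
        clock = g["clock_s"].to_numpy(dtype=np.float64)
        labels = g["stage"].fillna("").tolist()
        if activity_60s:
            activity = upsample_activity(activity)
            hrm = np.repeat(hrm, 2)
            hrsd = np.repeat(hrsd, 2)
            clock = (clock[0] + epoch_s * np.arange(activity.size)) % 86400.0
            labels = [lab for lab in labels for _ in range(2)]
        stage = None
        if any(lab != "" for lab in labels):
            if scheme_ is None:
                raise ValueError("table has stage labels; a scheme is required")
            stage = Hypnogram.from_labels(labels, scheme(scheme_), epoch_s)
        out.append(EpochSeries(str(sid), activity, hrm, hrsd, clock,
                               stage=stage, epoch_s=epoch_s))
    return out


def write_rpeaks(train: RPeakTrain, path) -> None:
    np.savetxt(path, train.timestamps, fmt="%.6f")


def read_rpeaks(path) -> RPeakTrain:
    return RPeakTrain(np.atleast_1d(np.loadtxt(path)))


def write_hypnogram(hyp: Hypnogram, path) -> None:
    Path(path).write_text("\n".join(hyp.to_labels()) + "\n")


def read_hypnogram(path, scheme_: str | StageScheme,
                   epoch_s: float = 30.0) -> Hypnogram:
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return Hypnogram.from_labels(labels, scheme(scheme_), epoch_s)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_TRAIN_KEYS = {f.name for f in _dc_fields(TrainConfig)}
_EXTRA_KEYS = {"train_table", "val_table", "test_table", "checkpoint", "out_dir"}


def load_run_config(path) -> tuple[TrainConfig, dict]:
    """Parse a YAML run config into (TrainConfig, path/extra options).

    Unknown keys are rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"run config {path} must be a YAML mapping")
    unknown = set(raw) - _TRAIN_KEYS - _EXTRA_KEYS
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    cfg = TrainConfig(**{k: v for k, v in raw.items() if k in _TRAIN_KEYS})
    extra = {k: v for k, v in raw.items() if k in _EXTRA_KEYS}
    return cfg, extra


def config_hash(path) -> str:
    """Short digest of a config file, for run logs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def write_training_log(history: list[dict], path) -> None:
    pd.DataFrame(history).to_csv(path, index=False)
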