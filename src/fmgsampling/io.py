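"""Plain-text serialization of trials, metadata, configs and reports.

One delimited-text file per trial (columns ``time_s, ch1..chM``), a metadata
sidecar table, and YAML/JSON configs.  Values are written with 12 significant
digits so a write/read round trip preserves signals to well under 1e-9.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import ActionSpec, FMGRecording, SyntheticConfig

METADATA_FILE = "metadata.csv"
_FLOAT_FMT = "%.12g"


def trial_filename(rec: FMGRecording) -> str:
    return f"p{rec.participant:02d}_{rec.action}_t{rec.trial}_{rec.placement}.csv"


def write_dataset(recordings: list[FMGRecording], out_dir: str | Path) -> Path:
    """Write one CSV per trial plus the metadata sidecar; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = trial_filename(rec)
        n, m = rec.signal.shape
        frame = pd.DataFrame(
            rec.signal, columns=[f"ch{j + 1}" for j in range(m)]
        )
        frame.insert(0, "time_s", np.arange(n) / rec.fs)
        frame.to_csv(out / fname, index=False, float_format=_FLOAT_FMT)
        rows.append(
            {
                "participant": rec.participant,
                "action": rec.action,
                "action_type": rec.action_type,
                "placement": rec.placement,
                "trial": rec.trial,
                "fs": rec.fs,
                "n_channels": m,
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out / METADATA_FILE, index=False)
    return out


class TrialParseError(ValueError):
    """A trial file violated the expected format (reported with line number)."""


def _read_trial_file(path: Path, fs: float, n_channels: int | None = None) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip()
    cols = header.split(",")
    if not cols or cols[0] != "time_s" or len(cols) < 2:
        raise TrialParseError(f"{path.name}:1: header must be 'time_s,ch1,...', got {header!r}")
    if n_channels is not None and len(cols) - 1 != n_channels:
        raise TrialParseError(
            f"{path.name}:1: {len(cols) - 1} channel columns, "
            f"{n_channels} declared in metadata"
        )
    expected = ["time_s"] + [f"ch{j + 1}" for j in range(len(cols) - 1)]
    if cols != expected:
        raise TrialParseError(
            f"{path.name}:1: channel columns must be ch1..ch{len(cols) - 1} in order"
        )
    try:
        data = pd.read_csv(path)
    except Exception as exc:  # malformed rows
        raise TrialParseError(f"{path.name}: {exc}") from exc
    arr = data.to_numpy(dtype=float)
    if np.isnan(arr).any():
        bad = int(np.nonzero(np.isnan(arr).any(axis=1))[0][0])
        raise TrialParseError(f"{path.name}:{bad + 2}: missing or non-numeric value")
    t = arr[:, 0]
    if np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0])
        raise TrialParseError(f"{path.name}:{bad + 3}: time column not strictly increasing")
    dt = np.median(np.diff(t))
    if abs(dt - 1.0 / fs) > 1e-6 / fs:
        raise TrialParseError(
            f"{path.name}: sample spacing {dt:g}s inconsistent with fs={fs:g} Hz"
        )
    return arr[:, 1:]


def read_trials(path: str | Path) -> list[FMGRecording]:
    """Load a trial directory written by :func:`write_dataset`.

    Validates headers, channel counts against the metadata, numeric rows and
    a strictly increasing time column; raises :class:`TrialParseError` with
    the offending file and line.
    """
    root = Path(path)
    meta_path = root / METADATA_FILE
    if not meta_path.exists():
        raise ValueError(f"no {METADATA_FILE} found in {root} (empty or invalid dataset)")
    meta = pd.read_csv(meta_path)
    if meta.empty:
        raise ValueError(f"{meta_path}: metadata table is empty")
    recordings = []
    n_channels = None
    for row in meta.itertuples():
        declared = int(row.n_channels) if hasattr(row, "n_channels") else None
        sig = _read_trial_file(root / row.file, float(row.fs), declared)
        if n_channels is None:
            n_channels = sig.shape[1]
        elif sig.shape[1] != n_channels:
            raise TrialParseError(
                f"{row.file}: {sig.shape[1]} channels, expected {n_channels}"
            )
        recordings.append(
            FMGRecording(
                signal=sig,
                fs=float(row.fs),
                participant=int(row.participant),
                action=str(row.action),
                action_type=str(row.action_type),
                placement=str(row.placement),
                trial=int(row.trial),
            )
        )
    return recordings


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["actions"] = [dataclasses.asdict(a) for a in config.actions]
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "actions" in d:
        d["actions"] = tuple(
            ActionSpec(**{**a, "fundamental_range": tuple(a["fundamental_range"])})
            for a in d["actions"]
        )
    for key in (
        "channel_gain_range",
        "channel_offset_range",
        "drift_freq_range",
        "secondary_drift_freq_range",
        "participant_gain_range",
        "placements",
    ):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a synthetic-study config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    p = Path(path)
    d = config_to_dict(config)
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
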