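"""End-to-end orchestration: simulate (or load) -> normalize -> RMSE sweep ->
percentile curves -> PSD -> bandwidth -> ANOVA/Tukey -> summary report.

Every stage is deterministic given the config and seed, so all artifacts are
regenerable byte-for-byte.  Trials may come from the synthetic generator or
from an external directory in the trial-file format — the pipeline does not
distinguish the two.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .factors import bin_frequencies, n_way_anova, tukey_hsd
from .io import config_to_dict, read_trials, write_json
from .preprocessing import normalize
from .reconstruction import (
    METHODS,
    CategoryKey,
    categories,
    percentile_curves,
    rmse_sweep,
)
from .spectral import category_bandwidth, recording_max_psd
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("fmgsampling")


def default_steps() -> tuple[int, ...]:
    """Decimation steps for a standard run: every step resolving 10-100 Hz
    (the factorial-analysis band) plus sparse coverage of the full 1-500 Hz
    sweep for the distribution curves."""
    dense = range(10, 101)  # 100 Hz down to 10 Hz
    sparse = (2, 3, 4, 5, 6, 8, 125, 167, 250, 333, 500, 1000)
    return tuple(sorted(set(dense) | set(sparse)))


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_dir: str | None = None  # externally supplied trials, if any
    steps: tuple[int, ...] = field(default_factory=default_steps)
    methods: tuple[str, ...] = METHODS
    norm_scope: str = "per_participant_placement"
    psd_method: str = "fft"  # {"fft", "burg", "yule_walker"}
    ar_order: int = 30
    threshold_fraction: float = 0.01
    percentile: float = 95.0
    channel_mean: bool = False
    checkpoint_hz: float = 100.0

    def validate(self) -> None:
        self.synthetic.validate()
        n = self.synthetic.n_samples
        for s in self.steps:
            if not (2 <= s <= n):
                raise ValueError(f"step {s} outside [2, {n}]")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValueError(f"input_dir {self.input_dir!r} does not exist")
        if not (0 < self.threshold_fraction <= 1):
            raise ValueError("threshold_fraction must be in (0, 1]")


@dataclass
class SummaryReport:
    """Per-category band edges and error checkpoints, the ANOVA table, and
    full provenance (config hash, seed, package/library versions)."""

    categories: dict
    anova: pd.DataFrame
    tukey: pd.DataFrame
    rmse_records: pd.DataFrame
    curves: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "categories": self.categories,
            "anova": {
                term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for term, row in self.anova[["F", "p"]].iterrows()
            },
            "provenance": self.provenance,
        }


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d["synthetic"] = config_to_dict(config.synthetic)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> SummaryReport:
    """Execute all stages; optionally write plain-text artifacts to out_dir."""
    config.validate()

    stage = "simulate"
    try:
        if config.input_dir is not None:
            stage = "read_trials"
            recordings = read_trials(config.input_dir)
        else:
            recordings, _ = generate_dataset(config.synthetic)
        logger.info("stage=%s recordings=%d", stage, len(recordings))

        stage = "normalize"
        normalized = normalize(recordings, scope=config.norm_scope)

        stage = "rmse_sweep"
        records = rmse_sweep(
            normalized,
            steps=config.steps,
            methods=config.methods,
            channel_mean=config.channel_mean,
        )
        logger.info("stage=rmse_sweep records=%d", len(records))

        stage = "distributions"
        cats = categories(records)
        curves = {
            c.label(): percentile_curves(records, c, method=config.methods[0])
            for c in cats
        }

        stage = "psd"
        psd_method = "fft" if config.psd_method == "fft" else config.psd_method
        by_cat: dict[str, list] = {c.label(): [] for c in cats}
        for rec in normalized:
            key = CategoryKey(rec.action_type, rec.placement).label()
            if key in by_cat:
                by_cat[key].append(
                    recording_max_psd(rec, method=psd_method, order=config.ar_order)
                )

        stage = "bandwidth"
        cat_summary = {}
        fs = normalized[0].fs
        for c in cats:
            bw = category_bandwidth(
                by_cat[c.label()], c.label(),
                q=config.percentile, threshold_fraction=config.threshold_fraction,
            )
            curve = curves[c.label()]
            # RMSE checkpoint: the percentile curve at the reference frequency.
            step = int(round(fs / config.checkpoint_hz))
            f_ref = fs / step
            col = f"p{config.percentile:g}"
            checkpoint = (
                float(curve.loc[f_ref, col])
                if col in curve.columns and f_ref in curve.index
                else None
            )
            cat_summary[c.label()] = {
                "upper_bound_hz": bw.upper_bound_hz,
                "min_sampling_hz": bw.min_sampling_hz,
                "max_power_freq": bw.max_power_freq,
                f"rmse_{col}_at_{config.checkpoint_hz:g}hz": checkpoint,
                "n_trials": len(by_cat[c.label()]),
            }

        stage = "anova"
        table = bin_frequencies(records)
        factors = ["freq_group", "action_type", "participant", "placement", "method"]
        factors = [f for f in factors if table[f].nunique() >= 2]
        interactions = [
            (f, "method") for f in factors if f != "method" and "method" in factors
        ]
        anova = n_way_anova(table, factors=factors, interactions=interactions)
        tukey = tukey_hsd(table, factor="freq_group")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.synthetic.seed,
        "norm_scope": config.norm_scope,
        "psd_method": config.psd_method,
        "percentile": config.percentile,
        "threshold_fraction": config.threshold_fraction,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    report = SummaryReport(
        categories=cat_summary,
        anova=anova,
        tukey=tukey,
        rmse_records=records,
        curves=curves,
        provenance=provenance,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "rmse_records.csv", index=False)
        for label, curve in curves.items():
            curve.to_csv(out / f"rmse_curves_{label}.csv")
        anova.to_csv(out / "anova.csv")
        tukey.to_csv(out / "tukey.csv", index=False)
        write_json(report.to_dict(), out / "summary.json")
    return report
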