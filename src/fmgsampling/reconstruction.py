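"""Decimation, interpolation-based reconstruction, and the mean-RMSE statistic.

The core discrepancy measure: decimate a normalized multichannel signal by an
integer step (plain sample-dropping, no anti-alias filter — the question is
precisely what slow sampling loses), reconstruct it on the original 1 kHz
index grid by interpolation, and summarize the difference with the mean RMSE

    avg_rmse = sqrt( sum_j sum_i (x_ij - x'_ij)^2 / (n * m) )

pooled over all n samples and m channels (an option averages per-channel
RMSEs instead).  Interpolation levels mirror the three factor levels of the
factorial analysis: ``linear``, ``cubic`` (shape-preserving local cubic,
PCHIP) and ``spline`` (not-a-knot cubic spline).  Beyond the last retained
sample the reconstruction holds the last value for every method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

METHODS = ("linear", "cubic", "spline")
PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class CategoryKey:
    """One of the four analysis categories: action type x strap placement."""

    action_type: str
    placement: str

    def label(self) -> str:
        return f"{self.action_type}_{self.placement}"


def categories(records: pd.DataFrame | None = None) -> list[CategoryKey]:
    """The category partition: all four by default, or those present in a table."""
    if records is None:
        return [
            CategoryKey(a, p)
            for a in ("isometric", "dynamic")
            for p in ("forearm", "wrist")
        ]
    pairs = records[["action_type", "placement"]].drop_duplicates()
    return [CategoryKey(r.action_type, r.placement) for r in pairs.itertuples()]


def downsample(signal: np.ndarray, step: int, phase: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Keep samples at indices phase, phase+step, ... (plain decimation).

    Returns the decimated matrix and the retained-index array.  Output length
    is ceil((n - phase) / step); step must satisfy 1 <= step <= n.
    """
    signal = np.asarray(signal)
    n = signal.shape[0]
    step = int(step)
    if step < 1 or step > n:
        raise ValueError(f"step must satisfy 1 <= step <= n_samples ({n}), got {step}")
    if not (0 <= phase < step):
        raise ValueError(f"phase must satisfy 0 <= phase < step, got {phase}")
    idx = np.arange(phase, n, step)
    return signal[idx], idx


def reconstruct(
    decimated: np.ndarray,
    retained_indices: np.ndarray,
    target_length: int,
    method: str,
) -> np.ndarray:
    """Interpolate decimated samples back onto the full original index grid.

    Between retained indices the named interpolant is used; past the last
    retained index the last value is held.  Linear needs >= 2 retained
    samples, cubic/spline need >= 4.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    dec = np.asarray(decimated, dtype=float)
    idx = np.asarray(retained_indices)
    squeeze = dec.ndim == 1
    if squeeze:
        dec = dec[:, None]
    min_pts = 2 if method == "linear" else 4
    if len(idx) < min_pts:
        raise ValueError(
            f"{method} reconstruction needs at least {min_pts} retained samples, "
            f"got {len(idx)}"
        )
    grid = np.arange(target_length)
    last = idx[-1]
    inside = grid[grid <= last]

    if method == "linear":
        out = np.empty((target_length, dec.shape[1]))
        for j in range(dec.shape[1]):
            out[: len(inside), j] = np.interp(inside, idx, dec[:, j])
    else:
        interp = (
            PchipInterpolator(idx, dec, axis=0)
            if method == "cubic"
            else CubicSpline(idx, dec, axis=0, bc_type="not-a-knot")
        )
        out = np.empty((target_length, dec.shape[1]))
        out[: len(inside)] = interp(inside)
    # Hold-last-value extrapolation for the tail.
    out[len(inside):] = dec[-1]
    return out[:, 0] if squeeze else out


def mean_rmse(original: np.ndarray, reconstructed: np.ndarray, channel_mean: bool = False) -> float:
    """The mean-RMSE discrepancy between an original and reconstructed matrix.

    Default reading: square root of the grand mean of squared errors pooled
    over samples and channels.  With ``channel_mean=True`` the per-channel
    RMSEs are averaged instead.  Zero iff the matrices are identical.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(reconstructed, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sq = (a - b) ** 2
    if channel_mean and a.ndim == 2:
        return float(np.mean(np.sqrt(sq.mean(axis=0))))
    return float(np.sqrt(sq.mean()))


def rmse_sweep(
    recordings: Iterable,
    steps: Sequence[int] = range(2, 1001),
    methods: Sequence[str] = METHODS,
    channel_mean: bool = False,
    phase: int = 0,
) -> pd.DataFrame:
    """One mean-RMSE record per (trial, step, interpolation method).

    ``recordings`` are normalized recordings; ``sub_frequency = fs / step``
    is kept at full precision (binning happens in the factor analysis).
    """
    steps = [int(s) for s in steps]
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown interpolation method {m!r}")
    rows = []
    for rec in recordings:
        sig = rec.signal
        n = sig.shape[0]
        for step in steps:
            dec, idx = downsample(sig, step, phase=phase)
            for method in methods:
                recon = reconstruct(dec, idx, n, method)
                rows.append(
                    (
                        rec.participant,
                        rec.action,
                        rec.action_type,
                        rec.placement,
                        rec.trial,
                        step,
                        rec.fs / step,
                        method,
                        mean_rmse(sig, recon, channel_mean=channel_mean),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "action",
            "action_type",
            "placement",
            "trial",
            "step",
            "sub_frequency",
            "method",
            "rmse",
        ],
    )


def percentile_curves(
    records: pd.DataFrame,
    category: CategoryKey,
    percentiles: Sequence[float] = PERCENTILES,
    method: str | None = "linear",
) -> pd.DataFrame:
    """Percentile-vs-frequency curves of the RMSE distribution for one category.

    Returns a frame indexed by ``sub_frequency`` (ascending) with one column
    per requested percentile (``p5`` ... ``p95``).  Percentiles use linear
    interpolation between closest ranks (numpy's default), so curves are
    reproducible bit-for-bit.
    """
    sel = records[
        (records["action_type"] == category.action_type)
        & (records["placement"] == category.placement)
    ]
    if method is not None:
        sel = sel[sel["method"] == method]
    if sel.empty:
        raise ValueError(f"no RMSE records in category {category.label()!r}")
    grouped = sel.groupby("sub_frequency")["rmse"]
    data = {
        f"p{int(q) if float(q).is_integer() else q}": grouped.quantile(q / 100.0)
        for q in percentiles
    }
    curves = pd.DataFrame(data).sort_index()
    curves.attrs["category"] = category.label()
    return curves
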