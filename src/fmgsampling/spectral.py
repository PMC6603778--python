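"""PSD estimation and Nyquist-based minimum-sampling-frequency derivation.

Two estimators share one frequency grid (k/T for k = 1..N/2; the 0 Hz bin is
always excluded because the strictly positive sensor voltage makes it
disproportionately large):

* ``psd_fft`` — raw one-sided boxcar periodogram, density scaling, so the
  bin-sum times the bin width recovers the signal's mean square power
  (Parseval);
* ``psd_ar`` — autoregressive spectrum (maximum-entropy Burg fit by default,
  Yule-Walker selectable), which does not assume periodicity.

Per-channel spectra are reduced bin-wise by maximum across the eight sensors
("maximum FMG power density"), percentile curves are formed across all trials
of a category, and the band upper bound is the highest frequency at which the
curve still reaches ``threshold_fraction`` (default 1%) of its maximum
reading.  The recommended minimum sampling frequency is twice that bound,
rounded to the nearest integer hertz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import freqz, periodogram
from statsmodels.regression.linear_model import burg as _burg
from statsmodels.regression.linear_model import yule_walker as _yule_walker


@dataclass(frozen=True)
class PSDCurve:
    """A one-sided PSD on a DC-excluded frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    source: str = "fft"  # {"fft", "ar"}
    reduction: str = "per_channel"  # {"per_channel", "max_channels", "percentile_q"}

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1 or f.size == 0:
            raise ValueError("freqs and power must be equal-length 1-D arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if f[0] <= 0:
            raise ValueError("the 0 Hz bin must be excluded from a PSDCurve")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("power must be finite and nonnegative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class BandwidthResult:
    """The 1%-criterion band upper bound and its Nyquist minimum rate."""

    category: str
    upper_bound_hz: float
    threshold_fraction: float
    max_power: float
    max_power_freq: float
    min_sampling_hz: int


def _grid(n: int, fs: float) -> np.ndarray:
    return np.arange(1, n // 2 + 1) * (fs / n)


def psd_fft(signal: np.ndarray, fs: float) -> PSDCurve:
    """Raw one-sided periodogram of a single-channel record, DC bin dropped.

    For a 5 s record at 1 kHz the grid is 0.2, 0.4, ..., 500 Hz.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("psd_fft expects a 1-D signal of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("psd_fft input contains non-finite values")
    freqs, pxx = periodogram(
        x, fs=fs, window="boxcar", detrend=False, scaling="density"
    )
    return PSDCurve(freqs=freqs[1:], power=pxx[1:], source="fft")


def psd_ar(
    signal: np.ndarray, fs: float, order: int = 30, method: str = "burg"
) -> PSDCurve:
    """Autoregressive PSD on the same DC-excluded grid as ``psd_fft``.

    AR coefficients are fit by the maximum-entropy Burg criterion (default)
    or Yule-Walker, after mean removal; the spectrum is the all-pole transfer
    function scaled so it is a one-sided density.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("psd_ar expects a 1-D signal")
    if order < 1 or order >= x.size / 2:
        raise ValueError(f"order must satisfy 1 <= order < n/2, got {order}")
    if not np.all(np.isfinite(x)):
        raise ValueError("psd_ar input contains non-finite values")
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        raise ValueError("degenerate AR fit: zero-variance signal has no spectrum")
    if method == "burg":
        ar, sigma2 = _burg(xc, order=order, demean=False)
    elif method == "yule_walker":
        ar, sigma2 = _yule_walker(xc, order=order, method="mle")
        sigma2 = sigma2**2  # yule_walker returns an innovation scale, not variance
    else:
        raise ValueError(f"method must be 'burg' or 'yule_walker', got {method!r}")
    freqs = _grid(x.size, fs)
    _, h = freqz(1.0, np.r_[1.0, -np.asarray(ar)], worN=2 * np.pi * freqs / fs)
    power = 2.0 * (sigma2 / fs) * np.abs(h) ** 2
    if not np.all(np.isfinite(power)):
        raise ValueError(
            f"unstable AR({order}) fit by {method}: non-finite spectrum values"
        )
    return PSDCurve(freqs=freqs, power=power, source="ar")


def _check_grids(curves: Sequence[PSDCurve]) -> np.ndarray:
    if not curves:
        raise ValueError("need at least one PSD curve")
    f0 = curves[0].freqs
    for c in curves[1:]:
        if c.freqs.shape != f0.shape or not np.allclose(c.freqs, f0):
            raise ValueError("PSD curves are not on identical frequency grids")
    return f0


def max_psd(per_channel_curves: Sequence[PSDCurve]) -> PSDCurve:
    """Bin-wise maximum across channels: the maximum FMG power density."""
    f0 = _check_grids(per_channel_curves)
    power = np.maximum.reduce([c.power for c in per_channel_curves])
    return PSDCurve(
        freqs=f0, power=power,
        source=per_channel_curves[0].source, reduction="max_channels",
    )


def recording_max_psd(recording, method: str = "fft", order: int = 30) -> PSDCurve:
    """Per-channel PSDs of one recording, reduced by bin-wise maximum."""
    sig = recording.signal
    if method == "fft":
        curves = [psd_fft(sig[:, j], recording.fs) for j in range(sig.shape[1])]
    else:
        curves = [
            psd_ar(sig[:, j], recording.fs, order=order, method=method)
            for j in range(sig.shape[1])
        ]
    return max_psd(curves)


def psd_percentile(trial_curves: Sequence[PSDCurve], q: float) -> PSDCurve:
    """Bin-wise q-th percentile across a category's trial curves."""
    f0 = _check_grids(trial_curves)
    power = np.percentile(np.stack([c.power for c in trial_curves]), q, axis=0)
    return PSDCurve(
        freqs=f0, power=power,
        source=trial_curves[0].source, reduction=f"percentile_{q:g}",
    )


def upper_bound_frequency(curve: PSDCurve, threshold_fraction: float = 0.01) -> float:
    """Highest frequency at which power still reaches the threshold fraction
    of the curve's maximum reading (all higher bins are below threshold).

    The last-bin-above-threshold rule is conservative: isolated tail
    re-crossings cannot shrink the estimated band.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    pmax = curve.power.max()
    if pmax <= 0:
        raise ValueError("cannot locate a band edge on an all-zero PSD curve")
    above = np.nonzero(curve.power >= threshold_fraction * pmax)[0]
    return float(curve.freqs[above[-1]])


def nyquist_minimum(upper_bound_hz: float) -> int:
    """Twice the band upper bound, rounded to the nearest integer hertz."""
    if upper_bound_hz < 0:
        raise ValueError("upper_bound_hz must be >= 0")
    return int(np.floor(2.0 * upper_bound_hz + 0.5))


def category_bandwidth(
    trial_curves: Sequence[PSDCurve],
    category: str,
    q: float = 95.0,
    threshold_fraction: float = 0.01,
) -> BandwidthResult:
    """Percentile-reduce a category's trial curves and derive its band edge."""
    curve = psd_percentile(trial_curves, q)
    ub = upper_bound_frequency(curve, threshold_fraction)
    imax = int(np.argmax(curve.power))
    return BandwidthResult(
        category=category,
        upper_bound_hz=ub,
        threshold_fraction=threshold_fraction,
        max_power=float(curve.power[imax]),
        max_power_freq=float(curve.freqs[imax]),
        min_sampling_hz=nyquist_minimum(ub),
    )
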