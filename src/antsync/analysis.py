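"""Activity time-series analysis pipeline.

The processing chain applied to every colony activity record (simulated or
empirical-style) is: Gaussian-weighted moving-average smoothing (15-point
window at 30 s cadence = 7.5 min), min-max rescaling to [0, 1], and then
either peak/interval statistics, a Morse continuous-wavelet dominant-period
estimate (see :mod:`antsync.wavelet`) or Lomb-Scargle periodograms.  Long
non-stationary records are detrended with a fourth-degree polynomial before
Lomb-Scargle analysis.

Rhythm regularity of spike-like activity trains is summarised by the
coefficient of variation of the inter-beat intervals,
``CV = std(IBI) / mean(IBI)`` (CV = 0 perfectly periodic, CV -> 1 for a
Poisson process).  The standard deviation is the sample one (n - 1 in the
denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .trace import ActivityTrace

__all__ = [
    "SpikeTrainStats",
    "SpectrumResult",
    "gaussian_smooth",
    "minmax_normalize",
    "detect_peaks",
    "ibi_cv",
    "detrend_poly",
    "lomb_scargle",
    "aggregate_spectra",
    "birhythmicity_index",
    "subharmonic_birhythmic",
    "preprocess",
]


@dataclass
class SpikeTrainStats:
    """Peak-interval summary of a spike-like activity record."""

    peak_times: np.ndarray  # seconds
    mean_ibi: float  # seconds
    cv: float  # dimensionless


@dataclass
class SpectrumResult:
    """A period-domain power spectrum with peak diagnostics.

    ``dominant_period`` is the grid period with maximal power;
    ``secondary_period`` is the highest local maximum whose period differs
    from the dominant by at least ``separation factor`` (1.25 by default in
    the detectors), and ``secondary_ratio`` its power relative to the
    dominant peak.
    """

    periods: np.ndarray  # seconds, ascending
    power: np.ndarray
    dominant_period: float
    secondary_period: Optional[float] = None
    secondary_ratio: float = 0.0
    method: str = ""


def gaussian_smooth(trace: ActivityTrace, window: int = 15, sigma: Optional[float] = None) -> ActivityTrace:
    """Gaussian-weighted moving average with an odd ``window`` (points).

    ``sigma`` defaults to ``window / 5`` points.  Edges are handled with a
    renormalised truncated kernel, so constants are preserved everywhere and
    the output has the input's length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if len(trace) < window:
        raise ValueError(f"trace length {len(trace)} shorter than window {window}")
    if sigma is None:
        sigma = window / 5.0
    half = window // 2
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    num = np.convolve(trace.values, k, mode="same")
    den = np.convolve(np.ones(len(trace)), k, mode="same")
    return trace.with_values(num / den)


def minmax_normalize(trace: ActivityTrace) -> ActivityTrace:
    """Affinely rescale so the smallest value is 0 and the largest is 1."""
    lo, hi = float(np.min(trace.values)), float(np.max(trace.values))
    if hi <= lo:
        raise ValueError("cannot min-max normalize a constant series")
    return trace.with_values((trace.values - lo) / (hi - lo))


def preprocess(trace: ActivityTrace, window: int = 15) -> ActivityTrace:
    """Standard pipeline front end: smooth, then rescale to [0, 1]."""
    return minmax_normalize(gaussian_smooth(trace, window=window))


def detect_peaks(trace: ActivityTrace, min_prominence: float = 0.2) -> np.ndarray:
    """Indices of local maxima with topographic prominence >= ``min_prominence``.

    Prominence is the peak height minus the higher of the two deepest valleys
    separating the peak from higher terrain (or the series edge).  Flat-topped
    peaks report their centre sample.
    """
    idx, _ = signal.find_peaks(trace.values, prominence=min_prominence)
    return idx


def peak_times(trace: ActivityTrace, min_prominence: float = 0.2) -> np.ndarray:
    """Peak times in seconds for ``detect_peaks`` on a uniform trace."""
    return trace.times[detect_peaks(trace, min_prominence)]


def ibi_cv(peak_times: Sequence[float]) -> SpikeTrainStats:
    """Inter-beat-interval mean and coefficient of variation.

    Requires at least three strictly increasing peak times (two intervals);
    CV uses the sample standard deviation (ddof=1).
    """
    tp = np.asarray(peak_times, float)
    if tp.size < 3:
        raise ValueError("CV needs >= 3 peak times (>= 2 intervals)")
    if np.any(np.diff(tp) <= 0):
        raise ValueError("peak times must be strictly increasing")
    ibis = np.diff(tp)
    mean_ibi = float(np.mean(ibis))
    cv = float(np.std(ibis, ddof=1) / mean_ibi)
    return SpikeTrainStats(peak_times=tp, mean_ibi=mean_ibi, cv=cv)


def detrend_poly(trace: ActivityTrace, degree: int = 4) -> ActivityTrace:
    """Subtract the least-squares polynomial of the given degree."""
    n = len(trace)
    if n <= degree + 1:
        raise ValueError(f"need more than degree+1={degree + 1} samples, got {n}")
    t = trace.times
    coeffs = np.polynomial.polynomial.Polynomial.fit(t, trace.values, degree)
    return trace.with_values(trace.values - coeffs(t))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _find_secondary(
    periods: np.ndarray, power: np.ndarray, dominant_period: float, separation_factor: float
) -> Tuple[Optional[float], float]:
    """Highest local maximum separated from the dominant peak by >= factor."""
    if periods.size < 3:
        return None, 0.0
    loc, _ = signal.find_peaks(power)
    if loc.size == 0:
        return None, 0.0
    pd_ = periods[loc]
    sep = np.maximum(pd_ / dominant_period, dominant_period / pd_) >= separation_factor
    if not np.any(sep):
        return None, 0.0
    cand = loc[sep]
    best = cand[np.argmax(power[cand])]
    pmax = float(np.max(power))
    if pmax <= 0:
        return None, 0.0
    return float(periods[best]), float(power[best] / pmax)


def _make_spectrum(
    periods: np.ndarray, power: np.ndarray, method: str, separation_factor: float = 1.25
) -> SpectrumResult:
    dom = float(periods[int(np.argmax(power))])
    sec, ratio = _find_secondary(periods, power, dom, separation_factor)
    return SpectrumResult(
        periods=periods,
        power=power,
        dominant_period=dom,
        secondary_period=sec,
        secondary_ratio=ratio,
        method=method,
    )


def period_grid(trace: ActivityTrace, n_periods: int = 2000,
                period_range: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Logarithmic period grid from 2*dt to half the record length."""
    if period_range is None:
        period_range = (2.0 * trace.dt, trace.duration / 2.0)
    lo, hi = period_range
    if not 0 < lo < hi:
        raise ValueError("invalid period range")
    return np.geomspace(lo, hi, n_periods)


def lomb_scargle(
    trace: ActivityTrace,
    n_periods: int = 2000,
    period_range: Optional[Tuple[float, float]] = None,
    separation_factor: float = 1.25,
) -> SpectrumResult:
    """Variance-normalised Lomb-Scargle periodogram over a log period grid.

    The default grid spans 2*dt to half the record length with 2 000 points.
    """
    periods = period_grid(trace, n_periods, period_range)
    freqs = 2.0 * np.pi / periods  # angular
    y = trace.values - np.mean(trace.values)
    power = signal.lombscargle(trace.times, y, freqs, normalize=True)
    order = np.argsort(periods)
    return _make_spectrum(periods[order], power[order], "lomb_scargle", separation_factor)


def aggregate_spectra(spectra: List[SpectrumResult]) -> SpectrumResult:
    """Rescale each spectrum to unit maximum and sum pointwise.

    Spectra are interpolated (linearly in log period) onto the first
    spectrum's grid when grids differ.  Shared periodicities across records
    reinforce; idiosyncratic peaks stay at unit height.
    """
    if not spectra:
        raise ValueError("aggregate_spectra needs at least one spectrum")
    grid = spectra[0].periods
    total = np.zeros_like(grid, dtype=float)
    for sp in spectra:
        pmax = float(np.max(sp.power))
        if pmax <= 0:
            raise ValueError("cannot rescale an all-zero spectrum")
        scaled = sp.power / pmax
        if sp.periods.shape == grid.shape and np.allclose(sp.periods, grid):
            total += scaled
        else:
            total += np.interp(np.log(grid), np.log(sp.periods), scaled, left=0.0, right=0.0)
    return _make_spectrum(grid, total, "aggregate")


def birhythmicity_index(
    spectrum: SpectrumResult,
    ratio_threshold: float = 0.5,
    separation_factor: float = 1.25,
) -> str:
    """Classify a spectrum as ``"birhythmic"`` or ``"monorhythmic"``.

    Birhythmic when a secondary peak at least ``separation_factor`` away in
    period carries at least ``ratio_threshold`` of the dominant peak's power.
    The secondary peak is re-derived from the spectrum at the requested
    separation, so a stricter separation than the one stored on the
    :class:`SpectrumResult` can be used (two rhythms produced by
    period-doubling sit near a 2:1 ratio, while noise broadening of a single
    rhythm produces spurious neighbours within ~1.5x).
    """
    sec, ratio = _find_secondary(
        spectrum.periods, spectrum.power, spectrum.dominant_period, separation_factor
    )
    if sec is not None and ratio >= ratio_threshold:
        return "birhythmic"
    return "monorhythmic"


def subharmonic_birhythmic(
    spectrum: SpectrumResult,
    ratio_threshold: float = 0.5,
    ratio_window: Tuple[float, float] = (1.6, 2.5),
) -> bool:
    """Detect switching between a cycle and its period-doubled partner.

    In systems where a second collective rhythm appears by period doubling
    (agents skipping every other wave), the two cycles sit near a 2:1 period
    ratio.  This detector asks for a secondary spectral peak whose period
    differs from the dominant one by a factor inside ``ratio_window``
    (either direction) and whose power is at least ``ratio_threshold`` of
    the dominant peak — distinguishing genuine two-cycle dynamics from the
    spectral broadening of a single noisy rhythm, whose spurious neighbours
    fall closer than ~1.5x.
    """
    loc, _ = signal.find_peaks(spectrum.power)
    if loc.size == 0:
        return False
    pd_ = spectrum.periods[loc]
    r = np.maximum(pd_ / spectrum.dominant_period, spectrum.dominant_period / pd_)
    inside = (r >= ratio_window[0]) & (r <= ratio_window[1])
    if not np.any(inside):
        return False
    pmax = float(np.max(spectrum.power))
    return bool(np.max(spectrum.power[loc[inside]]) >= ratio_threshold * pmax)
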