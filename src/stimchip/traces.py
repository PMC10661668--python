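"""Per-ROI fluorescence traces: extraction, ΔF/F₀ normalization, spike calls.

The raw trace of an ROI is the spatial mean of its pixels in every frame.
Slow drift (bleaching, focus) is removed by subtracting a centered rolling
median (default window 20 frames, shrinking at the edges); the residual is
normalized by the mean of that trend, giving a dimensionless ΔF/F₀ trace.
Calcium spikes are called where ΔF/F₀ exceeds mean + k·SD (default k = 3,
SD over the full processed trace): the calls are the supra-threshold local
maxima of the trace, with peaks closer than ``min_separation`` frames
merged (taller wins).  Rates are reported per minute and,
when a baseline session is given, normalized by its mean rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DomainError, NormalizationError

__all__ = [
    "TraceParams",
    "FluorescenceTrace",
    "SpikeCalls",
    "extract_traces",
    "rolling_median_trend",
    "detrend_normalize",
    "detect_spikes",
    "normalized_rate",
]


@dataclass(frozen=True)
class TraceParams:
    rolling_window: int = 20
    spike_k: float = 3.0
    min_separation: int = 2

    def __post_init__(self) -> None:
        if self.rolling_window < 2:
            raise DomainError("rolling_window must be >= 2")
        if self.spike_k <= 0:
            raise DomainError("spike_k must be > 0")
        if self.min_separation < 0:
            raise DomainError("min_separation must be >= 0")


@dataclass
class FluorescenceTrace:
    """Raw, trend and ΔF/F₀ layers of one ROI's time series."""

    label: int
    raw: np.ndarray
    frame_interval: float
    trend: np.ndarray | None = None
    dff: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.raw.size

    @property
    def duration_minutes(self) -> float:
        return self.n_frames * self.frame_interval / 60.0


@dataclass
class SpikeCalls:
    """Called spike frames for one ROI, with the threshold that produced them."""

    label: int
    frames: np.ndarray
    threshold: float
    rate_per_min: float


def extract_traces(
    movie_channel: np.ndarray, mask: np.ndarray, frame_interval: float = 0.120
) -> list[FluorescenceTrace]:
    """Spatial mean per labeled ROI per frame.

    ``mask`` holds 0 for background and 1..K for ROIs; every label in
    1..max(mask) must be present.
    """
    stack = np.asarray(movie_channel)
    if stack.ndim != 3:
        raise DomainError("expected a (T, H, W) stack")
    if mask.shape != stack.shape[1:]:
        raise DomainError("mask shape does not match frame shape")
    n_labels = int(mask.max())
    if n_labels == 0:
        return []

    flat_mask = mask.ravel()
    inside = flat_mask > 0
    labels = flat_mask[inside]
    counts = np.bincount(labels, minlength=n_labels + 1)[1:]
    if (counts == 0).any():
        empty = 1 + int(np.argmin(counts))
        raise DomainError(f"label {empty} has no pixels")

    T = stack.shape[0]
    sums = np.empty((T, n_labels))
    frames = stack.reshape(T, -1)
    for t in range(T):
        sums[t] = np.bincount(labels, weights=frames[t, inside].astype(float),
                              minlength=n_labels + 1)[1:]
    means = sums / counts
    return [
        FluorescenceTrace(label=k + 1, raw=means[:, k], frame_interval=frame_interval)
        for k in range(n_labels)
    ]


def rolling_median_trend(raw: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median with the window shrinking at the edges.

    For an even window the span at index i is ``[i - w//2, i + w//2 - 1]``,
    clipped to the trace; every frame gets a trend value.
    """
    series = pd.Series(np.asarray(raw, dtype=float))
    return series.rolling(window=window, center=True, min_periods=1).median().to_numpy()


def detrend_normalize(
    trace: FluorescenceTrace, params: TraceParams | None = None
) -> np.ndarray:
    """Compute ΔF/F₀ = (F - trend) / mean(trend); stores trend and dff on the
    trace and returns the dff array."""
    params = params or TraceParams()
    if trace.n_frames <= params.rolling_window:
        raise DomainError(
            f"trace length {trace.n_frames} must exceed window {params.rolling_window}"
        )
    trend = rolling_median_trend(trace.raw, params.rolling_window)
    f0 = float(trend.mean())
    if f0 <= 0:
        raise NormalizationError(f"mean trend must be > 0, got {f0}")
    dff = (np.asarray(trace.raw, dtype=float) - trend) / f0
    trace.trend = trend
    trace.dff = dff
    return dff


def detect_spikes(
    dff: np.ndarray | FluorescenceTrace,
    params: TraceParams | None = None,
    frame_interval: float = 0.120,
    label: int = 0,
) -> SpikeCalls:
    """Call spikes at threshold mean + k·SD of the processed trace.

    Calls are the local maxima of the trace above the threshold (a flat-top
    transient is called once, at the plateau's middle frame); peaks closer
    than ``min_separation`` frames are merged and the taller one wins.
    Counting peaks rather than threshold crossings keeps the call count
    non-increasing in ``k``: raising the threshold can split one
    supra-threshold run into several, but never creates a local maximum.
    A zero-variance trace yields no calls.
    """
    params = params or TraceParams()
    if isinstance(dff, FluorescenceTrace):
        label = dff.label
        frame_interval = dff.frame_interval
        if dff.dff is None:
            raise DomainError("trace has no dff layer; run detrend_normalize first")
        x = np.asarray(dff.dff, dtype=float)
    else:
        x = np.asarray(dff, dtype=float)
    if not np.isfinite(x).all():
        raise DomainError("dff contains non-finite values")

    sd = float(x.std())
    theta = float(x.mean()) + params.spike_k * sd
    duration_min = x.size * frame_interval / 60.0

    if sd == 0:
        return SpikeCalls(label, np.empty(0, dtype=int), theta, 0.0)

    peaks, _ = signal.find_peaks(
        x, height=theta, distance=max(1, params.min_separation)
    )
    rate = peaks.size / duration_min
    return SpikeCalls(label, peaks.astype(int), theta, rate)


def normalized_rate(
    rates: np.ndarray | list[float] | list[SpikeCalls], baseline_mean_rate: float
) -> np.ndarray:
    """Divide spike rates by the baseline-session mean rate of their culture."""
    if not baseline_mean_rate > 0:
        raise NormalizationError(
            f"baseline mean rate must be > 0, got {baseline_mean_rate}"
        )
    if len(rates) and isinstance(rates[0], SpikeCalls):
        values = np.array([c.rate_per_min for c in rates], dtype=float)
    else:
        values = np.asarray(rates, dtype=float)
    return values / baseline_mean_rate
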