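"""Trend extraction, oscillation diagnostics, cross-correlation delay
inference and trajectory classification for vein radius / shear series.

The peristaltic contraction (period T ≈ 1–2 min) is fast compared to vein
wall adaptation (tens of minutes); all causal analysis therefore runs on
time-averaged trends ⟨a⟩(t), ⟨τ⟩(t).  The sensing delay is inferred as the
lag maximising the Pearson cross-correlation between the shifted shear
trend ⟨τ⟩(t − Δ) and the adaptation rate d⟨a⟩/dt(t); a positive lag means
shear leads radius change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "DelayEstimate",
    "TrajectoryClass",
    "ClassifyConfig",
    "trend",
    "contraction_period",
    "estimate_delay",
    "delay_census",
    "loop_orientation",
    "classify_trajectory",
]


@dataclass
class DelayEstimate:
    """Result of the cross-correlation lag scan."""

    t_delay_s: float            # signed; positive = shear leads radius change
    peak_correlation: float     # in [-1, 1]
    significant: bool           # peak_correlation > threshold

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.peak_correlation <= 1.0 + 1e-9:
            raise ValueError("correlation outside [-1, 1]")


@dataclass
class TrajectoryClass:
    """Label of one (⟨a⟩, ⟨τ⟩) trajectory."""

    label: Literal["stable", "shrinking_monotonic_decrease",
                   "shrinking_monotonic_increase", "shrinking_nonmonotonic",
                   "unclassifiable"]
    orientation: Literal["clockwise", "anticlockwise", "none"] = "none"

    def __post_init__(self) -> None:
        if self.orientation != "none" and self.label != "stable":
            raise ValueError("orientation applies to stable loops only")


@dataclass
class ClassifyConfig:
    """Thresholds of the trajectory census (package defaults, configurable)."""

    min_duration_s: float = 900.0     # 15 min of data required
    shrink_fraction: float = 0.25     # final/initial radius below -> shrinking
    drift_fraction: float = 0.20      # |net drift| below this × mean -> stable
    a_min_um: float = 0.5             # reaching this radius counts as vanished
    smooth_window_s: float | None = None  # for dτ/dt sign analysis


# ---------------------------------------------------------------------------

def trend(times: np.ndarray, values: np.ndarray, window_s: float
          ) -> np.ndarray:
    """Centered moving average over ``window_s`` seconds.

    Trapezoidal end-weights (half weight on the two outermost samples), so
    a sinusoid whose period divides the window cancels exactly on a uniform
    grid.  Output is on the input grid; edge windows are truncated.  The
    window must cover at least two samples.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    cadence = float(np.median(np.diff(times)))
    if window_s < 2.0 * cadence:
        raise ValueError(
            f"window {window_s} s shorter than 2 × cadence ({cadence} s)")
    half = max(1, int(round(window_s / cadence)) // 2)
    kernel = np.ones(2 * half + 1)
    kernel[0] = kernel[-1] = 0.5
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def contraction_period(times: np.ndarray, values: np.ndarray,
                       peak_factor: float = 10.0) -> float | None:
    """Dominant oscillation period of a detrended series, in seconds.

    The series is detrended with a moving average, then the periodogram's
    largest non-zero-frequency peak is taken.  Returns None when no peak
    stands above the noise floor (power < ``peak_factor`` × mean power),
    e.g. for white noise.  Requires ≥ 5 putative periods of data.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    cadence = float(np.median(np.diff(times)))
    n = values.size
    win = max(4.0 * cadence, (times[-1] - times[0]) / 5.0)
    detrended = values - trend(times, values, win)
    freqs, power = signal.periodogram(detrended, fs=1.0 / cadence,
                                      detrend="constant")
    freqs, power = freqs[1:], power[1:]
    if power.sum() <= 0:
        return None
    i = int(np.argmax(power))
    if power[i] < peak_factor * power.mean():
        return None
    return float(1.0 / freqs[i])


# ---------------------------------------------------------------------------
# delay inference
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    d = np.sqrt((x * x).sum() * (y * y).sum())
    if d == 0:
        return np.nan
    return float((x * y).sum() / d)


def estimate_delay(times: np.ndarray, tau_trend: np.ndarray,
                   a_trend: np.ndarray, max_lag_s: float = 900.0,
                   threshold: float = 0.5,
                   derivative_smooth_s: float | None = None) -> DelayEstimate:
    """Cross-correlation delay between shear trend and adaptation rate.

    Correlates ⟨τ⟩(t − Δ) against d⟨a⟩/dt(t) (central differences of the
    radius trend) for Δ scanned over ±max_lag at cadence resolution; both
    signs are searched.  Returns the argmax lag, the peak correlation, and
    a significance flag (peak > threshold).  Ties are broken toward the
    smallest |Δ|.  Degenerate (zero-variance) inputs yield an
    insignificant NaN estimate.

    ``derivative_smooth_s``: differencing amplifies any peristaltic ripple
    surviving the trend average, which can make the lag scan lock onto the
    contraction period; re-smoothing the rate series with a centred window
    (typically the one used for the trends) suppresses the ripple without
    adding lag.  None (default) keeps the raw central differences.
    """
    times = np.asarray(times, dtype=float)
    tau_trend = np.asarray(tau_trend, dtype=float)
    a_trend = np.asarray(a_trend, dtype=float)
    cadence = float(np.median(np.diff(times)))
    max_shift = int(round(max_lag_s / cadence))
    n = times.size
    if n < 4 * max_shift:
        raise ValueError("series length must be >= 4 × max lag")
    dadt = np.gradient(a_trend, times)
    if derivative_smooth_s is not None:
        dadt = trend(times, dadt, derivative_smooth_s)

    best: tuple[float, int] | None = None
    for k in range(-max_shift, max_shift + 1):
        if k >= 0:
            x, y = tau_trend[:n - k] if k else tau_trend, dadt[k:]
        else:
            x, y = tau_trend[-k:], dadt[:n + k]
        if x.size < 3:
            continue
        c = _pearson(x, y)
        if np.isnan(c):
            continue
        if best is None or c > best[0] + 1e-15 or \
                (abs(c - best[0]) <= 1e-15 and abs(k) < abs(best[1])):
            best = (c, k)
    if best is None:
        return DelayEstimate(t_delay_s=np.nan, peak_correlation=0.0,
                             significant=False)
    c, k = best
    return DelayEstimate(t_delay_s=k * cadence, peak_correlation=c,
                         significant=bool(c > threshold))


def delay_census(estimates: Iterable[DelayEstimate],
                 cadence_s: float = 6.0) -> dict:
    """Population summary of significant delay estimates.

    Returns a dict with n_significant, fraction_positive, the mean positive
    delay, and a histogram binned at cadence resolution.  An empty
    significant set yields an explicit empty summary.
    """
    sig = [e for e in estimates if e.significant and np.isfinite(e.t_delay_s)]
    if not sig:
        return {"n_significant": 0, "fraction_positive": np.nan,
                "mean_positive_delay_s": np.nan,
                "histogram": (np.array([]), np.array([]))}
    lags = np.array([e.t_delay_s for e in sig])
    pos = lags[lags > 0]
    lo = np.floor(lags.min() / cadence_s) * cadence_s - cadence_s / 2
    hi = np.ceil(lags.max() / cadence_s) * cadence_s + cadence_s / 2
    edges = np.arange(lo, hi + cadence_s, cadence_s)
    counts, edges = np.histogram(lags, bins=edges)
    return {
        "n_significant": len(sig),
        "fraction_positive": float(pos.size / lags.size),
        "mean_positive_delay_s": float(pos.mean()) if pos.size else np.nan,
        "histogram": (counts, edges),
    }


# ---------------------------------------------------------------------------
# trajectory geometry and classification
# ---------------------------------------------------------------------------

def loop_orientation(a_trend: Sequence[float], tau_trend: Sequence[float],
                     rel_tol: float = 1e-6) -> str:
    """Circulation sense of the (⟨a⟩, ⟨τ⟩) trajectory.

    Shoelace signed area of the closed polyline with ⟨a⟩ on the abscissa and
    ⟨τ⟩ on the ordinate: negative area = clockwise.  Returns "none" for
    degenerate (nearly collinear) trajectories.
    """
    x = np.asarray(a_trend, dtype=float)
    y = np.asarray(tau_trend, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 points")
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    scale = (x.max() - x.min()) * (y.max() - y.min())
    if scale == 0 or abs(area) < rel_tol * scale:
        return "none"
    return "clockwise" if area < 0 else "anticlockwise"


def _interior_extrema(times: np.ndarray, series: np.ndarray,
                      window_s: float | None) -> tuple[int, int]:
    """(number of interior maxima, number of sign changes of the smoothed
    derivative)."""
    cadence = float(np.median(np.diff(times)))
    if window_s is None:
        window_s = max(4 * cadence, (times[-1] - times[0]) / 10.0)
    smooth = trend(times, series, window_s)
    d = np.gradient(smooth, times)
    # suppress numerically-zero derivative chatter
    tol = 1e-9 * max(np.abs(d).max(), 1e-300)
    sgn = np.sign(np.where(np.abs(d) < tol, 0.0, d))
    sgn = sgn[sgn != 0]
    changes = int(np.sum(sgn[1:] != sgn[:-1]))
    maxima = int(np.sum((sgn[1:] < 0) & (sgn[:-1] > 0)))
    return maxima, changes


def classify_trajectory(times: np.ndarray, a_trend: np.ndarray,
                        tau_trend: np.ndarray,
                        config: ClassifyConfig | None = None
                        ) -> TrajectoryClass:
    """Assign a trajectory to the stable / shrinking / unclassifiable census.

    Shrinking: the radius trend ends below ``shrink_fraction`` of its start
    or reaches the vanish threshold; the sub-label comes from the sign
    structure of the smoothed shear trend (monotonic decrease / increase, or
    non-monotonic = a single interior maximum).  Stable: net radius drift
    below ``drift_fraction`` of the mean, orientation from the shoelace
    area.  Anything else — including too-short records — is unclassifiable.
    """
    cfg = config if config is not None else ClassifyConfig()
    times = np.asarray(times, dtype=float)
    a = np.asarray(a_trend, dtype=float)
    tau = np.asarray(tau_trend, dtype=float)
    if times.size < 8 or times[-1] - times[0] < cfg.min_duration_s:
        return TrajectoryClass(label="unclassifiable")

    shrinking = (a[-1] < cfg.shrink_fraction * a[0]) or \
        (a.min() <= cfg.a_min_um)
    if shrinking:
        maxima, changes = _interior_extrema(times, tau, cfg.smooth_window_s)
        if changes == 0:
            d = np.gradient(trend(times, tau, max(
                4 * float(np.median(np.diff(times))),
                (times[-1] - times[0]) / 10.0)), times)
            label = ("shrinking_monotonic_increase" if np.nanmean(d) > 0
                     else "shrinking_monotonic_decrease")
        elif maxima == 1 and changes == 1:
            label = "shrinking_nonmonotonic"
        else:
            return TrajectoryClass(label="unclassifiable")
        return TrajectoryClass(label=label)

    drift = abs(a[-1] - a[0])
    if drift < cfg.drift_fraction * a.mean():
        try:
            orient = loop_orientation(a, tau)
        except ValueError:
            orient = "none"
        return TrajectoryClass(label="stable", orientation=orient)
    return TrajectoryClass(label="unclassifiable")
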