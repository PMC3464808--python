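"""Maximum specific growth rate from plate-reader OD600 time series.

The estimator mirrors standard plate-reader practice for fast-sampling
anaerobic cultivation: blank-correct each reading, rescale to a 1 cm
pathlength, take the natural log, and slide a fixed-size window (20 points
at 3-min sampling = 1 h) along the series, fitting an ordinary
least-squares line in each window.  The maximum slope over all windows is
the maximum specific growth rate, muMax (h^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "preprocess",
    "fit_mu_max",
    "fit_growth_curve",
    "percent_reduction",
]


@dataclass
class GrowthCurve:
    """One well's OD600 trajectory.

    ``times`` in hours (strictly increasing), ``od`` dimensionless
    absorbance, ``blank`` the medium-only OD to subtract,
    ``pathlength_factor`` the multiplicative rescale to a 1 cm pathlength.
    """

    times: np.ndarray
    od: np.ndarray
    blank: float = 0.0
    pathlength_factor: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.size < 2:
            raise ValueError("times and od must be equal-length arrays of size >= 2")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pathlength_factor <= 0:
            raise ValueError("pathlength_factor must be > 0")


@dataclass(frozen=True)
class GrowthRateEstimate:
    mu_max: float            # h^-1
    window_start: float      # h
    window_end: float        # h
    stderr: float            # h^-1, OLS slope standard error in the best window
    n_points: int

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


def preprocess(curve: GrowthCurve, floor: float = 1e-4) -> np.ndarray:
    """Blank-correct, rescale to 1 cm, floor, and natural-log transform.

    Readings at or below zero after blank correction are clamped to
    ``floor`` rather than dropped, preserving window alignment.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    corrected = (curve.od - curve.blank) * curve.pathlength_factor
    clamped = np.maximum(corrected, floor)
    if np.all(clamped == floor):
        warnings.warn("all readings at the floor: no growth signal", stacklevel=2)
    return np.log(clamped)


def _sliding_slopes(y: np.ndarray, t: np.ndarray, w: int) -> np.ndarray:
    """OLS slope of y on t for every contiguous window of w points, O(n)."""
    one = np.ones_like(t)
    kernel = np.ones(w)
    s_t = np.convolve(t, kernel, "valid")
    s_y = np.convolve(y, kernel, "valid")
    s_tt = np.convolve(t * t, kernel, "valid")
    s_ty = np.convolve(t * y, kernel, "valid")
    sxx = s_tt - s_t * s_t / w
    sxy = s_ty - s_t * s_y / w
    return sxy / sxx


def fit_mu_max(
    log_track: np.ndarray,
    times: np.ndarray,
    window_points: int = 20,
    min_mean_od: float | None = None,
    od: np.ndarray | None = None,
) -> GrowthRateEstimate:
    """muMax as the maximal sliding-window OLS slope of log-OD vs time.

    The window advances one reading at a time; ties go to the earliest
    window.  ``min_mean_od`` (with the raw ``od`` array) optionally
    excludes windows whose mean OD is below a noise threshold; it is off
    by default.
    """
    y = np.asarray(log_track, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("log_track and times must have the same length")
    n = y.size
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    if window_points > n:
        raise ValueError(f"series of {n} points shorter than window {window_points}")
    slopes = _sliding_slopes(y, t, window_points)
    if min_mean_od is not None:
        if od is None:
            raise ValueError("min_mean_od requires the raw od array")
        mean_od = np.convolve(np.asarray(od, float), np.ones(window_points), "valid") / window_points
        slopes = np.where(mean_od >= min_mean_od, slopes, -np.inf)
        if not np.any(np.isfinite(slopes)):
            raise ValueError("no window passes the min_mean_od guard")
    best = int(np.argmax(slopes))  # argmax returns the earliest maximiser
    tw = t[best : best + window_points]
    yw = y[best : best + window_points]
    slope, intercept = np.polyfit(tw, yw, 1)
    resid = yw - (slope * tw + intercept)
    dof = window_points - 2
    sxx = np.sum((tw - tw.mean()) ** 2)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else 0.0
    return GrowthRateEstimate(
        mu_max=float(slopes[best]),
        window_start=float(tw[0]),
        window_end=float(tw[-1]),
        stderr=se,
        n_points=window_points,
    )


def fit_growth_curve(
    curve: GrowthCurve,
    window_points: int = 20,
    floor: float = 1e-4,
    min_mean_od: float | None = None,
) -> GrowthRateEstimate:
    """Convenience: preprocess then fit in one call."""
    y = preprocess(curve, floor=floor)
    return fit_mu_max(
        y, curve.times, window_points=window_points,
        min_mean_od=min_mean_od, od=curve.od,
    )


def percent_reduction(mu_mutant: float, mu_control: float) -> float:
    """Growth-rate cost of plasmid carriage, as a percentage of the control."""
    if mu_control <= 0:
        raise ValueError("control rate must be > 0")
    return 100.0 * (mu_control - mu_mutant) / mu_control
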