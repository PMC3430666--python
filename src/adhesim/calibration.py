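"""Virtual-to-real time calibration and segregation-law extrapolation.

The simulation's distance scale is 1 unit = 10 um, so squared
displacements are a factor 100 larger on a real-units MSD plot.  With
F = S_R / S_V the ratio of the observed (um^2/s) to the simulated
(unit^2/step) MSD slope, one virtual step corresponds to

    T_R / T_V = 100 / F   seconds per step.

Segregation growth over long runs follows a square-root law
S = m * sqrt(n) + k (n in thousands of steps); extrapolating the fitted
line to the score of an artificially split population predicts the time
to full segregation, and interpolating a replicate-mean score series to
an observed score yields the virtual time a live experiment corresponds
to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: factor (um per unit)^2 entering the time conversion
DISTANCE_SCALE_UM = 10.0
SQUARED_SCALE = DISTANCE_SCALE_UM**2

SECONDS_PER_HOUR = 3600.0


@dataclass
class TimeScale:
    """Mapping between virtual steps and real seconds."""

    F: float                       # observed / simulated MSD slope
    ratio_TR_per_TV: float         # seconds of real time per virtual step
    distance_scale: float = DISTANCE_SCALE_UM

    @property
    def ratio_rounded(self) -> int:
        """Display value, nearest whole second per step."""
        return int(round(self.ratio_TR_per_TV))


@dataclass
class SqrtLawFit:
    """Power-law and square-root fits of score vs run length.

    a, b, c parameterise S = a * n^b + c; m, k the linear refit
    S = m * sqrt(n) + k, with n in thousands of steps.
    """

    a: float
    b: float
    c: float
    m: float
    k: float


def time_scale(observed_slope: float, simulated_slope: float) -> TimeScale:
    """Seconds of real time per virtual step from the two MSD slopes.

    ``observed_slope`` is in um^2/s, ``simulated_slope`` in
    unit^2/step; F = observed/simulated and the ratio is 100/F.  The
    unrounded ratio is carried; rounding is display-only.
    """
    if observed_slope <= 0 or simulated_slope <= 0:
        raise ValueError("MSD slopes must be positive")
    F = observed_slope / simulated_slope
    return TimeScale(F=F, ratio_TR_per_TV=SQUARED_SCALE / F)


def to_real_time(virtual_steps: float, scale: TimeScale) -> float:
    """Real seconds corresponding to a number of virtual steps."""
    if virtual_steps < 0:
        raise ValueError("steps must be non-negative")
    return virtual_steps * scale.ratio_TR_per_TV


def to_hours(seconds: float) -> float:
    return seconds / SECONDS_PER_HOUR


def fit_sqrt_law(points, c_bound: float = 10.0) -> SqrtLawFit:
    """Fit S = a n^b + c and the linear law S = m sqrt(n) + k.

    ``points`` is a sequence of (n, S) with n in thousands of steps.
    The power law is fitted by nonlinear least squares from multiple
    exponent starts; the linear law by least squares on sqrt(n).  The
    offset is constrained to |c| <= c_bound (default 10, the scale of
    the random-mixture baseline): the unconstrained three-parameter
    family has a degenerate limit a n^b + c -> const + ab log(n) as
    b -> 0 with a, -c -> infinity, into which noisy or saturating
    score data otherwise collapses.  Pass c_bound=inf to disable.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or len(pts) < 4:
        raise ValueError("need at least 4 (n, S) points")
    n, S = pts[:, 0], pts[:, 1]
    if (n <= 0).any():
        raise ValueError("run lengths must be positive")
    if np.ptp(S) < 1e-12 or np.ptp(n) < 1e-12:
        raise ValueError("degenerate input: constant series cannot be fitted")
    root = np.sqrt(n)
    m, k = np.polyfit(root, S, 1)

    def law(x, a, b, c):
        return a * np.power(x, b) + c

    # multi-start over exponents: the (a, b, c) surface has shallow
    # valleys where c trades off against small b
    best = None
    k0 = float(np.clip(k, -c_bound, c_bound))
    for b0 in (0.3, 0.5, 0.8):
        try:
            popt, _ = curve_fit(
                law, n, S, p0=[max(m, 1e-3), b0, k0], maxfev=20_000,
                bounds=([1e-8, 0.01, -c_bound], [np.inf, 3.0, c_bound]))
        except (RuntimeError, ValueError):
            continue
        rss = float(((law(n, *popt) - S) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:  # pragma: no cover - pathological input
        raise ValueError("power-law fit failed on all starts")
    a, b, c = best[1]
    return SqrtLawFit(float(a), float(b), float(c), float(m), float(k))


def extrapolate_full_segregation(fit: SqrtLawFit, S_target: float) -> float:
    """Run length n (thousands of steps) at which the fitted line
    m sqrt(n) + k reaches ``S_target`` — the exact inverse of
    evaluating the law."""
    if fit.m <= 0:
        raise ValueError("square-root law slope must be positive")
    if S_target < fit.k:
        raise ValueError("target score below the fitted intercept")
    return ((S_target - fit.k) / fit.m) ** 2


def crossing_time(score_series, S_observed: float) -> float:
    """Virtual steps at which the replicate-mean score reaches an
    observed score, by linear interpolation of the series.

    ``score_series`` is a sequence of (n_steps, mean S) pairs.  Raises
    if ``S_observed`` lies outside the series' score range, with advice
    to extend the simulated bracket.
    """
    pts = np.asarray(list(score_series), dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 (n, S) points")
    order = np.argsort(pts[:, 0])
    n, S = pts[order, 0], pts[order, 1]
    lo, hi = S.min(), S.max()
    if not lo <= S_observed <= hi:
        raise ValueError(
            f"observed score {S_observed} outside simulated range "
            f"[{lo:.3g}, {hi:.3g}]; extend the run-length bracket")
    # interpolate on the (assumed monotone) mean curve
    return float(np.interp(S_observed, S, n))
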