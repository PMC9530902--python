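"""Growth rates from plate-reader OD time series.

The estimator is windowed log-linear fitting: least-squares lines on
ln(OD) over every contiguous window of fixed length. Windows qualify when
their fit is clean (r^2 gate, absolute ln-residual gate) and their signal
sits above the reader's noise floor (estimated from the flattest stretch of
the same curve on the OD scale). Because the local log-slope of a logistic
culture declines linearly with density, mu(1 - OD/K), the growth rate is
read off as the zero-density intercept of the qualifying window slopes
regressed on window mean density (density-weighted); when too few windows
qualify to support that regression the maximal qualifying slope is used
directly. On an exact exponential every window carries the same slope and
both routes return it to machine precision.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import GrowthCurve, GrowthFit, QualityError

DEFAULT_WINDOW = 5
DEFAULT_R2_GATE = 0.95
#: Maximum RMS of ln(OD) residuals for a window to count as clean growth.
DEFAULT_MAX_RMS = 0.05
#: A window's mean OD must exceed this multiple of the noise floor.
DEFAULT_SNR_FLOOR = 10.0
DEFAULT_OD_FLOOR = 1e-3


def preprocess_curve(
    curve: GrowthCurve, blank_od: float = 0.0, floor: float = DEFAULT_OD_FLOOR
) -> GrowthCurve:
    """Blank-correct a curve and clamp to a positive floor so logs exist."""
    if blank_od < 0:
        raise ValueError("blank_od must be >= 0")
    od = np.maximum(curve.od - blank_od, floor)
    if od.size < 5:
        raise QualityError("fewer than 5 usable points after preprocessing")
    return GrowthCurve(curve.well_id, curve.times, od)


def _window_fits(t: np.ndarray, y: np.ndarray, w: int):
    """Vectorized least-squares over all contiguous windows of length w.

    Returns (slopes, r2, rms) with one entry per window start.
    """
    T = sliding_window_view(t, w)
    Y = sliding_window_view(y, w)
    t_mean = T.mean(axis=1)
    y_mean = Y.mean(axis=1)
    t_c = T - t_mean[:, None]
    y_c = Y - y_mean[:, None]
    sxx = (t_c**2).sum(axis=1)
    sxy = (t_c * y_c).sum(axis=1)
    syy = (y_c**2).sum(axis=1)
    slopes = sxy / sxx
    ss_res = np.maximum(syy - sxy**2 / sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, 1.0 - ss_res / syy, 1.0)
    rms = np.sqrt(ss_res / w)
    return slopes, r2, rms


def growth_rate(
    curve: GrowthCurve,
    window_points: int = DEFAULT_WINDOW,
    r2_gate: float = DEFAULT_R2_GATE,
    max_rms: float = DEFAULT_MAX_RMS,
    snr_floor: float = DEFAULT_SNR_FLOOR,
) -> GrowthFit:
    """Estimate one curve's growth rate (h^-1) from its qualifying windows.

    Qualifying windows have ln-linear r^2 >= r2_gate, ln-residual RMS <=
    max_rms, and mean OD >= snr_floor times the curve's read-noise floor.
    With three or more qualifying windows spanning a density range, the
    rate is the density-weighted zero-density intercept of slope vs mean
    OD; otherwise it is the maximal qualifying slope. A perfectly flat
    curve has rate 0 by convention.
    """
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    n = curve.times.size
    if window_points > n:
        raise ValueError(f"window_points={window_points} exceeds curve length {n}")
    t = curve.times
    od = curve.od
    log_od = np.log(od)
    if np.allclose(log_od, log_od[0]):
        return GrowthFit(rate=0.0, window=(0, n - 1), r2=1.0)

    # noise floor: smallest OD-scale window residual (flattest stretch)
    _, _, od_rms = _window_fits(t, od, window_points)
    od_min = snr_floor * float(od_rms.min())

    slopes, r2, rms = _window_fits(t, log_od, window_points)
    density = sliding_window_view(od, window_points).mean(axis=1)
    ok = (density >= od_min) & (r2 >= r2_gate) & (rms <= max_rms)
    if not ok.any():
        raise QualityError(
            f"no window of {window_points} points qualified "
            f"(best r2 = {r2.max():.4f})"
        )

    best_idx = int(np.flatnonzero(ok)[np.argmax(slopes[ok])])
    rate = float(slopes[best_idx])
    d_ok, s_ok = density[ok], slopes[ok]
    if d_ok.size >= 3 and np.ptp(d_ok) > 0.1 * d_ok.max():
        # local log-slope of a logistic falls linearly with density:
        # extrapolate to zero density, weighting by density^2 (the ln-OD
        # noise variance scales as 1/OD^2)
        weights = d_ok**2
        X = np.column_stack([np.ones_like(d_ok), d_ok])
        beta = np.linalg.solve(
            (X * weights[:, None]).T @ X, (X * weights[:, None]).T @ s_ok
        )
        rate = float(beta[0])
    return GrowthFit(
        rate=max(rate, 0.0),
        window=(best_idx, best_idx + window_points - 1),
        r2=float(r2[best_idx]),
    )


def aggregate_replicates(fits: Sequence[GrowthFit]) -> GrowthFit:
    """Mean rate and SE over replicate wells."""
    if len(fits) == 0:
        raise QualityError("no growth fits to aggregate (all wells filtered?)")
    rates = np.array([f.rate for f in fits])
    se = (
        float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
    )
    best = max(fits, key=lambda f: f.r2)
    return GrowthFit(
        rate=float(rates.mean()),
        window=best.window,
        r2=best.r2,
        se=se,
        n_replicates=len(fits),
    )


def rate_from_curves(
    curves: Sequence[GrowthCurve],
    blank_od: float = 0.0,
    window_points: int = DEFAULT_WINDOW,
    r2_gate: float = DEFAULT_R2_GATE,
) -> GrowthFit:
    """Preprocess, fit, and aggregate a set of replicate wells.

    Wells with no qualifying window are dropped; if every well fails, the
    quality error propagates.
    """
    fits = []
    last_err: QualityError | None = None
    for curve in curves:
        try:
            fits.append(
                growth_rate(
                    preprocess_curve(curve, blank_od), window_points, r2_gate
                )
            )
        except QualityError as err:
            last_err = err
    if not fits:
        raise last_err if last_err is not None else QualityError("no curves")
    return aggregate_replicates(fits)
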