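"""MSD analysis and anomalous-diffusion fitting for 1D motion on DNA.

The mean squared displacement uses overlapping displacements,

    MSD(n*dt) = 1/(N-n) * sum_{i=1}^{N-n} (x_{i+n} - x_i)^2 ,

and is fitted with the anomalous-diffusion model ``2*D*(n*dt)**alpha + y``.
The "linear portion" of the curve is selected automatically: among initial
lag windows covering at least 10% of the curve, the fit maximizing R^2 is
kept (longest window wins ties).  Fits with R^2 < 0.8 or using < 10% of the
curve are rejected; tracks shorter than 1 s are fitted with alpha fixed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidInputError

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "compute_msd",
    "fit_diffusion",
    "classify_motile",
    "geometric_mean_D",
]

#: default localization-jitter noise floor for motility calls, µm²/s
DEFAULT_NOISE_FLOOR_D = 0.005


@dataclass
class MSDCurve:
    """MSD at integer frame lags 1..N-1."""

    lags: np.ndarray       # lag steps n
    lag_times: np.ndarray  # n * dt, s
    msd: np.ndarray        # µm²


@dataclass
class DiffusionFit:
    """Result of fitting 2D(nΔt)^α + y to an MSD curve."""

    D: float               # µm²/s
    alpha: float
    intercept: float       # µm²
    r_squared: float
    fraction_used: float   # of the MSD curve's lags
    accepted: bool
    alpha_fixed: bool = False


def compute_msd(positions, dt: float) -> MSDCurve:
    """Exact overlapping-displacement MSD for every lag n in 1..N-1."""
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least 2 positions")
    n_frames = x.size
    lags = np.arange(1, n_frames)
    msd = np.empty(lags.size)
    for j, n in enumerate(lags):
        diff = x[n:] - x[:-n]
        msd[j] = np.mean(diff * diff)
    return MSDCurve(lags=lags, lag_times=lags * dt, msd=msd)


def _fit_window(t, y, fix_alpha: bool):
    if fix_alpha:
        # linear model 2*D*t + y0
        A = np.vstack([2.0 * t, np.ones_like(t)]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        D, y0, alpha = coef[0], coef[1], 1.0
        pred = A @ coef
    else:
        def model(tt, D, alpha, y0):
            return 2.0 * D * tt**alpha + y0
        p0 = (max((y[-1] - y[0]) / (2 * (t[-1] - t[0] + 1e-12)), 1e-6), 1.0, y[0])
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=([0, 0.05, -np.inf], [np.inf, 2.0, np.inf]),
            maxfev=20000,
        )
        D, alpha, y0 = popt
        pred = model(t, *popt)
    rss = float(((y - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss if tss > 0 else -np.inf
    return float(D), float(alpha), float(y0), r2


def fit_diffusion(
    msd: MSDCurve,
    track_duration: float | None = None,
    min_fraction: float = 0.1,
    min_r_squared: float = 0.8,
    short_track_cutoff: float = 1.0,
) -> DiffusionFit:
    """Fit the anomalous-diffusion model to the initial portion of an MSD curve.

    The initial window end is scanned over all lengths covering at least
    ``min_fraction`` of the lags (and >= 3 points); the window maximizing R^2
    is kept.  For tracks shorter than ``short_track_cutoff`` s the anomalous
    exponent is fixed at 1.  ``accepted`` reflects the R^2/fraction filter;
    non-convergence yields a rejected fit, never an exception.
    """
    t, y = msd.lag_times, msd.msd
    if t.size < 3:
        return DiffusionFit(0.0, 1.0, 0.0, np.nan, 0.0, accepted=False)
    fix_alpha = track_duration is not None and track_duration < short_track_cutoff
    n_min = max(3, int(np.ceil(min_fraction * t.size)))
    # candidate window ends on a geometric grid (caps the number of refits)
    ends = np.unique(np.geomspace(n_min, t.size, num=24).round().astype(int))
    best = None
    for n_use in ends:
        try:
            D, alpha, y0, r2 = _fit_window(t[:n_use], y[:n_use], fix_alpha)
        except (RuntimeError, ValueError):
            continue
        frac = n_use / t.size
        # prefer higher R^2; on near-ties (<0.1%) prefer the longer window
        if best is None or r2 > best[3] + 1e-3:
            best = (D, alpha, y0, r2, frac)
        elif abs(r2 - best[3]) <= 1e-3 and frac > best[4]:
            best = (D, alpha, y0, r2, frac)
    if best is None:
        return DiffusionFit(0.0, 1.0, 0.0, np.nan, 0.0, accepted=False,
                            alpha_fixed=fix_alpha)
    D, alpha, y0, r2, frac = best
    accepted = bool(r2 >= min_r_squared and frac >= min_fraction and D >= 0)
    return DiffusionFit(D=max(D, 0.0), alpha=alpha, intercept=y0, r_squared=r2,
                        fraction_used=frac, accepted=accepted, alpha_fixed=fix_alpha)


def classify_motile(fit: DiffusionFit,
                    noise_floor_D: float = DEFAULT_NOISE_FLOOR_D) -> str:
    """``"motile"`` iff the fit passed the quality filter and D exceeds the
    localization-jitter noise floor; otherwise ``"nonmotile"``."""
    return "motile" if (fit.accepted and fit.D > noise_floor_D) else "nonmotile"


def geometric_mean_D(values) -> float:
    """exp(mean(log D)); all values must be positive."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise InvalidInputError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(v))))
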