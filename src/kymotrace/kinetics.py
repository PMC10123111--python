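"""Dwell-time kinetics.

The workhorse is the cumulative residence time distribution (CRTD): the count
of binding events with dwell >= t, evaluated at every distinct observed dwell.
An exponential-mixture survival model

    CRTD(t) = N * sum_i f_i * exp(-t / tau_i),    sum_i f_i = 1

is fitted by unweighted nonlinear least squares with multi-start
initialization; model order (1-3 components) is chosen by BIC.  Apparent
lifetimes shortened by photobleaching are corrected per component by rate
subtraction, 1/tau_c = 1/tau_obs - 1/tau_b, then averaged with the fitted
fractions as weights.  The photobleach lifetime tau_b itself is estimated by
binning total photon counts from immobilized fluorophores into 1 s intervals
and fitting a single-exponential decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import (
    FitFailureError,
    InvalidCorrectionError,
    InvalidInputError,
    InvalidParameterError,
)
from .io import Kymograph

__all__ = [
    "CRTD",
    "ExponentialFit",
    "PhotobleachModel",
    "build_crtd",
    "fit_exponentials",
    "fit_dwells_mle",
    "select_model",
    "weighted_average_lifetime",
    "estimate_photobleach",
    "correct_lifetime",
    "correct_fit",
    "event_rate",
    "estimate_kd",
]


@dataclass
class CRTD:
    """Cumulative residence time distribution: counts of dwells >= t."""

    t: np.ndarray       # thresholds, s, ascending
    counts: np.ndarray  # events with duration >= t

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("thresholds must be strictly ascending")
        if np.any(np.diff(self.counts) > 0):
            raise InvalidInputError("counts must be non-increasing in t")


@dataclass
class ExponentialFit:
    """A 1-3 component exponential-mixture fit to a CRTD.

    Lifetimes are reported ascending; fractions sum to 1.
    """

    n_components: int
    lifetimes: np.ndarray            # s, ascending
    fractions: np.ndarray
    amplitude: float                 # total N at t=0
    stderr_lifetimes: np.ndarray = field(default_factory=lambda: np.empty(0))
    stderr_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))
    r_squared: float = np.nan
    bic: float = np.nan
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.sum(
            self.fractions[:, None] * np.exp(-t[None, :] / self.lifetimes[:, None]),
            axis=0,
        )

    @property
    def weighted_average(self) -> float:
        return weighted_average_lifetime(list(zip(self.lifetimes, self.fractions)))


@dataclass
class PhotobleachModel:
    """Single-exponential photobleaching decay under a stated exposure scheme."""

    label: str
    lifetime: float   # s of wall time under the measured scheme
    r_squared: float


def build_crtd(durations) -> CRTD:
    """CRTD(t) = #{d_i >= t} evaluated at each distinct duration."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise InvalidInputError("no durations")
    t = np.unique(d)
    # count of dwells >= each threshold
    counts = d.size - np.searchsorted(np.sort(d), t, side="left")
    return CRTD(t=t, counts=counts.astype(float))


def _model(t, amps, taus):
    return np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)


def _fit_once(t, y, amps0, taus0):
    k = len(taus0)
    x0 = np.log(np.concatenate([amps0, taus0]))

    def resid(x):
        amps, taus = np.exp(x[:k]), np.exp(x[k:])
        return _model(t, amps, taus) - y

    sol = least_squares(resid, x0, method="lm", max_nfev=20000)
    return sol


def fit_exponentials(crtd: CRTD, n_components: int) -> ExponentialFit:
    """Nonlinear least squares of ``N * sum_i f_i exp(-t/tau_i)`` to the CRTD.

    Uses several starting lifetime spreads and keeps the best solution;
    parameter standard errors come from the Gauss-Newton covariance of the
    fit, propagated from the internal log parameterization.
    """
    k = int(n_components)
    if k not in (1, 2, 3):
        raise InvalidParameterError("n_components must be 1, 2 or 3")
    t, y = crtd.t, crtd.counts
    if t.size < 5 * k:
        raise InvalidInputError(
            f"need >= {5 * k} distinct thresholds for {k} components, have {t.size}"
        )
    n_total = y.max()
    tmin = max(t[t > 0].min() if np.any(t > 0) else 0.01, 1e-3)
    tmax = max(t.max(), 2 * tmin)
    mean_d = max(np.trapezoid(y, t) / n_total if t.size > 1 else tmin, tmin)

    starts: list[np.ndarray] = []
    if k == 1:
        starts = [np.array([mean_d]), np.array([tmax / 3]), np.array([tmin * 3])]
    else:
        spreads = [
            np.geomspace(tmin * 2, tmax / 2, k),
            np.geomspace(mean_d / 5, mean_d * 5, k),
            np.geomspace(tmin * 5, tmax, k),
        ]
        starts = [np.asarray(s) for s in spreads]

    best = None
    for taus0 in starts:
        amps0 = np.full(k, n_total / k)
        try:
            sol = _fit_once(t, y, amps0, taus0)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("exponential fit did not converge",
                              best_residual=None if best is None else float(best.cost))

    amps, taus = np.exp(best.x[:k]), np.exp(best.x[k:])
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    N = amps.sum()
    fracs = amps / N
    resid = _model(t, amps, taus) - y
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    n = t.size
    bic = n * np.log(max(rss, 1e-300) / n) + (2 * k) * np.log(n)

    # covariance in log space -> delta method for taus and fractions
    try:
        J = best.jac
        dof = max(n - 2 * k, 1)
        cov_log = np.linalg.pinv(J.T @ J) * (rss / dof)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
        se_log_amp, se_log_tau = se_log[:k][order], se_log[k:][order]
        se_tau = taus * se_log_tau
        se_frac = fracs * se_log_amp  # first-order, ignores amp covariance
    except Exception:
        se_tau = np.full(k, np.nan)
        se_frac = np.full(k, np.nan)

    return ExponentialFit(
        n_components=k, lifetimes=taus, fractions=fracs, amplitude=float(N),
        stderr_lifetimes=se_tau, stderr_fractions=se_frac,
        r_squared=r2, bic=float(bic), residuals=resid,
    )


def fit_dwells_mle(durations, n_components: int, max_iter: int = 500,
                   tol: float = 1e-10, seed: int = 0) -> ExponentialFit:
    """Maximum-likelihood exponential-mixture fit of raw dwell times (EM).

    Alternative to least-squares CRTD fitting; same return type (amplitude is
    the event count, BIC computed from the log-likelihood).
    """
    d = np.asarray(durations, dtype=float)
    k = int(n_components)
    if d.size < 2 * k:
        raise InvalidInputError("too few dwells")
    rng = np.random.default_rng(seed)
    q = np.quantile(d, np.linspace(0.25, 0.9, k))
    taus = np.maximum(q * (1 + 0.1 * rng.standard_normal(k)), 1e-6)
    fracs = np.full(k, 1.0 / k)
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = fracs[:, None] / taus[:, None] * np.exp(-d[None, :] / taus[:, None])
        tot = dens.sum(axis=0)
        ll = float(np.log(np.clip(tot, 1e-300, None)).sum())
        resp = dens / np.clip(tot, 1e-300, None)
        w = resp.sum(axis=1)
        fracs = w / d.size
        taus = np.maximum((resp @ d) / np.clip(w, 1e-300, None), 1e-9)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    order = np.argsort(taus)
    bic = -2 * ll + (2 * k - 1) * np.log(d.size)
    return ExponentialFit(
        n_components=k, lifetimes=taus[order], fractions=fracs[order],
        amplitude=float(d.size), bic=float(bic),
    )


def select_model(crtd: CRTD, max_components: int = 3) -> ExponentialFit:
    """Fit 1..3 components and return the lowest-BIC model.

    Ties break toward fewer components, and a richer model is only accepted
    when it is both strongly favored (ΔBIC > 10 — CRTD points are cumulative
    and hence correlated, so the nominal BIC overstates evidence) and
    non-redundant (every fraction at least 10%, lifetimes separated by at
    least a factor of 3).  Component counts needing more distinct thresholds
    than the CRTD has (5 per component) are skipped.
    """
    fits: list[ExponentialFit] = []
    for k in range(1, max_components + 1):
        if crtd.t.size < 5 * k:
            break
        try:
            fits.append(fit_exponentials(crtd, k))
        except FitFailureError:
            continue
    if not fits:
        raise FitFailureError("no component count could be fitted")
    best = fits[0]
    for f in fits[1:]:
        redundant = np.any(f.fractions < 0.10) or np.any(
            f.lifetimes[1:] / f.lifetimes[:-1] < 3.0
        )
        if not redundant and f.bic < best.bic - 10.0:
            best = f
    return best


def weighted_average_lifetime(components) -> float:
    """Fraction-weighted average lifetime, ``sum_i f_i * tau_i``.

    Printed percentages are typically rounded, so fractions may sum to
    1 ± 0.02.  The result is reported at full precision; round to one decimal
    for tables.
    """
    taus = np.array([t for t, _ in components], dtype=float)
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(taus < 0) or np.any(fracs < 0):
        raise InvalidParameterError("lifetimes and fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 0.02:
        raise InvalidParameterError(f"fractions sum to {fracs.sum():.3f}, not 1")
    return float(np.sum(taus * fracs))


def estimate_photobleach(
    kymo: Kymograph,
    channel: int = 0,
    bin_width: float = 1.0,
    label: str = "",
    max_lifetime: float = 1e4,
) -> PhotobleachModel:
    """Photobleaching lifetime from a kymograph of immobilized fluorophores.

    Total photon counts are binned into ``bin_width`` s intervals and fitted
    to ``A * exp(-t/tau_b) + C``.  Requires at least 10 bins; a flat or
    increasing trend (tau_b <= 0 or beyond ``max_lifetime``) raises
    :class:`FitFailureError`.
    """
    frames_per_bin = max(1, int(round(bin_width / kymo.line_time)))
    per_line = kymo.counts[channel].sum(axis=1).astype(float)
    n_bins = per_line.size // frames_per_bin
    if n_bins < 10:
        raise InvalidInputError(f"need >= 10 bins of {bin_width} s, have {n_bins}")
    binned = per_line[: n_bins * frames_per_bin].reshape(n_bins, frames_per_bin).sum(axis=1)
    t = (np.arange(n_bins) + 0.5) * frames_per_bin * kymo.line_time

    a0 = max(binned[0] - binned[-1], 1.0)
    tau0 = max(t[-1] / 3.0, bin_width)
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t, binned, p0=(a0, tau0, max(binned[-1], 0.0)),
            # the offset is physical background and cannot be negative
            bounds=([0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"photobleach fit failed: {exc}") from exc
    a, tau, c = popt
    pred = a * np.exp(-t / tau) + c
    rss = float(((binned - pred) ** 2).sum())
    tss = float(((binned - binned.mean()) ** 2).sum())
    r2 = 1 - rss / tss if tss > 0 else np.nan
    # demand a decay amplitude clearly above shot noise of the binned counts
    noise_sd = np.sqrt(max(binned.mean(), 1.0))
    if tau <= 0 or tau > max_lifetime or a <= 3.0 * noise_sd:
        raise FitFailureError(
            f"no photobleaching decay detected (tau={tau:.3g} s)", best_residual=rss
        )
    return PhotobleachModel(label=label or kymo.channel_names[channel],
                            lifetime=float(tau), r_squared=r2)


def correct_lifetime(tau_obs: float, tau_bleach: float) -> float:
    """Remove the photobleaching contribution from an observed lifetime.

    The observed off-rate is the sum of the true dissociation rate and the
    bleach rate, so ``1/tau_c = 1/tau_obs - 1/tau_bleach``.  Requires
    ``tau_bleach > tau_obs``; equality or worse means the streak lengths are
    bleaching-dominated and the true lifetime is unidentifiable.
    """
    if tau_obs <= 0:
        raise InvalidParameterError("tau_obs must be positive")
    if np.isinf(tau_bleach):
        return float(tau_obs)
    if tau_bleach <= tau_obs:
        raise InvalidCorrectionError(
            f"tau_bleach ({tau_bleach} s) must exceed tau_obs ({tau_obs} s)"
        )
    return 1.0 / (1.0 / tau_obs - 1.0 / tau_bleach)


def correct_fit(fit: ExponentialFit, tau_bleach: float) -> ExponentialFit:
    """Apply :func:`correct_lifetime` per component, keeping the fractions."""
    taus = np.array([correct_lifetime(t, tau_bleach) for t in fit.lifetimes])
    return ExponentialFit(
        n_components=fit.n_components, lifetimes=taus,
        fractions=fit.fractions.copy(), amplitude=fit.amplitude,
        r_squared=fit.r_squared, bic=fit.bic,
    )


def event_rate(tracks, observation_time: float) -> float:
    """Curated binding events per second of observation."""
    if observation_time <= 0:
        raise InvalidParameterError("observation_time must be positive")
    return len(tracks) / observation_time


def estimate_kd(koff: float, kon: float) -> float:
    """Equilibrium dissociation constant K_d = k_off / k_on (in M when
    ``koff`` is 1/s and ``kon`` is 1/(M·s))."""
    if koff <= 0 or kon <= 0:
        raise InvalidParameterError("rates must be positive")
    return koff / kon
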