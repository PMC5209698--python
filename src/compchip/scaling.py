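"""Per-locus sigmoid fitting and scaling to kinetic boundary conditions.

Each locus's normalized ratio time course is fit with a Hill-like sigmoid
plus an additive constant,

    value(t) = B + amplitude * t^n / (t^n + t0^n),

where B is the locus-specific differential background between the two tags
at t = 0, the amplitude is the fitted asymptote above B, and t0 (the
response time) is the half-rise time — approximately the protein induction
time plus the in-vivo residence time.  Subtracting B and multiplying by
alpha = rho_inf / amplitude (the relative antibody affinity) maps the series
onto the in-vivo occupancy ratio theta_B/theta_A, which the kinetic model
requires to start at 0 and saturate at rho_inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .series import LocusSeries, ScaledLocusSeries

logger = logging.getLogger(__name__)

__all__ = [
    "LocusScalingFit",
    "fit_locus_sigmoid",
    "scale_series",
    "t0_percent_error",
    "reliability_filter",
]

#: Response-time resolution limit (min): below this the separation between
#: the locus response and the induction curve is within the data noise and
#: kinetic fits become unstable.
DEFAULT_T0_MIN = 24.5


@dataclass
class LocusScalingFit:
    """Sigmoid-plus-background fit of one locus series."""

    locus_id: str
    B: float
    amplitude: float
    t0: float
    t0_se: float
    alpha: float
    rss: float
    converged: bool
    n_points: int
    hill_n: int = 4
    noise_sd: float = float("nan")


def _sigmoid(t, B, amplitude, t0, n):
    x = (np.asarray(t, dtype=float) / t0) ** n
    return B + amplitude * x / (x + 1.0)


def fit_locus_sigmoid(
    series: LocusSeries,
    hill_n: int = 4,
    rho_inf: float = 1.0,
    t0_bounds: tuple[float, float] = (1.0, 500.0),
) -> LocusScalingFit:
    """Least-squares fit of B + amplitude * t^n/(t^n + t0^n) to a locus series.

    ``rho_inf`` is the global induction saturation used to compute the scale
    factor alpha = rho_inf / amplitude.  Non-convergence or a non-positive
    amplitude yields a flagged (converged=False) result, not an exception.
    The t0 standard error comes from the fit covariance; ``noise_sd`` is the
    residual standard deviation (rss / (n - 3) degrees of freedom).
    """
    t, v = series.times, series.values
    if len(t) < 5 or t[0] != 0.0:
        raise ValueError("need >= 5 time points including t = 0")

    B0 = float(v[0])
    A0 = max(float(np.max(v)) - B0, 1e-6)
    half = B0 + 0.5 * A0
    above = np.nonzero(v >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        frac = (half - v[i - 1]) / (v[i] - v[i - 1]) if v[i] != v[i - 1] else 0.0
        t0_start = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    else:
        t0_start = float(np.median(t[t > 0])) if np.any(t > 0) else 10.0
    t0_start = float(np.clip(t0_start, *t0_bounds))

    def model(tt, B, A, t0):
        return _sigmoid(tt, B, A, t0, hill_n)

    try:
        popt, pcov = curve_fit(
            model, t, v, p0=[B0, A0, t0_start],
            bounds=([-np.inf, -np.inf, t0_bounds[0]], [np.inf, np.inf, t0_bounds[1]]),
            maxfev=10000,
        )
        B, A, t0 = (float(p) for p in popt)
        t0_se = float(np.sqrt(pcov[2, 2]))
        resid = v - model(t, *popt)
        rss = float(np.sum(resid ** 2))
        dof = max(len(t) - 3, 1)
        noise_sd = float(np.sqrt(rss / dof))
        converged = np.isfinite([B, A, t0]).all() and A > 0
    except (RuntimeError, ValueError) as err:
        logger.warning("sigmoid fit failed at locus %s: %s", series.locus_id, err)
        return LocusScalingFit(series.locus_id, np.nan, np.nan, np.nan, np.nan,
                               np.nan, np.nan, False, len(t), hill_n)
    alpha = rho_inf / A if A > 0 else np.nan
    return LocusScalingFit(series.locus_id, B, A, t0, t0_se, alpha, rss,
                           bool(converged), len(t), hill_n, noise_sd)


def scale_series(
    series: LocusSeries,
    fit: LocusScalingFit,
    rho_inf: float,
) -> ScaledLocusSeries:
    """Map a locus series onto the in-vivo occupancy ratio scale.

    values' = alpha * (value - B) with alpha = rho_inf / amplitude, so the
    fitted asymptote becomes rho_inf and the fitted t = 0 value becomes 0.
    Raises on an unconverged or non-positive-amplitude fit (the caller
    excludes and logs such loci).  A scaled t = 0 value more than 3
    fitted-noise SDs from 0 clears ``boundary_ok``.
    """
    if not fit.converged or not fit.amplitude > 0:
        raise ValueError(f"locus {series.locus_id}: unusable fit; excluded")
    alpha = rho_inf / fit.amplitude
    values = alpha * (series.values - fit.B)
    tol = 3.0 * alpha * fit.noise_sd if np.isfinite(fit.noise_sd) else 0.0
    boundary_ok = bool(abs(values[0]) <= max(tol, 1e-8))
    if not boundary_ok:
        logger.warning("locus %s: scaled t=0 value %.3g violates the zero boundary",
                       series.locus_id, values[0])
    return ScaledLocusSeries(
        locus_id=series.locus_id, times=series.times.copy(), values=values,
        boundary_ok=boundary_ok,
        meta={"alpha": alpha, "B": fit.B, "t0": fit.t0},
    )


def t0_percent_error(fit: LocusScalingFit) -> float:
    """Percent error in the response time: 100 * se(t0) / t0."""
    if not fit.t0 > 0:
        raise ValueError("t0 must be > 0")
    return 100.0 * fit.t0_se / fit.t0


def reliability_filter(
    fit: LocusScalingFit,
    t0_min: float = DEFAULT_T0_MIN,
    max_relative_rss: float = 0.003,
    max_pct_err: float = 50.0,
    rho_inf: float = 2.23,
) -> tuple[bool, list[str]]:
    """Noise criteria deciding whether a locus supports a kinetic fit.

    Passes only when the fit converged, t0 >= ``t0_min`` (the resolution
    limit below which kinetic fits are unstable), the relative residual
    rss / (n * rho_inf^2) is small, and the t0 percent error is bounded.
    Returns (passes, failure reasons).
    """
    reasons: list[str] = []
    if not fit.converged:
        reasons.append("fit did not converge")
        return False, reasons
    if fit.t0 < t0_min:
        reasons.append("t0 below resolution threshold")
    rel_rss = fit.rss / (fit.n_points * rho_inf ** 2)
    if rel_rss > max_relative_rss:
        reasons.append("relative rss above threshold")
    if t0_percent_error(fit) > max_pct_err:
        reasons.append("t0 percent error above threshold")
    return len(reasons) == 0, reasons
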