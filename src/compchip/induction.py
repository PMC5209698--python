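"""Hill-form model of competitor induction.

In a competition ChIP experiment an alternatively tagged copy of the
transcription factor is induced at t = 0 and competes with the constitutively
expressed endogenous copy for chromatin binding.  The soluble concentration
ratio of competitor to endogenous protein,

    rho(t) = C_B(t) / C_A = rho_inf * t^n / (t^n + t_ind^n),

is measured independently (Western blots) and drives the kinetic model.  The
parameterization makes ``t_ind`` exactly the half-saturation time: the curve
is zero at the origin, sigmoidal (positive then negative curvature for
n > 1), and saturates at ``rho_inf``.  The Hill exponent ``n`` is held fixed
when fitting; for the TBP competition design used throughout, n = 4 and the
fitted constants are rho_inf = 2.23 and t_ind = 22 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "InductionCurve",
    "InductionFitError",
    "DEFAULT_INDUCTION",
    "eval_induction",
    "fit_induction",
    "read_induction_table",
    "write_induction_table",
]


class InductionFitError(RuntimeError):
    """Raised when the induction-curve fit fails to converge."""


@dataclass(frozen=True)
class InductionCurve:
    """Hill-form competitor/endogenous concentration ratio.

    Parameters
    ----------
    rho_inf : float
        Saturation value of the concentration ratio (dimensionless, > 0).
    t_ind : float
        Induction time in minutes: the time at which the ratio reaches half
        of ``rho_inf`` (> 0).
    hill_n : int
        Hill exponent (>= 1); fixed, not fitted.
    rho_inf_se, t_ind_se : float, optional
        Per-parameter standard errors from a fit, NaN when not fitted.
    """

    rho_inf: float
    t_ind: float
    hill_n: int = 4
    rho_inf_se: float = float("nan")
    t_ind_se: float = float("nan")

    def __post_init__(self) -> None:
        if not self.rho_inf > 0:
            raise ValueError(f"rho_inf must be > 0, got {self.rho_inf}")
        if not self.t_ind > 0:
            raise ValueError(f"t_ind must be > 0, got {self.t_ind}")
        if self.hill_n < 1 or int(self.hill_n) != self.hill_n:
            raise ValueError(f"hill_n must be an integer >= 1, got {self.hill_n}")

    def __call__(self, t):
        return eval_induction(self, t)


#: Fitted induction constants for the TBP competition design (half-saturation
#: at 22 min, saturation ratio 2.23, Hill exponent 4).
DEFAULT_INDUCTION = InductionCurve(rho_inf=2.23, t_ind=22.0, hill_n=4)


def eval_induction(curve: InductionCurve, t):
    """Evaluate rho(t) = rho_inf * t^n / (t^n + t_ind^n).

    ``t`` may be a scalar or array of times in minutes; all must be >= 0.
    Returns values in [0, rho_inf) with rho(0) = 0 and
    rho(t_ind) = rho_inf / 2 exactly.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("induction times must be >= 0")
    # (t/t_ind)^n avoids overflow for large t and keeps rho(t_ind) exact
    x = (t / curve.t_ind) ** curve.hill_n
    out = curve.rho_inf * x / (x + 1.0)
    return float(out) if out.ndim == 0 else out


def fit_induction(
    times,
    ratios,
    hill_n: int = 4,
    max_restarts: int = 5,
) -> InductionCurve:
    """Least-squares fit of (rho_inf, t_ind) to measured concentration ratios.

    The Hill exponent is held fixed.  Starting values are analytic:
    rho_inf0 = max observed ratio, t_ind0 = first time the ratio crosses
    rho_inf0/2 by linear interpolation.  On non-convergence the fit is
    restarted from perturbed starts up to ``max_restarts`` times before
    raising :class:`InductionFitError`.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("times and ratios must be 1-D arrays of equal length")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(r)):
        raise ValueError("times and ratios must be finite")
    if np.any(r < 0):
        raise ValueError("ratios must be nonnegative")
    if len(np.unique(t)) < 4:
        raise ValueError("need >= 4 distinct time points to fit 2 parameters")

    def model(tt, rho_inf, t_ind):
        x = (np.asarray(tt) / t_ind) ** hill_n
        return rho_inf * x / (x + 1.0)

    rho0 = float(np.max(r))
    if rho0 <= 0:
        raise ValueError("all ratios are zero; nothing to fit")
    t0 = _half_crossing_time(t, r, rho0 / 2.0)

    rng = np.random.default_rng(0)
    start = np.array([rho0, t0])
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        try:
            popt, pcov = curve_fit(
                model, t, r, p0=start,
                bounds=([1e-12, 1e-6], [np.inf, np.inf]),
                maxfev=10000,
            )
            se = np.sqrt(np.diag(pcov))
            return InductionCurve(
                rho_inf=float(popt[0]), t_ind=float(popt[1]), hill_n=hill_n,
                rho_inf_se=float(se[0]), t_ind_se=float(se[1]),
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            start = np.array([rho0, t0]) * rng.lognormal(0.0, 0.3, size=2)
    raise InductionFitError(
        f"induction fit failed after {max_restarts + 1} attempts: {last_err}"
    )


def _half_crossing_time(t, r, half: float) -> float:
    """First time the series crosses ``half``, by linear interpolation."""
    order = np.argsort(t)
    ts, rs = t[order], r[order]
    above = np.nonzero(rs >= half)[0]
    if len(above) == 0:
        return float(ts[-1]) if ts[-1] > 0 else 1.0
    i = above[0]
    if i == 0 or rs[i] == rs[i - 1]:
        return max(float(ts[i]), 1e-3)
    frac = (half - rs[i - 1]) / (rs[i] - rs[i - 1])
    return max(float(ts[i - 1] + frac * (ts[i] - ts[i - 1])), 1e-3)


def read_induction_table(path: str | Path) -> pd.DataFrame:
    """Read a 2-column induction table (``time_min<TAB>ratio``, ``#`` comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"time_min", "ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"induction table must have columns {sorted(required)}")
    return df


def write_induction_table(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
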