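"""Competitive-binding kinetics: simulation and residence-time estimation.

The in-vivo dynamics of endogenous (A) and induced competitor (B) copies of a
transcription factor competing for a shared chromatin site are modeled by the
mass-action system

    d theta_A / dt = k_a (1 - theta_A - theta_B) - k_d theta_A
    d theta_B / dt = k_a rho(t) (1 - theta_A - theta_B) - k_d theta_B

where theta_A, theta_B are fractional occupancies, rho(t) is the soluble
competitor/endogenous concentration ratio (the induction curve), and the
endogenous concentration has been absorbed into k_a so both rates carry units
of 1/min.  Association and dissociation rates are shared between the two
species (they are the same protein).  The observable is the occupancy ratio
theta_B(t)/theta_A(t), which at steady state equals rho(infinity) for every
(k_a, k_d) and, in the dilute-binding regime, is nearly insensitive to k_a —
so only k_d (equivalently the residence time t_1/2 = ln2/k_d) is estimable.

Estimation proceeds in three stages:

1. ``fit_ideal`` — least squares with the closed-form *ideal induction*
   solution (the exact solution of the system for a step in rho, evaluated
   with the actual time-dependent rho(t) plugged in).  Fast but biased,
   because the real induction is gradual.
2. ``correct_bias`` — inverts a pre-generated lookup table mapping true k_d
   to the ideal-fit k_d (built by simulating the exact ODE and fitting it
   with the ideal solution).
3. ``newton_refine`` — one-dimensional Newton iteration on d(RSS)/d(k_d) = 0
   where the residuals use exact ODE solutions, started from the
   bias-corrected estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize_scalar

from .induction import InductionCurve, eval_induction
from .series import ScaledLocusSeries

__all__ = [
    "KineticModel",
    "KineticFitResult",
    "BiasTable",
    "DEFAULT_KA",
    "simulate_occupancy",
    "ideal_induction_solution",
    "fit_ideal",
    "build_bias_table",
    "correct_bias",
    "newton_refine",
    "residence_time",
    "dissociation_rate",
    "estimate_residence_time",
]

LN2 = float(np.log(2.0))

#: Nuisance association rate (1/min).  The occupancy ratio is almost
#: insensitive to k_a in the dilute regime, so it is held fixed, not fitted.
DEFAULT_KA = 0.01


@dataclass(frozen=True)
class KineticModel:
    """Association/dissociation rates of the TF-chromatin interaction (1/min)."""

    k_a: float
    k_d: float

    def __post_init__(self) -> None:
        if not self.k_a > 0:
            raise ValueError(f"k_a must be > 0, got {self.k_a}")
        if not self.k_d > 0:
            raise ValueError(f"k_d must be > 0, got {self.k_d}")

    @property
    def t_half(self) -> float:
        return LN2 / self.k_d


@dataclass
class KineticFitResult:
    """Outcome of the three-stage residence-time fit at one locus."""

    k_d: float
    k_d_ideal: float
    rss: float
    n_iter: int
    converged: bool
    method_trace: list[str] = field(default_factory=list)
    locus_id: str = ""

    @property
    def t_half(self) -> float:
        """Residence time ln2/k_d in minutes."""
        return LN2 / self.k_d


def residence_time(k_d) -> float:
    """Residence time (physical half-life) t_1/2 = ln2 / k_d, in minutes."""
    k_d = np.asarray(k_d, dtype=float)
    if np.any(k_d <= 0):
        raise ValueError("k_d must be > 0")
    out = LN2 / k_d
    return float(out) if out.ndim == 0 else out


def dissociation_rate(t_half) -> float:
    """Inverse of :func:`residence_time`: k_d = ln2 / t_1/2 (1/min)."""
    t_half = np.asarray(t_half, dtype=float)
    if np.any(t_half <= 0):
        raise ValueError("t_half must be > 0")
    out = LN2 / t_half
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Forward simulation (exact ODE)
# ---------------------------------------------------------------------------

def simulate_occupancy(
    model: KineticModel,
    induction: InductionCurve,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    return_state: bool = False,
):
    """Integrate the competitive-binding ODEs; return theta_B(t)/theta_A(t).

    Initial conditions are the pre-induction equilibrium
    theta_A(0) = k_a/(k_a + k_d), theta_B(0) = 0.  Integration uses an
    adaptive solver at relative tolerance <= 1e-8, with an implicit-method
    fallback for stiff parameter combinations.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be sorted, unique, and start at 0")

    k_a, k_d = model.k_a, model.k_d

    def rhs(t, y):
        free = 1.0 - y[0] - y[1]
        return (k_a * free - k_d * y[0],
                k_a * eval_induction(induction, t) * free - k_d * y[1])

    y0 = (k_a / (k_a + k_d), 0.0)
    sol = solve_ivp(rhs, (0.0, times[-1]), y0, t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        sol = solve_ivp(rhs, (0.0, times[-1]), y0, t_eval=times,
                        method="Radau", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed for k_a={k_a}, k_d={k_d}: {sol.message}"
        )
    theta_a, theta_b = sol.y
    ratio = theta_b / theta_a
    if return_state:
        return ratio, theta_a, theta_b
    return ratio


# ---------------------------------------------------------------------------
# Ideal-induction closed form
# ---------------------------------------------------------------------------

def _step_solution(k_a: float, k_d: float, rho, t):
    """Exact occupancy ratio for constant rho (step induction at t = 0).

    Solving the linear system for constant rho: the total occupancy
    s = theta_A + theta_B relaxes with rate lam = k_a(1 + rho) + k_d toward
    s_inf = k_a(1 + rho)/lam, and theta_B follows by variation of constants
    from theta_B(0) = 0, theta_A(0) = k_a/(k_a + k_d).
    """
    rho = np.asarray(rho, dtype=float)
    t = np.asarray(t, dtype=float)
    lam = k_a * (1.0 + rho) + k_d
    s_inf = k_a * (1.0 + rho) / lam
    s0 = k_a / (k_a + k_d)
    e_lam = np.exp(-lam * t)
    e_kd = np.exp(-k_d * t)
    s = s_inf + (s0 - s_inf) * e_lam
    theta_b = (
        k_a * rho * (1.0 - s_inf) * (1.0 - e_kd) / k_d
        + rho * (s0 - s_inf) * (e_lam - e_kd) / (1.0 + rho)
    )
    theta_a = s - theta_b
    return theta_b / theta_a


def ideal_induction_solution(model: KineticModel, induction: InductionCurve, t):
    """Approximate occupancy ratio: step-induction closed form with rho -> rho(t).

    Exact when rho is constant in time; for a gradual induction it is an
    approximation whose bias the lookup table corrects.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    rho = eval_induction(induction, t)
    out = _step_solution(model.k_a, model.k_d, rho, t)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Stage 1: ideal fit
# ---------------------------------------------------------------------------

class KineticFitError(RuntimeError):
    """Raised when a residence-time fitting stage cannot produce an estimate."""


def _t0_guess(times, values, asymptote: float) -> float:
    """Half-rise time of the series by linear interpolation."""
    half = 0.5 * min(asymptote, float(np.max(values)) if np.max(values) > 0 else asymptote)
    above = np.nonzero(values >= half)[0]
    if len(above) == 0 or above[0] == 0:
        return max(float(times[1]) if len(times) > 1 else 1.0, 1.0)
    i = above[0]
    if values[i] == values[i - 1]:
        return float(times[i])
    frac = (half - values[i - 1]) / (values[i] - values[i - 1])
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def fit_ideal(
    series: ScaledLocusSeries,
    induction: InductionCurve,
    k_a: float = DEFAULT_KA,
) -> float:
    """Least-squares k_d estimate using the ideal-induction closed form.

    k_a is held at a fixed nuisance value.  The starting value is
    k_d0 = ln2 / max(t0 - t_ind, 0.5 min) with t0 the series half-rise time.
    Returns the (biased) ideal-fit k_d in 1/min.
    """
    times, values = series.times, series.values
    if len(times) < 3:
        raise KineticFitError("need at least 3 time points to fit k_d")
    t0 = _t0_guess(times, values, induction.rho_inf)
    k_d0 = LN2 / max(t0 - induction.t_ind, 0.5)
    rho = eval_induction(induction, times)

    def resid(log_kd):
        return _step_solution(k_a, np.exp(log_kd[0]), rho, times) - values

    res = least_squares(
        resid, x0=[np.log(k_d0)],
        bounds=([np.log(1e-6)], [np.log(1e3)]),
        xtol=1e-12, ftol=1e-12,
    )
    if not res.success:
        raise KineticFitError(f"ideal-induction fit did not converge: {res.message}")
    return float(np.exp(res.x[0]))


# ---------------------------------------------------------------------------
# Stage 2: bias lookup table
# ---------------------------------------------------------------------------

@dataclass
class BiasTable:
    """Monotone mapping between true k_d and ideal-induction-fit k_d (1/min).

    Built by simulating the exact ODE across a k_d grid and fitting each
    noiseless curve with the ideal solution; inverted by interpolation to
    correct new ideal-fit estimates.
    """

    k_d_true: np.ndarray
    k_d_ideal: np.ndarray
    k_a: float
    times: np.ndarray
    induction: InductionCurve

    def __post_init__(self) -> None:
        self.k_d_true = np.asarray(self.k_d_true, dtype=float)
        self.k_d_ideal = np.asarray(self.k_d_ideal, dtype=float)
        if np.any(np.diff(self.k_d_true) <= 0) or np.any(np.diff(self.k_d_ideal) <= 0):
            raise ValueError("bias table must be strictly monotone in both columns")


def default_kd_grid(t_half_min: float = 0.5, t_half_max: float = 120.0, n: int = 60):
    """Log-spaced k_d grid spanning residence times [t_half_min, t_half_max] min."""
    return np.geomspace(LN2 / t_half_max, LN2 / t_half_min, n)


def build_bias_table(
    induction: InductionCurve,
    k_d_grid=None,
    times=None,
    k_a: float = DEFAULT_KA,
) -> BiasTable:
    """Tabulate ideal-fit k_d against true k_d over the working range.

    For each true k_d the exact ODE is simulated on the experimental time
    grid and refit with the ideal-induction solution; a non-monotone table
    indicates fit instability and raises.
    """
    from .series import DEFAULT_TIME_GRID

    if k_d_grid is None:
        k_d_grid = default_kd_grid()
    k_d_grid = np.sort(np.asarray(k_d_grid, dtype=float))
    if len(k_d_grid) < 50:
        raise ValueError("k_d grid must have >= 50 points for reliable inversion")
    if times is None:
        times = np.asarray(DEFAULT_TIME_GRID)
    times = np.asarray(times, dtype=float)

    ideals = np.empty_like(k_d_grid)
    for i, kd in enumerate(k_d_grid):
        ratio = simulate_occupancy(KineticModel(k_a, kd), induction, times)
        ser = ScaledLocusSeries(locus_id=f"_grid_{i}", times=times, values=ratio)
        ideals[i] = fit_ideal(ser, induction, k_a=k_a)
    return BiasTable(k_d_true=k_d_grid, k_d_ideal=ideals, k_a=k_a,
                     times=times, induction=induction)


def correct_bias(k_d_ideal: float, table: BiasTable) -> float:
    """Map an ideal-fit k_d to a bias-corrected k_d by monotone inverse interpolation.

    Values outside the table's ideal-fit range are clamped with a warning;
    beyond twice the table bounds an error is raised.
    """
    if not k_d_ideal > 0:
        raise ValueError("k_d_ideal must be > 0")
    lo, hi = table.k_d_ideal[0], table.k_d_ideal[-1]
    if k_d_ideal < lo / 2.0 or k_d_ideal > hi * 2.0:
        raise ValueError(
            f"k_d_ideal={k_d_ideal:.4g} is beyond 2x the table range [{lo:.4g}, {hi:.4g}]"
        )
    if k_d_ideal < lo or k_d_ideal > hi:
        warnings.warn(
            f"k_d_ideal={k_d_ideal:.4g} outside table range; clamped", stacklevel=2
        )
        k_d_ideal = float(np.clip(k_d_ideal, lo, hi))
    # interpolate in log-log space: both columns span decades
    return float(np.exp(np.interp(
        np.log(k_d_ideal), np.log(table.k_d_ideal), np.log(table.k_d_true)
    )))


# ---------------------------------------------------------------------------
# Stage 3: Newton refinement on the exact ODE
# ---------------------------------------------------------------------------

def newton_refine(
    series: ScaledLocusSeries,
    induction: InductionCurve,
    k_d_start: float,
    k_a: float = DEFAULT_KA,
    rel_step: float = 1e-3,
    rel_tol: float = 1e-4,
    max_iter: int = 50,
    k_d_ideal: float = float("nan"),
    trace: list[str] | None = None,
) -> KineticFitResult:
    """One-dimensional Newton minimization of the exact-ODE residual over k_d.

    Iterates on d(RSS)/d(k_d) = 0 with central-difference derivatives
    (relative step ``rel_step``); converges when the relative update falls
    below ``rel_tol``.  If Newton diverges (non-finite step, non-positive
    curvature escape, or iteration budget exhausted without convergence), a
    bounded golden-section search on [k_d_start/10, 10 k_d_start] is used.
    """
    if not k_d_start > 0:
        raise ValueError("k_d_start must be > 0")
    times, values = series.times, series.values
    method_trace = list(trace) if trace else []

    def rss(kd: float) -> float:
        r = simulate_occupancy(KineticModel(k_a, kd), induction, times)
        return float(np.sum((r - values) ** 2))

    kd = float(k_d_start)
    converged = False
    n_iter = 0
    fallback = False
    for n_iter in range(1, max_iter + 1):
        h = rel_step * kd
        f0, fp, fm = rss(kd), rss(kd + h), rss(kd - h)
        if not np.isfinite([f0, fp, fm]).all():
            return KineticFitResult(k_d=kd, k_d_ideal=k_d_ideal, rss=np.nan,
                                    n_iter=n_iter, converged=False,
                                    method_trace=method_trace + ["newton:non-finite-rss"],
                                    locus_id=series.locus_id)
        grad = (fp - fm) / (2.0 * h)
        curv = (fp - 2.0 * f0 + fm) / (h * h)
        if curv <= 0 or not np.isfinite(curv):
            fallback = True
            break
        step = -grad / curv
        # keep the iterate positive and the step sane
        step = float(np.clip(step, -0.5 * kd, 1.0 * kd))
        kd_new = kd + step
        if abs(kd_new - kd) / kd < rel_tol:
            kd = kd_new
            converged = True
            break
        kd = kd_new
    else:
        fallback = True

    if fallback:
        res = minimize_scalar(
            rss, bounds=(k_d_start / 10.0, 10.0 * k_d_start), method="bounded",
            options={"xatol": rel_tol * k_d_start},
        )
        kd = float(res.x)
        converged = bool(res.success)
        method_trace.append("golden-section")
    else:
        method_trace.append("newton")

    final_rss = rss(kd)
    return KineticFitResult(k_d=kd, k_d_ideal=k_d_ideal, rss=final_rss,
                            n_iter=n_iter, converged=converged,
                            method_trace=method_trace, locus_id=series.locus_id)


def estimate_residence_time(
    series: ScaledLocusSeries,
    induction: InductionCurve,
    bias_table: BiasTable | None = None,
    k_a: float = DEFAULT_KA,
) -> KineticFitResult:
    """Full three-stage estimator: ideal fit -> lookup correction -> Newton.

    ``bias_table`` should be built once (per induction curve and time grid)
    and reused across loci; when None it is built on the fly.
    """
    if bias_table is None:
        bias_table = build_bias_table(induction, times=series.times, k_a=k_a)
    kd_ideal = fit_ideal(series, induction, k_a=k_a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kd_corrected = correct_bias(kd_ideal, bias_table)
    return newton_refine(series, induction, kd_corrected, k_a=k_a,
                         k_d_ideal=kd_ideal, trace=["ideal", "lookup"])
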