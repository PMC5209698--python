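"""Probe-level preprocessing of two-color competition ChIP arrays.

Raw arrays report the competitor/endogenous optical ratio per probe, in two
dye orientations (dye swap).  Preprocessing: (1) geometrically average the
dye-swapped ratios; (2) at each time point, fit a normal to the unenriched
side of the log2 ratio distribution to model non-specific background;
(3) call signal probes at t = 0 by tail p-values with BH-FDR control;
(4) divide ratios by the background mean so background maps to 1;
(5) average probes within each peak into a per-locus time series.

Signal probes at t = 0 carry high endogenous but only background competitor
signal, so they sit in the LEFT tail of log2(competitor/endogenous); the
normal is anchored on the right (unenriched) half.  The anchored side is
configurable for designs with the opposite orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .series import LocusSeries
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundModel",
    "geometric_average_dyeswap",
    "fit_background_normal",
    "select_signal_probes",
    "normalize_to_background",
    "aggregate_to_locus",
    "preprocess_probes",
]

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "time_min", "ratio_fwd", "ratio_rev"]


@dataclass(frozen=True)
class BackgroundModel:
    """Normal model of the non-specific background on the log2 ratio scale."""

    mu_log2: float
    sigma_log2: float
    time_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_log2 > 0:
            raise ValueError(f"sigma_log2 must be > 0, got {self.sigma_log2}")


def geometric_average_dyeswap(ratio_fwd, ratio_rev):
    """Geometric mean sqrt(fwd * rev) of a dye-swapped ratio pair.

    Both ratios must be positive and oriented identically
    (competitor/endogenous).  Accepts scalars or arrays.
    """
    fwd = np.asarray(ratio_fwd, dtype=float)
    rev = np.asarray(ratio_rev, dtype=float)
    if np.any(fwd <= 0) or np.any(rev <= 0):
        raise ValueError("dye-swap ratios must be > 0")
    out = np.sqrt(fwd * rev)
    return float(out) if out.ndim == 0 else out


def fit_background_normal(
    log2_ratios,
    time_min: float = 0.0,
    signal_side: str = "left",
    cutoff_sigmas: float = 1.0,
) -> BackgroundModel:
    """Fit a normal to the unenriched side of a log2 ratio distribution.

    Signal probes contaminate only one tail, so the normal is anchored on
    the opposite (unenriched) side: a robust location (median) and scale
    (scaled MAD) place a cutoff ``cutoff_sigmas`` robust-SDs below the bulk
    mode, and (mu, sigma) are estimated by maximum likelihood treating the
    values beyond the cutoff as a truncated normal.  Consistent as long as
    the signal component stays beyond the cutoff, i.e. the enriched tail is
    a minority and well separated from the background bulk.
    """
    x = np.asarray(log2_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 100:
        raise ValueError("need >= 100 values to fit the background normal")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) input; background scale undefined")
    if signal_side not in ("left", "right"):
        raise ValueError("signal_side must be 'left' or 'right'")
    # reduce to the canonical case: signal in the left tail, background right
    flip = signal_side == "right"
    xx = -x if flip else x

    med = float(np.median(xx))
    mad = float(np.median(np.abs(xx - med)))
    s_rob = 1.4826 * mad
    if s_rob == 0:
        raise ValueError("degenerate bulk (zero MAD); background scale undefined")
    cut = med - cutoff_sigmas * s_rob
    tail = xx[xx >= cut]
    if len(tail) < 50:
        raise ValueError("too few values on the unenriched side of the cutoff")

    def nll(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        z = (tail - mu) / sigma
        log_norm = norm.logsf((cut - mu) / sigma)
        return float(np.sum(0.5 * z * z) + len(tail) * (log_sigma + log_norm))

    from scipy.optimize import minimize

    res = minimize(nll, x0=[med, np.log(s_rob)], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
    if not res.success:
        raise ValueError(f"background normal fit failed: {res.message}")
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    if flip:
        mu = -mu
    return BackgroundModel(mu_log2=mu, sigma_log2=sigma, time_min=time_min)


def select_signal_probes(
    log2_ratios,
    bg: BackgroundModel,
    fdr: float = 0.05,
    signal_side: str = "left",
) -> np.ndarray:
    """Indices of probes whose t = 0 ratio is signal at the given FDR.

    One-sided tail p-values under the fitted background normal (toward the
    signal side), Benjamini-Hochberg adjusted; probes with adjusted
    p <= ``fdr`` are returned.
    """
    x = np.asarray(log2_ratios, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    z = (x - bg.mu_log2) / bg.sigma_log2
    if signal_side == "left":
        p = norm.cdf(z)
    elif signal_side == "right":
        p = norm.sf(z)
    else:
        raise ValueError("signal_side must be 'left' or 'right'")
    p_adj = bh_adjust(p)
    return np.nonzero(p_adj <= fdr)[0]


def normalize_to_background(ratio, bg: BackgroundModel):
    """Divide a ratio by the background mean 2**mu_log2 of its time point.

    A ratio equal to the background mean maps to exactly 1.
    """
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("ratios must be > 0")
    out = ratio / 2.0 ** bg.mu_log2
    return float(out) if out.ndim == 0 else out


def aggregate_to_locus(
    probes: pd.DataFrame,
    peaks: pd.DataFrame,
    value_col: str = "value",
    stat: str = "mean",
) -> list[LocusSeries]:
    """Average normalized probe ratios within each peak into a LocusSeries.

    Probes are assigned to a peak by >= 1 bp interval overlap (0-based
    half-open coordinates).  ``peaks`` needs columns chrom/start/end and
    optionally ``name``; anonymous peaks get ``chrom:start-end`` ids.  Peaks
    with no overlapping probes are skipped with a warning.  ``stat`` is the
    per-time aggregate: 'mean' (default) or 'median'.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    peaks = peaks.copy()
    if "name" not in peaks.columns:
        peaks["name"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])
        ]
    out: list[LocusSeries] = []
    for _, pk in peaks.iterrows():
        same = probes["chrom"].to_numpy() == pk["chrom"]
        hit = same & (probes["start"].to_numpy() < pk["end"]) & (probes["end"].to_numpy() > pk["start"])
        sub = probes.loc[hit]
        if sub.empty:
            logger.warning("peak %s has no overlapping probes; skipped", pk["name"])
            continue
        agg = getattr(sub.groupby("time_min")[value_col], stat)().sort_index()
        out.append(LocusSeries(locus_id=str(pk["name"]),
                               times=agg.index.to_numpy(dtype=float),
                               values=agg.to_numpy(dtype=float)))
    return out


def preprocess_probes(
    probes: pd.DataFrame,
    peaks: pd.DataFrame,
    fdr: float = 0.05,
    signal_side: str = "left",
    stat: str = "mean",
) -> tuple[list[LocusSeries], pd.DataFrame, list[BackgroundModel]]:
    """Full probe-level pipeline: dye-swap average, background-normalize, aggregate.

    Returns the per-locus series, the normalized probe table restricted to
    signal probes (selected at t = 0), and the per-time background models.
    """
    missing = set(PROBE_COLUMNS) - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    df = probes.copy()
    df["ratio"] = geometric_average_dyeswap(
        df["ratio_fwd"].to_numpy(), df["ratio_rev"].to_numpy()
    )

    models: list[BackgroundModel] = []
    df["value"] = np.nan
    for t, idx in df.groupby("time_min").groups.items():
        log2r = np.log2(df.loc[idx, "ratio"].to_numpy())
        bg = fit_background_normal(log2r, time_min=float(t), signal_side=signal_side)
        models.append(bg)
        df.loc[idx, "value"] = normalize_to_background(
            df.loc[idx, "ratio"].to_numpy(), bg
        )

    t0 = df[df["time_min"] == df["time_min"].min()]
    bg0 = next(m for m in models if m.time_min == float(df["time_min"].min()))
    sel = select_signal_probes(
        np.log2(t0["ratio"].to_numpy()), bg0, fdr=fdr, signal_side=signal_side
    )
    signal_ids = set(t0.iloc[sel]["probe_id"])
    logger.info("selected %d/%d signal probes at FDR %.3g", len(signal_ids),
                t0["probe_id"].nunique(), fdr)
    signal_df = df[df["probe_id"].isin(signal_ids)].copy()
    series = aggregate_to_locus(signal_df, peaks, stat=stat)
    logger.info("aggregated %d loci from %d peaks", len(series), len(peaks))
    return series, signal_df, models
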