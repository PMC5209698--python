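"""Comparative statistics on residence times, transcription rates and efficiency.

Transcriptional efficiency is the product TR * t_1/2 of the nascent
transcription rate (RNA molecules/min) and the TF residence time (min): the
expected number of RNA molecules produced per TF-chromatin binding event.
Its inverse is the number of binding events per RNA.  Group contrasts use
the two-sample Kolmogorov-Smirnov test, associations use Spearman rank
correlation, and TF presence/absence effects use a label-permutation test on
the group mean difference with Benjamini-Hochberg FDR control across factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "transcription_efficiency",
    "binding_events_per_rna",
    "ks_compare",
    "spearman_corr",
    "permutation_test",
    "permutation_scan",
    "bh_adjust",
    "quartile_stratify",
]


@dataclass
class StatResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of range: {self.p_value}")


def transcription_efficiency(tr, t_half):
    """TR * t_1/2 in RNA molecules per binding event.

    ``tr`` is the transcription rate in molecules/min, ``t_half`` the
    residence time in minutes.
    """
    tr = np.asarray(tr, dtype=float)
    t_half = np.asarray(t_half, dtype=float)
    if np.any(tr < 0):
        raise ValueError("transcription rate must be >= 0")
    if np.any(t_half <= 0):
        raise ValueError("residence time must be > 0")
    out = tr * t_half
    return float(out) if out.ndim == 0 else out


def binding_events_per_rna(efficiency):
    """Number of TF binding events per RNA: 1 / (TR * t_1/2)."""
    eff = np.asarray(efficiency, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("efficiency must be > 0")
    out = 1.0 / eff
    return float(out) if out.ndim == 0 else out


def ks_compare(a, b) -> StatResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    res = ks_2samp(a, b, method="asymp")
    return StatResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n1=len(a), n2=len(b), method="ks")


def spearman_corr(x, y) -> float:
    """Spearman rank correlation; missing pairs dropped; constant input raises."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(spearmanr(x, y).statistic)


def permutation_test(
    values,
    present_mask,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> StatResult:
    """Label-permutation test on the mean difference (present - absent).

    Two-sided p-value with the add-one correction:
    p = (1 + #{|perm diff| >= |observed|}) / (n_perm + 1).
    Only the labels are permuted; the values stay fixed.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(present_mask, dtype=bool)
    if values.shape != mask.shape or values.ndim != 1:
        raise ValueError("values and present_mask must be 1-D and aligned")
    n1 = int(mask.sum())
    n0 = len(mask) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    total = values.sum()
    obs = values[mask].mean() - values[~mask].mean()
    # a permuted mean difference is determined by the sum over the n1
    # relabeled-present loci, so permute indices and take partial sums
    u = rng.random((n_perm, len(values)))
    idx = np.argpartition(u, n1 - 1, axis=1)[:, :n1]
    s1 = values[idx].sum(axis=1)
    diffs = s1 / n1 - (total - s1) / n0
    p = (1.0 + np.count_nonzero(np.abs(diffs) >= np.abs(obs) - 1e-12)) / (n_perm + 1.0)
    return StatResult(statistic=float(obs), p_value=float(min(p, 1.0)),
                      n1=n1, n2=n0, method="permutation")


def permutation_scan(
    values: pd.Series,
    presence: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-test one statistic against many TF presence columns.

    ``values`` is indexed by locus; ``presence`` is a boolean locus-by-factor
    matrix.  Returns a DataFrame (one row per factor) with the mean
    difference, permutation p-value and BH-adjusted FDR.
    """
    common = values.index.intersection(presence.index)
    vals = values.loc[common].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for tf in presence.columns:
        mask = presence.loc[common, tf].to_numpy(dtype=bool)
        if mask.all() or not mask.any():
            rows.append((tf, np.nan, np.nan, int(mask.sum()), int((~mask).sum())))
            continue
        res = permutation_test(vals, mask, n_perm=n_perm, seed=rng)
        rows.append((tf, res.statistic, res.p_value, res.n1, res.n2))
    out = pd.DataFrame(rows, columns=["tf_name", "mean_diff", "p", "n_present", "n_absent"])
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def quartile_stratify(counts, ids=None) -> dict:
    """Split loci into top and bottom quartiles of a count statistic.

    Ties at a quartile boundary are included in the corresponding set
    (symmetrically for both quartiles).  Returns a dict with ``upper`` and
    ``lower`` index arrays (or id arrays when ``ids`` is given) and a
    ``degenerate`` flag set when the two sets coincide.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 8:
        raise ValueError("need >= 8 loci to stratify by quartile")
    q1, q3 = np.quantile(counts, [0.25, 0.75])
    lower = np.nonzero(counts <= q1)[0]
    upper = np.nonzero(counts >= q3)[0]
    degenerate = bool(set(lower) == set(upper))
    if ids is not None:
        ids = np.asarray(ids)
        return {"upper": ids[upper], "lower": ids[lower], "degenerate": degenerate}
    return {"upper": upper, "lower": lower, "degenerate": degenerate}
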