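"""Synthetic competition-ChIP datasets with known ground truth.

The generator inverts the analysis pipeline: it draws per-locus residence
times, simulates exact-ODE occupancy ratios under the induction curve, maps
them to probe-level array observables (divide by the per-locus antibody
scale alpha, add the locus background B, apply a per-time-point global scale
drift), and then adds multiplicative log-normal measurement noise
independently to each dye orientation so the geometric dye-swap average has
the configured noise level.  A population of pure-background probes is added
so that background fitting and signal-probe selection can be exercised; at
t = 0 the signal probes sit in the left tail of the background distribution,
which is the preprocessing module's selection premise.

Defaults emulate the TBP competition design: induction saturating at 2.23
with a 22-minute half-time (Hill n = 4), residence times log-normal with a
3-minute median for Pol II loci (longer for Pol III), transcription rates
rank-correlated with residence time at about -0.11 so that the median
transcriptional efficiency falls near 0.2 molecules, and 11 array time
points across 0-70 minutes with dye-swap replicates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .induction import InductionCurve, eval_induction
from .kinetics import DEFAULT_KA, KineticModel, simulate_occupancy
from .series import DEFAULT_TIME_GRID, ScaledLocusSeries

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_null_annotations",
    "make_scaled_series",
    "write_dataset",
]

TF_CLASSES = ("transcription", "initiation", "elongation", "access", "orchestration")


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth distributions and noise levels for a synthetic dataset."""

    seed: int
    n_loci: int = 200
    n_background_probes: int = 20000
    probes_per_locus: int = 3
    time_grid: tuple = DEFAULT_TIME_GRID
    # induction truth
    rho_inf: float = 2.23
    t_ind: float = 22.0
    hill_n: int = 4
    induction_noise_log2: float = 0.05
    # residence-time truth (minutes; log-normal)
    t_half_median: float = 3.0
    t_half_log_sd: float = 0.8
    pol3_fraction: float = 0.2
    pol3_t_half_factor: float = 3.0
    tata_fraction: float = 0.2
    tata_t_half_factor: float = 0.8
    rp_fraction: float = 0.1
    # locus array parameters
    b_min: float = 0.02
    b_max: float = 0.15
    alpha_median: float = 2.2
    alpha_log_sd: float = 0.15
    # noise model
    noise_sigma_log2: float = 0.1
    bg_sigma_log2: float = 0.35
    drift_sigma_log2: float = 0.1
    # annotations
    tr_median: float = 0.067
    tr_log_sd: float = 1.0
    tr_spearman: float = -0.11
    noise_ext_spearman: float = -0.10
    n_tf: int = 20
    k_a: float = DEFAULT_KA

    def validate(self) -> None:
        bad = []
        if self.n_loci < 1:
            bad.append("n_loci")
        if self.n_background_probes < 100:
            bad.append("n_background_probes")
        if self.probes_per_locus < 1:
            bad.append("probes_per_locus")
        for name in ("rho_inf", "t_ind", "t_half_median", "t_half_log_sd",
                     "alpha_median", "bg_sigma_log2", "tr_median"):
            if not getattr(self, name) > 0:
                bad.append(name)
        for name in ("noise_sigma_log2", "drift_sigma_log2", "induction_noise_log2"):
            if getattr(self, name) < 0:
                bad.append(name)
        for name in ("pol3_fraction", "tata_fraction", "rp_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                bad.append(name)
        if not 0 < self.b_min <= self.b_max:
            bad.append("b_min/b_max")
        if bad:
            raise ValueError(f"invalid SyntheticConfig fields: {sorted(set(bad))}")

    @property
    def induction(self) -> InductionCurve:
        return InductionCurve(self.rho_inf, self.t_ind, self.hill_n)


@dataclass
class GroundTruth:
    """Per-locus generating parameters plus the global induction truth."""

    loci: pd.DataFrame  # locus_id, k_d, t_half, B, alpha
    rho_inf: float
    t_ind: float
    hill_n: int
    seed: int


@dataclass
class SyntheticDataset:
    probes: pd.DataFrame
    induction: pd.DataFrame
    peaks: pd.DataFrame
    annotations: pd.DataFrame
    tf_table: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig = field(repr=False, default=None)


def _copula_lognormal(rng, z_anchor, target_spearman, log_median, log_sd):
    """Log-normal sample rank-correlated with the anchor's normal scores.

    Uses the Gaussian-copula identity r_pearson = 2 sin(pi * r_spearman / 6).
    """
    r = 2.0 * np.sin(np.pi * target_spearman / 6.0)
    w = rng.standard_normal(len(z_anchor))
    z = r * z_anchor + np.sqrt(1.0 - r * r) * w
    return np.exp(log_median + log_sd * z)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset; byte-stable for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    times = np.asarray(config.time_grid, dtype=float)
    induction = config.induction
    locus_ids = [f"locus_{i:04d}" for i in range(n)]

    # --- annotations drive the residence-time distribution -----------------
    pol3 = rng.random(n) < config.pol3_fraction
    tata = rng.random(n) < config.tata_fraction
    rp = rng.random(n) < config.rp_fraction
    z = rng.standard_normal(n)
    log_med = (
        np.log(config.t_half_median)
        + np.log(config.pol3_t_half_factor) * pol3
        + np.log(config.tata_t_half_factor) * tata
    )
    t_half = np.exp(log_med + config.t_half_log_sd * z)
    k_d = np.log(2.0) / t_half

    tr = _copula_lognormal(rng, z, config.tr_spearman,
                           np.log(config.tr_median), config.tr_log_sd)
    noise_ext = np.log(_copula_lognormal(rng, z, config.noise_ext_spearman, 0.0, 1.0))

    annotations = pd.DataFrame({
        "locus_id": locus_ids,
        "pol_class": np.where(pol3, "PolIII", "PolII"),
        "tata": np.where(tata, "TATA", "TATA-less"),
        "rp": np.where(rp, "RP", "non-RP"),
        "tr": tr,
        "noise_ext": noise_ext,
    })

    tf_names = [f"TF{j:02d}" for j in range(config.n_tf)]
    tf_rows = []
    for j, name in enumerate(tf_names):
        rate = rng.uniform(0.2, 0.6)
        present = rng.random(n) < rate
        cls = TF_CLASSES[j % len(TF_CLASSES)]
        tf_rows.append(pd.DataFrame({
            "locus_id": locus_ids, "tf_name": name, "tf_class": cls,
            "present": present.astype(int),
        }))
    tf_table = pd.concat(tf_rows, ignore_index=True)

    # --- array-scale truth --------------------------------------------------
    B = rng.uniform(config.b_min, config.b_max, size=n)
    alpha = np.exp(np.log(config.alpha_median)
                   + config.alpha_log_sd * rng.standard_normal(n))
    drift = 2.0 ** (config.drift_sigma_log2 * rng.standard_normal(len(times)))

    # --- probe table ---------------------------------------------------------
    # per-orientation noise has sd sqrt(2) * sigma so the geometric average
    # of a dye-swap pair has sd sigma on the log2 scale
    sd_orient = np.sqrt(2.0) * config.noise_sigma_log2
    n_t = len(times)
    ppl = config.probes_per_locus

    ratio = np.vstack([
        simulate_occupancy(KineticModel(config.k_a, kd_i), induction, times)
        for kd_i in k_d
    ])  # (n_loci, n_t)
    sig_mean = ratio / alpha[:, None] + B[:, None]
    sig_base = np.repeat(sig_mean, ppl, axis=0) * drift  # (n_loci*ppl, n_t)
    sig_fwd = sig_base * 2.0 ** (sd_orient * rng.standard_normal(sig_base.shape))
    sig_rev = sig_base * 2.0 ** (sd_orient * rng.standard_normal(sig_base.shape))
    sig_ids = [f"{lid}_p{p}" for lid in locus_ids for p in range(ppl)]
    sig_start = np.array([2000 * i + 100 * p for i in range(n) for p in range(ppl)])

    n_bg = config.n_background_probes
    bg_base = (2.0 ** (config.bg_sigma_log2 * rng.standard_normal((n_bg, n_t)))
               * drift)
    bg_fwd = bg_base * 2.0 ** (sd_orient * rng.standard_normal(bg_base.shape))
    bg_rev = bg_base * 2.0 ** (sd_orient * rng.standard_normal(bg_base.shape))
    bg_ids = [f"bg_{j:05d}" for j in range(n_bg)]
    bg_start = 100 * np.arange(n_bg)

    def _long(ids, chrom, starts, fwd, rev):
        m = len(ids)
        return pd.DataFrame({
            "probe_id": np.repeat(ids, n_t),
            "chrom": chrom,
            "start": np.repeat(starts, n_t),
            "end": np.repeat(starts + 60, n_t),
            "time_min": np.tile(times, m),
            "ratio_fwd": fwd.ravel(),
            "ratio_rev": rev.ravel(),
        })

    probes = pd.concat([
        _long(sig_ids, "chrS", sig_start, sig_fwd, sig_rev),
        _long(bg_ids, "chrU", bg_start, bg_fwd, bg_rev),
    ], ignore_index=True)

    peaks = pd.DataFrame({
        "chrom": "chrS",
        "start": [2000 * i for i in range(n)],
        "end": [2000 * i + 100 * (config.probes_per_locus - 1) + 60 for i in range(n)],
        "name": locus_ids,
    })

    # --- induction measurements ----------------------------------------------
    ind_times = np.arange(0.0, times[-1] + 1e-9, 5.0)
    rho = eval_induction(induction, ind_times)
    ind_ratio = rho * 2.0 ** (config.induction_noise_log2
                              * rng.standard_normal(len(ind_times)))
    induction_df = pd.DataFrame({"time_min": ind_times, "ratio": ind_ratio})

    truth = GroundTruth(
        loci=pd.DataFrame({"locus_id": locus_ids, "k_d": k_d, "t_half": t_half,
                           "B": B, "alpha": alpha}),
        rho_inf=config.rho_inf, t_ind=config.t_ind, hill_n=config.hill_n,
        seed=config.seed,
    )
    return SyntheticDataset(probes=probes, induction=induction_df, peaks=peaks,
                            annotations=annotations, tf_table=tf_table,
                            truth=truth, config=config)


def generate_null_annotations(
    locus_ids,
    seed: int,
    n_tf: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotations with every flag independent of every numeric column.

    Used to calibrate type-I error of the downstream tests: class labels,
    TF presence, transcription rate and noise scores are all drawn
    independently of each other and of any residence-time estimates.
    """
    locus_ids = list(locus_ids)
    n = len(locus_ids)
    if n == 0:
        raise ValueError("no loci given")
    rng = np.random.default_rng(seed)
    annotations = pd.DataFrame({
        "locus_id": locus_ids,
        "pol_class": np.where(rng.random(n) < 0.2, "PolIII", "PolII"),
        "tata": np.where(rng.random(n) < 0.2, "TATA", "TATA-less"),
        "rp": np.where(rng.random(n) < 0.1, "RP", "non-RP"),
        "tr": np.exp(np.log(0.067) + rng.standard_normal(n)),
        "noise_ext": rng.standard_normal(n),
    })
    tf_rows = []
    for j in range(n_tf):
        rate = rng.uniform(0.2, 0.6)
        tf_rows.append(pd.DataFrame({
            "locus_id": locus_ids, "tf_name": f"TF{j:02d}",
            "tf_class": TF_CLASSES[j % len(TF_CLASSES)],
            "present": (rng.random(n) < rate).astype(int),
        }))
    return annotations, pd.concat(tf_rows, ignore_index=True)


def make_scaled_series(
    t_half: float,
    induction: InductionCurve,
    times=DEFAULT_TIME_GRID,
    sigma_log2: float = 0.0,
    k_a: float = DEFAULT_KA,
    seed: int = 0,
    locus_id: str = "synthetic",
) -> ScaledLocusSeries:
    """Exact-ODE occupancy-ratio series, optionally with log-normal noise.

    Convenience for testing the kinetic estimator in isolation: the series
    is already on the scaled (in-vivo occupancy ratio) scale.  Noise is
    multiplicative log2-normal and leaves the t = 0 zero untouched.
    """
    times = np.asarray(times, dtype=float)
    ratio = simulate_occupancy(KineticModel(k_a, np.log(2.0) / t_half),
                               induction, times)
    if sigma_log2 > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio * 2.0 ** (sigma_log2 * rng.standard_normal(len(times)))
    return ScaledLocusSeries(locus_id=locus_id, times=times, values=ratio)


def write_dataset(ds: SyntheticDataset, outdir: str | Path, header: str = "") -> dict:
    """Write all dataset tables as TSV/BED plus a manifest; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _write(df: pd.DataFrame, path: Path, sep="\t", with_header=True):
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep=sep, index=False, header=with_header,
                      float_format="%.10g")

    paths = {
        "probes": outdir / "probes.tsv",
        "induction": outdir / "induction.tsv",
        "peaks": outdir / "peaks.bed",
        "annotations": outdir / "annotations.tsv",
        "tf_table": outdir / "tf_presence.tsv",
        "truth": outdir / "truth.tsv",
    }
    _write(ds.probes, paths["probes"])
    _write(ds.induction, paths["induction"])
    with open(paths["peaks"], "w") as fh:  # BED: no header line
        ds.peaks[["chrom", "start", "end", "name"]].to_csv(
            fh, sep="\t", index=False, header=False)
    _write(ds.annotations, paths["annotations"])
    _write(ds.tf_table, paths["tf_table"])
    _write(ds.truth.loci, paths["truth"])

    manifest = {
        "config": asdict(ds.config) if ds.config else None,
        "seed": ds.truth.seed,
        "induction_truth": {"rho_inf": ds.truth.rho_inf, "t_ind": ds.truth.t_ind,
                            "hill_n": ds.truth.hill_n},
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = outdir / "manifest.json"
    return {k: str(v) for k, v in paths.items()}
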