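"""End-to-end run on a synthetic dataset with known ground truth.

Generates probe-level two-color array data (dye swaps, background probes,
per-time-point drift, log-normal noise), then runs every pipeline stage:
background normalization and probe selection, probe-to-locus aggregation,
induction fit, sigmoid scaling with reliability criteria, and the kinetic
estimator with joint (k_d, B, alpha) refinement.  Compares recovered
residence times with the generating truth.
"""

import numpy as np
from scipy.stats import spearmanr

from compchip import (
    SyntheticConfig,
    analyze_dataset,
    build_bias_table,
    fit_induction,
    generate_dataset,
    preprocess_probes,
)

config = SyntheticConfig(seed=20, n_loci=60)
dataset = generate_dataset(config)
print(f"simulated {config.n_loci} loci, "
      f"{dataset.probes['probe_id'].nunique()} probes "
      f"({config.n_background_probes} background)")

series, _, _ = preprocess_probes(dataset.probes, dataset.peaks, fdr=0.05)
print(f"preprocessing kept {len(series)} loci with signal probes")

curve = fit_induction(dataset.induction["time_min"].to_numpy(),
                      dataset.induction["ratio"].to_numpy())
print(f"induction fit: rho_inf = {curve.rho_inf:.3f}, t_ind = {curve.t_ind:.1f} min")

table = build_bias_table(curve, times=series[0].times)
results = analyze_dataset(series, curve, bias_table=table)

truth = dataset.truth.loci.set_index("locus_id")["t_half"]
reliable = [(r.t_half, truth[r.locus_id]) for r in results
            if r.passes and r.kinetics is not None]
est, tru = np.array(reliable).T
rel_err = np.abs(est - tru) / tru
print(f"\n{len(reliable)} loci pass the reliability criteria")
print(f"median |t1/2 error|: {100 * np.median(rel_err):.1f}%")
print(f"rank correlation (estimated vs true): "
      f"{spearmanr(est, tru).statistic:.3f}")
print("\nLoci failing the criteria are dominated by short residence times")
print("(response time t0 < 24.5 min), where the locus curve is separated")
print("from the induction curve by less than the data noise.")
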