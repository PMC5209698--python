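"""Three-stage residence-time estimation on a single locus.

Generates an occupancy-ratio time course from the exact ODE model at a known
residence time, then runs the estimator: (1) fast closed-form fit assuming
instantaneous induction, (2) lookup-table correction of the resulting bias,
(3) Newton refinement against the exact ODE.  Repeats with multiplicative
log-normal noise to show the estimator's behavior on realistic data.
"""

import numpy as np

from compchip import (
    DEFAULT_INDUCTION,
    build_bias_table,
    estimate_residence_time,
    make_scaled_series,
)
from compchip.series import DEFAULT_TIME_GRID

LN2 = np.log(2)
times = np.array(DEFAULT_TIME_GRID)
table = build_bias_table(DEFAULT_INDUCTION, times=times)

t_half_true = 9.0
print(f"true residence time: {t_half_true} min\n")

for label, sigma in [("noiseless", 0.0), ("sigma_log2 = 0.1", 0.1)]:
    series = make_scaled_series(t_half_true, DEFAULT_INDUCTION, times,
                                sigma_log2=sigma, seed=42)
    fit = estimate_residence_time(series, DEFAULT_INDUCTION, table)
    print(f"{label}:")
    print(f"  ideal-induction fit  t1/2 = {LN2 / fit.k_d_ideal:6.2f} min (biased)")
    print(f"  final estimate       t1/2 = {fit.t_half:6.2f} min "
          f"(k_d = {fit.k_d:.4f}/min, stages: {' -> '.join(fit.method_trace)})")

print()
print("The ideal-induction fit is systematically biased because the real")
print("competitor rises over ~60 min rather than instantly; the lookup table")
print("and Newton stages remove that bias using the exact kinetics.")
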