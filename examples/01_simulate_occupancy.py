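"""Forward model: how the occupancy ratio lags the induction curve.

Simulates the competitor/endogenous occupancy ratio theta_B/theta_A for
loci with fast, medium and slow chromatin exchange under the fitted TBP
induction curve (saturation 2.23, half-time 22 min, Hill n = 4).  The
slower the exchange (longer residence time), the further the ratio curve is
shifted right of the induction curve — the delay is what makes residence
times recoverable from competition ChIP.
"""

import numpy as np

from compchip import DEFAULT_INDUCTION, KineticModel, eval_induction, simulate_occupancy

times = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0])
print("time_min  rho(t)   t1/2=1min  t1/2=10min  t1/2=70min")
curves = {
    t_half: simulate_occupancy(
        KineticModel(k_a=0.01, k_d=np.log(2) / t_half), DEFAULT_INDUCTION, times)
    for t_half in (1.0, 10.0, 70.0)
}
for i, t in enumerate(times):
    rho = eval_induction(DEFAULT_INDUCTION, t)
    print(f"{t:8.0f}  {rho:6.3f}   {curves[1.0][i]:9.3f}  {curves[10.0][i]:10.3f}"
          f"  {curves[70.0][i]:10.3f}")

print()
print("A 1-minute locus tracks the soluble ratio rho(t) almost exactly; a")
print("70-minute locus reaches only ~0.5 by 60 min although rho is near 2.2 —")
print("the lag between the two curves encodes the residence time.")
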