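"""Fit the FvCB model to one A-Ci curve and read off the capacity estimates.

Simulates a 13-step CO2-response curve with realistic instrument noise
(sd 0.5 umol m-2 s-1) from known parameters, then fits it back.
"""

from leafn import FvCBParams, fit_aci
from leafn.synthetic import generate_aci_curve

true = FvCBParams(vcmax=60.0, jmax=120.0, rd=1.0)
curve = generate_aci_curve(true, noise_sd=0.5, seed=7, sample_id="demo")
fit = fit_aci(curve)

print(f"true:   Vcmax=60.00  Jmax=120.00  Rd=1.00")
print(f"fitted: Vcmax={fit.vcmax:.2f}  Jmax={fit.jmax:.2f}  Rd={fit.rd:.2f}")
print(f"transition Ci: {fit.transition_ci:.0f} umol mol-1 "
      f"({fit.n_points_c} Rubisco-limited points, {fit.n_points_j} RuBP-limited)")
print(f"residual sse: {fit.sse:.3f} (umol m-2 s-1)^2")
print("\nVcmax is the maximum Rubisco carboxylation rate, Jmax the maximum")
print("electron transport rate; both feed the nitrogen partition directly.")
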