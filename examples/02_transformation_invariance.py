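"""Demonstrate the workflow's central robustness property.

The Step-1 probit uses only the within-subject ordering of the outcomes, so
its estimate is bit-identical whether you analyse y, log(y) or cbrt(y) —
only the scale steps (2 and 3) change.
"""

import numpy as np

from cprobit import SimulationConfig, build_paired_dataset, fit_step1, fit_step2, generate_study2

config = SimulationConfig(n_subjects=500, beta=-0.06, true_lambda=0.0, seed=7)
records = generate_study2(config, replicate_seed=7)

for name, g in [("raw", lambda y: y), ("log", np.log), ("cbrt", np.cbrt)]:
    transformed = [r._replace(outcome=float(g(r.outcome))) for r in records]
    data = build_paired_dataset(transformed)
    s1 = fit_step1(data)
    s2 = fit_step2(data, s1)
    print(f"{name:>4}: beta_c = {s1.beta_c_hat[-1]: .6f}   "
          f"sigma_delta = {s2.sigma_delta_hat:10.4f}   "
          f"beta = {s2.beta_hat[-1]: .4f}   Lilliefors p = {s2.lilliefors_p:.3g}")

print()
print("beta_c is identical across rows (ordering-based), while the scale,")
print("the observed-scale effect and the normality diagnostic all depend on")
print("the scale you feed in — that is why Step 3 exists.")
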