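"""Conversion risk for minor-allele carriers with death as a competing event.

Estimates cumulative incidence of conversion per carrier group
(Aalen-Johansen) and the carrier subdistribution hazard ratio (Fine-Gray).
"""

import numpy as np

from dpscore import HazardSpec, SimulationConfig, cif_estimate, fine_gray
from dpscore.simulate import simulate_study

cfg = SimulationConfig(
    n_subjects=1500, n_variants=20, seed=7,
    hazards=HazardSpec(conversion_rate=0.08, carrier_hazard_ratio=0.6,
                       death_rate=0.04, censor_time=10.0))
study = simulate_study(cfg)
surv = study["survival"]

cif = cif_estimate(surv, event=1, by="carrier")
for grp, curve in sorted(cif.items()):
    label = "carriers    " if grp == 1 else "non-carriers"
    print(f"{label}: 10-year conversion incidence = {curve['cif'].iloc[-1]:.2f}")

res = fine_gray(surv, covariate_cols=("carrier",))
lo, hi = res["ci"]
print(f"\nsubdistribution HR (carrier vs non-carrier): "
      f"{res['hr']:.3f}  (95% CI {lo:.3f}-{hi:.3f}, p = {res['p']:.2g})")
print(f"events: {res['n_events']} conversions among {res['n']} subjects")
print("\nAn HR below 1 means carrying the minor allele is protective against")
print("conversion even after accounting for death as a competing risk;")
print("the generative hazard ratio here is 0.6.")
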