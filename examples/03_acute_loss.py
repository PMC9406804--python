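"""Acute follicle loss (e.g. gonadotoxic chemotherapy) at age 12.

Halving a median-supply woman's reserve at age 12 advances her menopause:
the surviving follicles keep the same exit-time law, so the reserve simply
runs out of follicles sooner.
"""

import numpy as np

from pfwalk import ContinuousParams, InterventionEvent, SubjectSpec, simulate_subject

params = ContinuousParams()
N = round(np.exp(12.686))

anm_base, anm_loss = [], []
for seed in range(50):
    base = SubjectSpec(starting_supply=N)
    loss = SubjectSpec(starting_supply=N,
                       interventions=(InterventionEvent(age=12.0,
                                                        surviving_fraction=0.5),))
    anm_base.append(simulate_subject(base, params, rng=seed).anm)
    anm_loss.append(simulate_subject(loss, params, rng=seed).anm)

print(f"mean ANM, uninterrupted decay : {np.mean(anm_base):.2f} yr")
print(f"mean ANM, 50% loss at age 12  : {np.mean(anm_loss):.2f} yr")
print(f"acceleration                  : {np.mean(anm_base) - np.mean(anm_loss):.2f} yr")
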