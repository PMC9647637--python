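"""TLS maturation stage vs TIL counts with a random-intercept mixed model.

Simulates a cohort with a planted stage effect of 0.7 on the log scale,
fits log(TILs) ~ stage with a per-lesion random intercept by REML and
prints the Wald test of the fixed effect.
"""

import pandas as pd

from tmefib.stats import fit_random_intercept_lmm, log_transform
from tmefib.synth import CohortGenParams, generate_cohort

params = CohortGenParams(n_lesions=200)
_, _, tumors = generate_cohort(params, seed=11)
prox = tumors[tumors.proximity == "proximal"]

y = log_transform(prox.til_count.to_numpy())
X = pd.DataFrame(
    {"const": 1.0, "primary_stage": (prox.nearest_tls_stage == "primary").astype(float)}
)
fit = fit_random_intercept_lmm(y, X, prox.lesion_id.to_numpy(), group_name="lesion")
print(fit.summary())
print(f"\nplanted stage effect: {params.til_beta_primary}")
# The primary_stage coefficient estimates the planted 0.7 (tumors near
# mature primary TLS carry ~e^0.7 ~ 2x the TILs of aggregate-stage ones);
# the per-lesion variance absorbs lesion-level TIL baseline differences.
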