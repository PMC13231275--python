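"""Generate one synthetic G-E interaction replicate and inspect its structure.

The generator draws p=100 gene-expression-like features with AR(0.25)
correlation, five environmental variables (three continuous, two binary), 15
important main effects and 15 interactions with the first environmental
variable, and discretizes a partially nonlinear latent response into K=3
ordered classes at quantile thresholds.
"""

import numpy as np

from osnn import SimulationConfig, generate_dataset

config = SimulationConfig(n_train=300, rho_ar=0.25, seed=42)
train, val, test, truth = generate_dataset(config)

print(f"train: {train.n} x (p={train.p} G variables, q={train.q} E variables, "
      f"{train.R.shape[1]} interactions)")
print(f"class counts (train): {np.bincount(train.y)[1:]}")
print(f"important main effects: {truth.important_main.tolist()}")
print(f"important interactions (feature, e-variable): {list(truth.important_inter)[:5]} ...")
print(f"active main coefficients in [{truth.main_coefs[truth.important_main].min():.2f}, "
      f"{truth.main_coefs[truth.important_main].max():.2f}] (drawn from U(0.6, 0.9))")
print(f"latent thresholds: {np.round(truth.thresholds, 3)}")
# The thresholds are the 1/3 and 2/3 quantiles of the pooled latent variable,
# so the three ordinal classes are approximately balanced.
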