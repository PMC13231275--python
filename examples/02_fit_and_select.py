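"""Fit the ordinal sparse network on one replicate and read off the selection.

Trains with the hierarchical sparse-group MCP penalty and the LQA algorithm,
then thresholds the sparse layer: a main effect is kept iff its group norm
||kappa_j|| exceeds tau, an interaction iff additionally |eta_jd| > tau — so the
reported model always obeys strong hierarchy.
"""

import numpy as np

from osnn import (
    ModelConfig,
    PenaltyConfig,
    SimulationConfig,
    TrainConfig,
    fit,
    generate_dataset,
    predict_proba,
    select_variables,
)
from osnn.metrics import prediction_metrics, selection_rates

train, val, test, truth = generate_dataset(SimulationConfig(n_train=300, rho_ar=0.25, seed=11))

result = fit(
    train,
    ModelConfig(K=3, hidden=(128, 128)),
    PenaltyConfig(lambda_ridge=1e-2, lambda_group=0.2, lambda_indiv=0.1),
    TrainConfig(optimizer="adam", learning_rate=0.01, max_iters=600, tol=1e-5, seed=42),
)
print(f"converged={result.converged} after {result.n_iters} iterations; "
      f"objective {result.objective_trace[0]:.3f} -> {result.objective_trace[-1]:.3f}")

sel = select_variables(result, tau=1e-2)
rates = selection_rates(sel, truth, p=train.p, q=train.q)
print(f"selected {len(sel.main_selected)} main effects "
      f"(TPR {rates.tpr_main:.2f}, FPR {rates.fpr_main:.3f})")
print(f"selected {len(sel.inter_selected)} interactions "
      f"(TPR {rates.tpr_inter:.2f}, FPR {rates.fpr_inter:.3f})")

pm = prediction_metrics(predict_proba(test, result.model), test.y)
print(f"test macro-AUC {pm.macro_auc:.3f}, RPS {pm.rps:.3f}, accuracy {pm.accuracy:.3f}")
# A high main-effect TPR at zero FPR means the sparse layer recovered most of
# the truly important features without false positives; interactions are much
# harder at n=300 (their signal is diluted by the product structure), matching
# the main-vs-interaction gap seen in selection studies.  Macro-AUC around 0.8
# shows the ordinal head ranks the three stages far better than chance.
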