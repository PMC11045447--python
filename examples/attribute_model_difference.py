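"""Which gamble features explain the lab/online model disagreement?

Trains a random forest on each synthetic family, regresses the per-problem
prediction difference on nested feature groups, and computes Kernel-SHAP
attributions of the difference over the base features.  Psychological
features (dominance, probability-of-better-outcome) should explain far more
of the difference than raw gamble parameters, because the injected noise
acts on the choice probabilities, not on the payoffs.
"""

import numpy as np

from choicebias import BeastConfig, SynthConfig, split_train_test, train_model
from choicebias.analysis import difference_shap, nested_group_regressions, per_feature_table
from choicebias.features import feature_table
from choicebias.synth import make_paired_datasets
from choicebias.transfer import nn_difference

config = SynthConfig(n_problems=400, seed=7, n_blocks=1, n_participants=15,
                     noise_f=0.6, noise_p_guess=0.25)
lab, online = make_paired_datasets(config, BeastConfig(n_agents=1000, seed=8))
lab_train, _ = split_train_test(lab, 0.8, seed=1)
online_train, _ = split_train_test(online, 0.8, seed=1)
model_lab = train_model("rf", lab_train, seed=0)
model_online = train_model("rf", online_train, seed=0)

problems = [o.problem for o in online]
diff = nn_difference(model_lab, model_online, problems)
features = feature_table(problems)

print("nested group regressions of the model difference:")
print(nested_group_regressions(features, diff).round(4).to_string(index=False))

top = per_feature_table(features, diff).nlargest(5, "r2")
print("\ntop single features by R^2 (95% CI):")
print(top.round(3).to_string(index=False))

# explain shapeless problems: their base features describe them completely,
# so the difference function on the base-feature space is exact
from choicebias import LotShape

flat = [p for p in problems if p.lot_shape_b is LotShape.NONE][:12]
flat_diff = nn_difference(model_lab, model_online, flat)
shap_frame, base = difference_shap(model_lab, model_online, flat,
                                   n_background=12, max_samples=256, seed=0)
print(f"\nSHAP base value {base:+.4f}; mean |attribution| per base feature:")
print(shap_frame.abs().mean().round(4).to_string())
recon = base + shap_frame.sum(axis=1).to_numpy()
print(f"max local-accuracy error: {np.abs(recon - flat_diff).max():.2e}")
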