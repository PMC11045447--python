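"""Dataset bias in miniature: train on one family, test on the other.

Generates a lab-like dataset (BEAST agent simulation) and an online-like
twin (the same problems, rates corrupted by guessing + log-odds noise and
binomial sampling), trains a random forest on each family, and cross-tests.
Own-family test error being visibly smaller than cross-family error is the
classic dataset-bias signature.
"""

from choicebias import BeastConfig, SynthConfig, split_train_test, train_model
from choicebias.synth import make_paired_datasets
from choicebias.transfer import transfer_matrix

config = SynthConfig(n_problems=400, seed=7, n_blocks=1, n_participants=15,
                     noise_f=0.6, noise_p_guess=0.25)
lab, online = make_paired_datasets(config, BeastConfig(n_agents=1000, seed=8))

lab_train, lab_test = split_train_test(lab, 0.8, seed=1)
online_train, online_test = split_train_test(online, 0.8, seed=1)

models = {
    "rf_lab": train_model("rf", lab_train, seed=0),
    "rf_online": train_model("rf", online_train, seed=0),
}
table = transfer_matrix(models, {
    "lab_test": lab_test, "online_test": online_test,
})
print("MSE x 100 per (model, test split):")
print(table.round(2).to_string())
print("\nEach model is best on its own family: the off-diagonal excess is")
print("the transfer penalty induced by the injected decision noise.")
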