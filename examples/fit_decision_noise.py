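"""Infer the decision-noise parameters and validate by parameter recovery.

Online-like rates are generated from lab-like rates at known noise
parameters (f = 0.6, p_guess = 0.25); the Bayesian noise model then
re-infers them from the corrupted counts alone.  Recovery of the truth
inside a tight posterior is the package's core self-check.
"""

from choicebias import RecoveryConfig, run_recovery_experiment

report = run_recovery_experiment(RecoveryConfig().reseeded(1))

print(f"truth:          f = {report.truth.f:.4f}, p_guess = {report.truth.p_guess:.4f}")
print(f"posterior mean: f = {report.posterior_mean.f:.4f}, "
      f"p_guess = {report.posterior_mean.p_guess:.4f}")
print(f"posterior s.d.: f = {report.sd_f:.4f}, p_guess = {report.sd_p_guess:.4f}")
print(f"95% interval f:       [{report.interval_f[0]:.4f}, {report.interval_f[1]:.4f}]"
      f"  contains truth: {report.truth_in_interval_f}")
print(f"95% interval p_guess: [{report.interval_p_guess[0]:.4f}, "
      f"{report.interval_p_guess[1]:.4f}]  contains truth: {report.truth_in_interval_p_guess}")
print(f"sampler converged: {report.converged};  recovery passed: {report.passed}")
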