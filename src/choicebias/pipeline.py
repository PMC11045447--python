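"""End-to-end orchestration: synthesize -> model -> noise fit -> recovery.

The recovery experiment is the package's self-validation loop: generate a
lab-like dataset with BEAST, corrupt it with known noise parameters,
re-infer those parameters with the noise model, and check that the truth is
recovered (posterior means close, truth inside the central 95% credible
interval).  A transfer check on the same paired data reports the
dataset-bias signature (a model evaluated on its own family beats its
cross-family transfer).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .beast import BeastConfig
from .data import split_train_test
from .models import train_model
from .noise import NoiseParams, SamplerConfig, fit_noise_model, mixture_predict
from .synth import SynthConfig, make_paired_datasets
from .transfer import evaluate, mse100, nn_difference

__all__ = [
    "RecoveryConfig",
    "RecoveryReport",
    "run_recovery_experiment",
    "load_config",
    "default_config_text",
]


@dataclass(frozen=True)
class RecoveryConfig:
    synth: SynthConfig = field(default_factory=lambda: SynthConfig(
        n_problems=1000, n_participants=100, n_blocks=1,
        noise_f=0.6, noise_p_guess=0.25))
    beast: BeastConfig = field(default_factory=lambda: BeastConfig(n_agents=1000))
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    mean_tolerance: float = 0.05
    with_transfer_check: bool = False
    seed: int = 0

    def reseeded(self, seed: int) -> "RecoveryConfig":
        return dataclasses.replace(
            self, seed=seed,
            synth=dataclasses.replace(self.synth, seed=seed),
            beast=dataclasses.replace(self.beast, seed=seed + 1),
            sampler=dataclasses.replace(self.sampler, seed=seed + 2))


@dataclass(frozen=True)
class RecoveryReport:
    truth: NoiseParams
    posterior_mean: NoiseParams
    sd_f: float
    sd_p_guess: float
    interval_f: tuple
    interval_p_guess: tuple
    error_f: float
    error_p_guess: float
    truth_in_interval_f: bool
    truth_in_interval_p_guess: bool
    converged: bool
    passed: bool
    transfer: dict | None = None

    def as_dict(self) -> dict:
        out = {
            "truth": {"f": self.truth.f, "p_guess": self.truth.p_guess},
            "posterior_mean": {"f": self.posterior_mean.f,
                               "p_guess": self.posterior_mean.p_guess},
            "posterior_sd": {"f": self.sd_f, "p_guess": self.sd_p_guess},
            "interval_95": {"f": list(self.interval_f),
                            "p_guess": list(self.interval_p_guess)},
            "abs_error": {"f": self.error_f, "p_guess": self.error_p_guess},
            "truth_in_interval": {"f": self.truth_in_interval_f,
                                  "p_guess": self.truth_in_interval_p_guess},
            "converged": self.converged,
            "passed": self.passed,
        }
        if self.transfer is not None:
            out["transfer"] = self.transfer
        return out


def run_recovery_experiment(config: RecoveryConfig | None = None) -> RecoveryReport:
    """Generate paired data at known noise parameters and re-infer them.

    The noise posterior is fitted on the true lab rates (isolating the
    inference machinery from model error).  With ``with_transfer_check`` a
    random-forest pair is additionally trained on the two families and the
    dataset-bias signature plus the noise-augmentation improvement are
    reported.
    """
    cfg = config or RecoveryConfig()
    truth = NoiseParams(f=cfg.synth.noise_f, p_guess=cfg.synth.noise_p_guess)
    lab, online = make_paired_datasets(cfg.synth, cfg.beast)

    p_lab = np.array([o.b_rate for o in lab])
    n = cfg.synth.n_participants
    counts = np.rint(np.array([o.b_rate for o in online]) * n).astype(int)
    posterior = fit_noise_model(p_lab, counts, n, cfg.sampler)

    iv_f = posterior.interval("f")
    iv_p = posterior.interval("p_guess")
    err_f = abs(posterior.mean.f - truth.f)
    err_p = abs(posterior.mean.p_guess - truth.p_guess)
    in_f = iv_f[0] <= truth.f <= iv_f[1]
    in_p = iv_p[0] <= truth.p_guess <= iv_p[1]
    passed = (err_f <= cfg.mean_tolerance and err_p <= cfg.mean_tolerance
              and in_f and in_p and posterior.converged)

    transfer = None
    if cfg.with_transfer_check:
        transfer = _transfer_check(lab, online, posterior.mean, cfg.seed)

    return RecoveryReport(
        truth=truth, posterior_mean=posterior.mean,
        sd_f=posterior.sd_f, sd_p_guess=posterior.sd_p_guess,
        interval_f=iv_f, interval_p_guess=iv_p,
        error_f=err_f, error_p_guess=err_p,
        truth_in_interval_f=in_f, truth_in_interval_p_guess=in_p,
        converged=posterior.converged, passed=passed, transfer=transfer)


def _transfer_check(lab, online, fitted: NoiseParams, seed: int) -> dict:
    """Dataset-bias signature + noise augmentation gain on the paired data."""
    lab_train, lab_test = split_train_test(lab, 0.8, seed)
    on_train, on_test = split_train_test(online, 0.8, seed)
    model_lab = train_model("rf", lab_train, seed=seed)
    model_online = train_model("rf", on_train, seed=seed)

    on_test_problems = [o.problem for o in on_test]
    on_test_rates = np.array([o.b_rate for o in on_test])
    raw = mse100(model_lab.predict(on_test_problems), on_test_rates)
    noised = mse100(
        mixture_predict(np.asarray(model_lab.predict(on_test_problems)), fitted),
        on_test_rates)
    diff = nn_difference(model_lab, model_online, on_test_problems)
    return {
        "lab_model_own_test": evaluate(model_lab, lab_test),
        "lab_model_cross_test": raw,
        "lab_model_cross_test_noised": noised,
        "online_model_own_test": evaluate(model_online, on_test),
        "online_model_cross_test": evaluate(model_online, lab_test),
        "model_difference_mse100": float(100.0 * np.mean(diff**2)),
    }


# ---------------------------------------------------------------------------
# Flat YAML config
# ---------------------------------------------------------------------------

_SECTIONS = {"synth": SynthConfig, "beast": BeastConfig, "sampler": SamplerConfig}


def default_config_text() -> str:
    """All configurable keys with their defaults, as flat YAML."""
    buf = io.StringIO()
    for section, cls in _SECTIONS.items():
        for f in dataclasses.fields(cls):
            default = (f.default_factory() if f.default_factory is not dataclasses.MISSING
                       else f.default)
            if isinstance(default, Mapping):
                default = dict(default)
            if isinstance(default, tuple):
                default = list(default)
            buf.write(f"{section}.{f.name}: {default!r}\n")
    return buf.getvalue()


def load_config(path_or_text) -> RecoveryConfig:
    """Parse a flat ``section.key: value`` YAML file into a RecoveryConfig.

    Unknown keys are rejected; values are validated by the dataclasses'
    own invariant checks.
    """
    if hasattr(path_or_text, "read"):
        raw = yaml.safe_load(path_or_text.read())
    else:
        text = str(path_or_text)
        if "\n" in text or ":" in text:
            raw = yaml.safe_load(text)
        else:
            with open(text) as fh:
                raw = yaml.safe_load(fh)
    raw = raw or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config must be a flat mapping of section.key: value")
    per_section: dict[str, dict] = {s: {} for s in _SECTIONS}
    extras: dict = {}
    for key, value in raw.items():
        if "." in str(key):
            section, name = str(key).split(".", 1)
            if section not in _SECTIONS:
                raise ValueError(f"unknown config section {section!r}")
            valid = {f.name for f in dataclasses.fields(_SECTIONS[section])}
            if name not in valid:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            per_section[section][name] = value
        elif str(key) in ("mean_tolerance", "with_transfer_check", "seed"):
            extras[str(key)] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return RecoveryConfig(
        synth=SynthConfig(**per_section["synth"]),
        beast=BeastConfig(**per_section["beast"]),
        sampler=SamplerConfig(**per_section["sampler"]),
        **extras)
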