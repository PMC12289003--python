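"""Parameter containers and configuration handling.

The single-mediator model has two linear-Gaussian equations:

    M_i ~ Normal(i_m + a * X_i,                      sigma_m)
    Y_i ~ Normal(i_y + c' * X_i + d * Z_i + b * M_i, sigma_y)

where X is the randomized treatment indicator, M the mediator (adverse-event
severity), Y the outcome (fatigue severity) and Z a covariate (stress
severity). The treatment effect decomposes into a direct path c', an indirect
path a*b through the mediator, and the total effect c = c' + a*b.

All configuration objects are frozen dataclasses validated at construction;
:func:`load_config` reads them from a YAML/JSON file and rejects unknown keys.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = [
    "MediationParams",
    "CohortConfig",
    "PriorSpec",
    "MCMCConfig",
    "StudyConfig",
    "RHAT_THRESHOLD",
    "load_config",
    "config_to_dict",
]

#: Split-chain R-hat above this flags a replication as non-converged.
RHAT_THRESHOLD = 1.01


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _finite(name: str, value: float) -> None:
    _require(math.isfinite(value), f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MediationParams:
    """True (or prior-centred) values of the eight model parameters.

    ``a``: treatment -> mediator path; ``b``: mediator -> outcome path;
    ``c_prime``: direct treatment -> outcome path; ``d``: covariate ->
    outcome path; ``i_m``/``i_y``: intercepts; ``sigma_m``/``sigma_y``:
    residual standard deviations (severity units on a nominal 0-10 scale).
    Residual SDs of exactly zero are allowed for noiseless data generation.
    """

    a: float = 0.4
    b: float = 0.5
    c_prime: float = 0.3
    d: float = 0.2
    i_m: float = 1.0
    i_y: float = 2.0
    sigma_m: float = 0.5
    sigma_y: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _finite(f.name, getattr(self, f.name))
        _require(self.sigma_m >= 0, f"sigma_m must be >= 0, got {self.sigma_m}")
        _require(self.sigma_y >= 0, f"sigma_y must be >= 0, got {self.sigma_y}")


@dataclass(frozen=True)
class CohortConfig:
    """One simulated trial cohort: sample size, truth, and rendering knobs.

    ``fatigue_threshold`` drives the yes/no fatigue branch of the dialogue
    router ("Yes" iff Y >= threshold); ``render_precision`` is the number of
    decimals with which severities are written into transcript text (>= 1 so
    round-tripping does not destroy recovery of the data-generating process).
    """

    n_subjects: int = 75
    params: MediationParams = field(default_factory=MediationParams)
    z_mean: float = 5.0
    z_sd: float = 2.0
    fatigue_threshold: float = 3.0
    render_precision: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_subjects >= 4,
                 f"n_subjects must be >= 4 (two per arm), got {self.n_subjects}")
        _require(self.z_sd >= 0, f"z_sd must be >= 0, got {self.z_sd}")
        _require(self.render_precision >= 1,
                 f"render_precision must be >= 1, got {self.render_precision}")
        for name in ("z_mean", "z_sd", "fatigue_threshold"):
            _finite(name, getattr(self, name))


@dataclass(frozen=True)
class PriorSpec:
    """Conjugate prior hyperparameters.

    Each regression coefficient (including intercepts) gets an independent
    Normal(coef_mean, coef_sd^2) prior; each residual variance an
    InverseGamma(sigma2_shape, sigma2_scale) prior. Defaults are weakly
    informative: Normal(0, 10^2) and InverseGamma(0.001, 0.001).
    """

    coef_mean: float = 0.0
    coef_sd: float = 10.0
    sigma2_shape: float = 0.001
    sigma2_scale: float = 0.001

    def __post_init__(self) -> None:
        _require(self.coef_sd > 0, f"coef_sd must be > 0, got {self.coef_sd}")
        _require(self.sigma2_shape > 0,
                 f"sigma2_shape must be > 0, got {self.sigma2_shape}")
        _require(self.sigma2_scale > 0,
                 f"sigma2_scale must be > 0, got {self.sigma2_scale}")
        _finite("coef_mean", self.coef_mean)


@dataclass(frozen=True)
class MCMCConfig:
    """Gibbs sampler settings: chains, retained draws, burn-in, seed."""

    n_chains: int = 4
    n_draws: int = 2000
    n_burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_chains >= 2, f"n_chains must be >= 2, got {self.n_chains}")
        _require(self.n_draws >= 500,
                 f"n_draws must be >= 500 per chain, got {self.n_draws}")
        _require(self.n_burn_in >= 0,
                 f"n_burn_in must be >= 0, got {self.n_burn_in}")


@dataclass(frozen=True)
class StudyConfig:
    """A replicated simulation study over the full pipeline.

    ``use_transcript_path=True`` routes every cohort through
    render -> extract (the full dialogue pipeline); ``False`` feeds the
    ground-truth table straight to the sampler (fast path).
    """

    n_replications: int = 100
    cohort: CohortConfig = field(default_factory=CohortConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    use_transcript_path: bool = True
    master_seed: int = 20240101

    def __post_init__(self) -> None:
        _require(self.n_replications >= 2,
                 f"n_replications must be >= 2, got {self.n_replications}")


_SECTIONS: dict[str, type] = {
    "cohort": CohortConfig,
    "priors": PriorSpec,
    "mcmc": MCMCConfig,
    "study": StudyConfig,
}


def _build(cls: type, data: Mapping[str, Any], context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {context}: {', '.join(unknown)}; "
            f"expected a subset of {sorted(known)}"
        )
    kwargs = dict(data)
    if cls is CohortConfig and isinstance(kwargs.get("params"), Mapping):
        kwargs["params"] = _build(MediationParams, kwargs["params"], "cohort.params")
    try:
        return cls(**kwargs)
    except TypeError as exc:  # wrong value type, e.g. string for a float
        raise ConfigError(f"invalid value in {context}: {exc}") from exc


def load_config(path: str | Path) -> StudyConfig:
    """Read a YAML (or JSON) config file into a fully validated StudyConfig.

    The file may contain any subset of the sections ``cohort``, ``priors``,
    ``mcmc`` and ``study`` (study-level scalars such as ``n_replications`` and
    ``master_seed`` live in ``study``); missing sections take package defaults.
    Unknown keys anywhere raise :class:`ConfigError` naming them.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    unknown = sorted(set(raw) - set(_SECTIONS))
    if unknown:
        raise ConfigError(
            f"unknown section(s) in {path}: {', '.join(unknown)}; "
            f"expected a subset of {sorted(_SECTIONS)}"
        )
    cohort = _build(CohortConfig, raw.get("cohort", {}), "cohort")
    priors = _build(PriorSpec, raw.get("priors", {}), "priors")
    mcmc = _build(MCMCConfig, raw.get("mcmc", {}), "mcmc")
    study_kwargs = dict(raw.get("study", {}))
    for key in ("cohort", "priors", "mcmc"):
        if key in study_kwargs:
            raise ConfigError(f"section '{key}' belongs at top level, not under 'study'")
    study = _build(StudyConfig, study_kwargs, "study")
    return dataclasses.replace(study, cohort=cohort, priors=priors, mcmc=mcmc)


def config_to_dict(config: StudyConfig) -> dict[str, Any]:
    """Resolved, JSON-serializable view of a StudyConfig (for manifests/logs)."""
    d = dataclasses.asdict(config)
    out = {
        "cohort": d.pop("cohort"),
        "priors": d.pop("priors"),
        "mcmc": d.pop("mcmc"),
        "study": d,
    }
    json.dumps(out)  # guarantee serializability
    return out
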