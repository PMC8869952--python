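"""Run configuration: defaults, YAML loading and validation.

A configuration file is a YAML document with up to four sections —
``simulate``, ``moe``, ``selection``, ``characterize`` — each mapping to the
dataclass of the same name.  Unknown keys anywhere are rejected so typos
cannot silently fall back to defaults.  An absent section takes all
defaults; the ``simulate`` section, when present, must carry an explicit
``seed`` because cohort generation is stochastic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def grid_values(min_exp: int = -3, max_exp: int = 10) -> list[float]:
    """Powers of two spanning the hyperparameter search range.

    The default 2^-3 .. 2^10 gives 14 values per parameter, i.e. a 14 x 14
    (C, t) grid of 196 cells.
    """
    if max_exp < min_exp:
        raise ConfigError("grid max_exp must be >= min_exp")
    return [float(2.0**e) for e in range(min_exp, max_exp + 1)]


@dataclass
class SimulateConfig:
    """Synthetic dual-modality cohort parameters (see :mod:`admoe.simulate`)."""

    n_cn: int = 200
    n_ad: int = 180
    effect_size: float = 0.3
    kappa: float = 0.8
    noise_sd: float = 0.1
    seed: int | None = None
    proportions: list[float] | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("simulate.seed is required (stochastic stage)")
        if not 0.0 <= self.kappa <= 1.0:
            raise ConfigError("simulate.kappa must lie in [0, 1]")
        if self.effect_size < 0:
            raise ConfigError("simulate.effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("simulate.noise_sd must be > 0")


@dataclass
class MOEConfig:
    """Hyperparameters of the joint SVM / fuzzy-c-means subtype model.

    K is the number of experts (subtypes); C the penalty on the squared
    hinge loss; t the trade-off between the discriminative (SVM) and
    clustering (FCM) terms; alpha the fuzzification exponent of the centroid
    update (alpha=2 makes the centroid step the exact minimizer of the
    m^2-weighted scatter).  cn_weight is the fixed hinge weight every CN
    subject carries in every expert; d_floor keeps the membership update
    defined when a point coincides with a centroid.
    """

    K: int = 4
    C: float = 0.125
    t: float = 2.0
    alpha: float = 2.0
    tol: float = 1e-6
    max_iter: int = 100
    seed: int = 0
    cn_weight: float = 1.0
    d_floor: float = 1e-12
    init: str = "kmeans"
    standardize_residuals: bool = True
    inner_max_iter: int = 300
    inner_tol: float = 1e-9

    def validate(self) -> None:
        if self.K < 2:
            raise ConfigError("moe.K must be >= 2")
        if self.C <= 0 or self.t <= 0:
            raise ConfigError("moe.C and moe.t must be > 0")
        if self.alpha <= 1:
            raise ConfigError("moe.alpha must be > 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ConfigError("moe.tol must be > 0 and moe.max_iter >= 1")
        if self.init not in ("kmeans", "random"):
            raise ConfigError("moe.init must be 'kmeans' or 'random'")


@dataclass
class SelectionConfig:
    """Grid-search bounds and cross-validation layout."""

    grid_min: int = -3
    grid_max: int = 10
    n_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.grid_max < self.grid_min:
            raise ConfigError("selection.grid_max must be >= grid_min")
        if self.n_folds < 2:
            raise ConfigError("selection.n_folds must be >= 2")

    def c_values(self) -> list[float]:
        return grid_values(self.grid_min, self.grid_max)

    def t_values(self) -> list[float]:
        return grid_values(self.grid_min, self.grid_max)


@dataclass
class CharacterizeConfig:
    """Subtype characterization thresholds."""

    q_threshold: float = 0.05
    correction: str = "bh"
    reference_subtype: int | None = None

    def validate(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ConfigError("characterize.q_threshold must lie in (0, 1)")
        if self.correction not in ("bh", "none"):
            raise ConfigError("characterize.correction must be 'bh' or 'none'")


@dataclass
class AnalysisConfig:
    simulate: SimulateConfig | None = None
    moe: MOEConfig = field(default_factory=MOEConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    characterize: CharacterizeConfig = field(default_factory=CharacterizeConfig)


_SECTIONS = {
    "simulate": SimulateConfig,
    "moe": MOEConfig,
    "selection": SelectionConfig,
    "characterize": CharacterizeConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    obj = cls(**data)
    obj.validate()
    return obj


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML configuration file.

    An empty file yields all defaults (K=4, alpha=2, tol=1e-6, max_iter=100)
    with no simulate section.  Unknown sections or keys raise
    :class:`ConfigError`; a simulate section without a seed raises too.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            data = raw[section] or {}
            if not isinstance(data, dict):
                raise ConfigError(f"section [{section}] must be a mapping")
            kwargs[section] = _build_section(cls, data, section)
    cfg = AnalysisConfig(**kwargs)
    cfg.moe.validate()
    cfg.selection.validate()
    cfg.characterize.validate()
    return cfg
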