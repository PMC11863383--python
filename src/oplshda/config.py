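"""Run configuration: every tunable of the pipeline with validated defaults.

All randomness in a model build flows from two named seeds: ``cv_seed``
(fold construction) and, for synthetic data, the generator seed — there is
no hidden global state, so a build is reproducible from its manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .data_model import ConfigurationError, SCALING_MODES
from .hierarchy import LINKAGES


@dataclass
class RunConfig:
    """Pipeline tunables.

    scaling
        Column preprocessing: ``uv`` (default), ``center``, ``pareto``,
        ``none``.
    cv_folds, cv_seed
        Stratified k-fold cross-validation (default k=7, seed 0).
    max_orth, q2_gain_threshold
        Orthogonal-component search: keep another component only while Q²
        improves by more than the threshold (defaults 5 and 0.01).
    linkage
        Dendrogram linkage (default ``average``/UPGMA; ``ward`` is offered
        but is nonstandard for a non-Euclidean dissimilarity).
    alpha, fold_threshold
        Volcano significance gate: p < alpha and fold change > threshold
        (defaults 0.01 and 2).
    cohens_d_cap
        Finite stand-in distance when the pooled SD is exactly zero.
    impute_missing
        Replace missing cells by column means at load time instead of
        rejecting the file.
    """

    scaling: str = "uv"
    cv_folds: int = 7
    cv_seed: int = 0
    max_orth: int = 5
    q2_gain_threshold: float = 0.01
    linkage: str = "average"
    alpha: float = 0.01
    fold_threshold: float = 2.0
    cohens_d_cap: float = 1e6
    impute_missing: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scaling not in SCALING_MODES:
            raise ConfigurationError(
                f"scaling must be one of {SCALING_MODES}, got {self.scaling!r}")
        if self.cv_folds < 2:
            raise ConfigurationError(
                f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.cv_seed < 0:
            raise ConfigurationError("cv_seed must be >= 0")
        if self.max_orth < 0:
            raise ConfigurationError("max_orth must be >= 0")
        if self.linkage not in LINKAGES:
            raise ConfigurationError(
                f"linkage must be one of {LINKAGES}, got {self.linkage!r}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(
                f"alpha must be in (0, 1), got {self.alpha}")
        if self.fold_threshold < 1:
            raise ConfigurationError(
                f"fold_threshold must be >= 1, got {self.fold_threshold}")
        if self.cohens_d_cap <= 0:
            raise ConfigurationError("cohens_d_cap must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config key {sorted(unknown)[0]!r}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def replace(self, **kwargs) -> "RunConfig":
        d = self.to_dict()
        d.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig.from_dict(d)
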