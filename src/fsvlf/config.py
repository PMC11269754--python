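"""Flat key/value run configuration with lossless YAML round-tripping.

Keys mirror the model's standard symbols (gamma, sigma, A, lam, m, Bi, alpha,
K, iters) so a config file reads like the parameter block of a methods
section.  Validation at this layer enforces the physical ranges, including
Bi > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from .basis import BasisParams
from .solver import ModelSpec, SolverConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Model, solver and output settings of one solver run."""

    gamma: float = 2.0
    sigma: float = 1.0
    A: float = 2.0
    lam: float = 1.0
    m: float = 1.0
    Bi: float = 1.0
    alpha: float = 1.0
    K: int = 6
    iters: int = 6
    tol: float = 1e-14
    precision: str = "double"
    n_grid: int = 2001

    def validate(self) -> "RunConfig":
        checks = [
            ("gamma", 1.0 < self.gamma <= 2.0, "must lie in (1, 2]"),
            ("sigma", 0.0 < self.sigma <= 1.0, "must lie in (0, 1]"),
            ("lam", self.lam >= 0, "must be nonnegative"),
            ("Bi", self.Bi > 0, "must be positive (Biot number)"),
            ("alpha", self.alpha > 0, "must be positive"),
            ("K", self.K >= 0, "must be nonnegative"),
            ("iters", self.iters >= 1, "must be >= 1"),
            ("tol", self.tol > 0, "must be positive"),
            ("precision", self.precision in ("double", "extended"), "must be 'double' or 'extended'"),
            ("n_grid", self.n_grid >= 2, "must be >= 2"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigError(f"field {name!r} {msg} (got {getattr(self, name)!r})")
        return self

    def model(self) -> ModelSpec:
        return ModelSpec(gamma=self.gamma, sigma=self.sigma, A=self.A,
                         lam=self.lam, m=self.m, Bi=self.Bi)

    def solver(self) -> SolverConfig:
        return SolverConfig(
            basis=BasisParams(K=self.K, alpha=self.alpha),
            n_iters=self.iters, tol=self.tol, precision=self.precision,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()
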