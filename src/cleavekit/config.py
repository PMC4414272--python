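"""Run configuration shared by the CLI and the file writers."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .errors import DomainError


@dataclass(frozen=True)
class RunConfig:
    """Package-wide knobs with their units and defaults.

    Concentrations are micromolar, times minutes, rates 1/min throughout;
    ``units`` is a declaration, not a converter.
    """

    units: str = "uM/min"
    near_complete_threshold: float = 0.95
    category_high: float = 0.90
    category_cleaved: float = 0.10
    category_trace: float = 0.01
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("near_complete_threshold", "category_high",
                     "category_cleaved", "category_trace"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise DomainError(f"{name} must lie in (0,1], got {v!r}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise DomainError("integrator tolerances must be positive")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise DomainError(f"seed must be a non-negative integer, got {self.seed!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise DomainError(f"config file {path} must hold a key/value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Short stable digest of the configuration, for file provenance."""
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
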