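"""Run configuration: one dataclass, YAML round-trip, validated ranges."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All analysis knobs in one serializable place.

    Thresholds carry their scientific meaning: ``cv_threshold`` is the
    peptide acceptance CV cut (0.5 = CV below 50%); the classification
    thresholds are fold changes (> 1) on the bait-normalized ratios;
    ``nominal_level`` is the simultaneous confidence level of the
    odds-ratio family; ``cak_qc_tolerance`` bounds the across-genotype CV
    of the CAK-internal ratios.
    """

    seed: int = 0
    cv_threshold: float = 0.5
    bait_id: str = "Cdk7"
    wildtype_genotype: str = "xpd_wt"
    down_threshold: float = 1.5
    strong_threshold: float = 3.0
    up_threshold: float = 1.5
    nominal_level: float = 0.95
    multiplicity: str = "sidak"
    cak_qc_tolerance: float = 0.2
    reference_genotype: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cv_threshold <= 1:
            raise ValueError("cv_threshold must be in (0, 1]")
        if not 0 < self.nominal_level < 1:
            raise ValueError("nominal_level must be in (0, 1)")
        if self.multiplicity not in ("sidak", "bonferroni"):
            raise ValueError("multiplicity must be 'sidak' or 'bonferroni'")
        for name in ("down_threshold", "strong_threshold", "up_threshold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")
        if not 0 < self.cak_qc_tolerance:
            raise ValueError("cak_qc_tolerance must be positive")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
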