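"""Analysis configuration: family registry, antivenom constants, thresholds."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import reference

__all__ = ["AnalysisConfig", "AntivenomConstants", "DichotomyThresholds", "load_config"]


class AntivenomConstants(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mass_on_column_mg: float = Field(default=reference.ANTIVENOM_MG_ON_COLUMN, gt=0)
    fab2_g_per_L: float = Field(default=reference.FAB2_G_PER_L, gt=0)
    fab2_g_per_vial: float = Field(default=reference.FAB2_G_PER_VIAL, gt=0)


class DichotomyThresholds(BaseModel):
    """Cutoffs for the K49/D49 compositional patterns (molar scale)."""

    model_config = ConfigDict(extra="forbid")

    k49_negligible_molar: float = Field(default=0.05, ge=0)
    k49_d49_high: float = Field(default=1.5, gt=0)
    k49_d49_low: float = Field(default=0.67, gt=0)


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    family_registry: dict[str, float] = Field(
        default_factory=lambda: dict(reference.FAMILY_MASSES_DA)
    )
    antivenom: AntivenomConstants = Field(default_factory=AntivenomConstants)
    n_challenge: int = Field(default=reference.N_CHALLENGE_LD50, gt=1)
    dichotomy: DichotomyThresholds = Field(default_factory=DichotomyThresholds)
    # printed-table rendering precisions (decimal places)
    rounding: dict[str, int] = Field(
        default_factory=lambda: {
            "molar_percent": 3,
            "capacity": 2,
            "potency": 1,
            "vials": 1,
            "percent_neutralizing": 2,
        }
    )

    @field_validator("family_registry")
    @classmethod
    def _masses_positive(cls, v: dict[str, float]) -> dict[str, float]:
        bad = {k: m for k, m in v.items() if m <= 0}
        if bad:
            raise ValueError(f"molecular masses must be > 0: {bad}")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a JSON configuration, filling defaults for missing keys.

    Unknown top-level keys warn and are dropped rather than erroring, so a
    config written by a newer version still loads.
    """
    if path is None:
        return AnalysisConfig()
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    known = set(AnalysisConfig.model_fields)
    unknown = set(raw) - known
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown config keys {sorted(unknown)}",
            stacklevel=2,
        )
    return AnalysisConfig(**{k: v for k, v in raw.items() if k in known})
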