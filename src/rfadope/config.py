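"""Validated run configuration for end-to-end simulations.

A :class:`RunConfig` captures everything a coupled run needs: geometry
selection, dopant kind and concentration, protocol, discretization and
output destination.  Defaults equal the study conditions wherever the study
states a value.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import properties as props
from .geometry import Geometry2DAxi, phantom_geometry, tissue_geometry
from .thermal import ProtocolSpec

__all__ = ["RunConfig"]

_TISSUE_ZONES_CM = (0.0, 2.0, 3.0, 4.0)


class RunConfig(BaseModel):
    """Schema-validated configuration of one ablation (or phantom) run."""

    kind: Literal["tissue", "phantom"] = "tissue"
    dopant: Literal["none", "nacl", "aunp"] = "none"
    concentration_pct: float = Field(0.0, ge=0.0, le=10.0)
    doped_zone_cm: float = 0.0
    v_applied: float = Field(50.0, ge=0.0, le=200.0)
    max_duration: float = Field(720.0, gt=0.0)
    time_step: float = Field(0.1, gt=0.0)
    rolloff_threshold: float = Field(100.0, gt=0.0)
    coolant_temperature: float = 8.0
    initial_temperature: float = 37.0
    cooling: Literal["dirichlet", "convective"] = "dirichlet"
    h_coolant: float = Field(2400.0, gt=0.0)
    refinement: int = Field(2, ge=1, le=4)
    sigma_temp_coeff: float = 0.015
    sigma_temp_model: Literal["exponential", "linear"] = "exponential"
    out_dir: str | None = None
    seed: int = 0

    @field_validator("doped_zone_cm")
    @classmethod
    def _zone_supported(cls, v: float) -> float:
        if not any(abs(v - z) < 1e-9 for z in _TISSUE_ZONES_CM):
            raise ValueError(
                f"doped_zone_cm must be one of {_TISSUE_ZONES_CM}, got {v}"
            )
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "RunConfig":
        if self.dopant != "none" and self.concentration_pct <= 0:
            raise ValueError("doped runs need a positive concentration")
        if self.dopant != "none" and self.kind == "tissue" and self.doped_zone_cm == 0:
            raise ValueError("doped tissue runs need a doped zone diameter")
        return self

    # -- factories -------------------------------------------------------
    def geometry(self) -> Geometry2DAxi:
        if self.kind == "phantom":
            return phantom_geometry()
        return tissue_geometry(self.doped_zone_cm / 100.0)

    def doped_props(self) -> props.DopedTissueProps | None:
        if self.dopant == "none" or self.concentration_pct == 0:
            return None
        dopant = props.NACL_09PCT if self.dopant == "nacl" else props.AUNP_COLLOID
        return props.doped_tissue_props(
            props.LIVER_TISSUE, dopant, self.concentration_pct / 100.0
        )

    def protocol(self) -> ProtocolSpec:
        return ProtocolSpec(
            v_applied=self.v_applied,
            max_duration=self.max_duration,
            rolloff_threshold=self.rolloff_threshold,
            time_step=self.time_step,
            coolant_temperature=self.coolant_temperature,
            initial_temperature=self.initial_temperature,
            cooling=self.cooling,
            h_coolant=self.h_coolant,
        )

    def thermal_law(self) -> props.ThermalLawParams:
        return props.ThermalLawParams(
            sigma_temp_coeff=self.sigma_temp_coeff,
            sigma_temp_model=self.sigma_temp_model,
        )

    # -- provenance ------------------------------------------------------
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(exclude={"out_dir"}), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.model_dump(), f)
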