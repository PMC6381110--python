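"""Validated pipeline configuration and tabular/JSON I/O.

All run configuration arrives as one JSON document validated against the
pydantic schema below before any computation; unknown keys are rejected so
typos fail loudly.  Traces travel as two-column CSV (``time_s,
signal_au``), calibrations as small JSON objects, fit reports as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .composition import LipidSpecies, LiposomeComposition
from .kinetics import KineticScheme, VelocityModelParams
from .signals import FluorescenceCalibration, FluorescenceTrace
from .synth import NoiseModel, ScenarioConfig

__all__ = [
    "ComponentConfig",
    "CompositionConfig",
    "CalibrationConfig",
    "ConditionParams",
    "NoiseConfig",
    "ScenarioBlock",
    "PipelineConfig",
    "load_config",
    "config_hash",
    "read_trace_csv",
    "write_trace_csv",
    "read_calibration_json",
    "write_calibration_json",
    "read_scheme_json",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ComponentConfig(_Strict):
    name: str
    mole_percent: float = Field(ge=0, le=100)
    accessible_fraction: float = Field(default=1.0, gt=0, le=1)
    role: Literal["structural", "fret_probe", "cargo", "doped_pip"] = "structural"


class CompositionConfig(_Strict):
    total_lipid_uM: float = Field(gt=0)
    components: list[ComponentConfig]

    def build(self) -> LiposomeComposition:
        doped = [
            (LipidSpecies(c.name, c.accessible_fraction, c.role), c.mole_percent)
            for c in self.components
        ]
        return LiposomeComposition.from_doping(self.total_lipid_uM, doped)


class CalibrationConfig(_Strict):
    F0: float
    Fref: float
    accessible_uM: float = Field(ge=0)
    assay: Literal["dhe_binding", "pip_binding", "dhe_transport", "pip_transport"]

    def build(self) -> FluorescenceCalibration:
        return FluorescenceCalibration(self.F0, self.Fref, self.accessible_uM, self.assay)


class ConditionParams(_Strict):
    K1_uM: float = Field(ge=0)
    k_plus2_per_s: float = Field(ge=0)
    L0_uM: float = Field(gt=0)
    condition: str

    def build(self) -> VelocityModelParams:
        return VelocityModelParams(self.K1_uM, self.k_plus2_per_s, self.L0_uM, self.condition)


class NoiseConfig(_Strict):
    multiplicative_cv: float = Field(default=0.05, ge=0)
    additive_sd: float = Field(default=0.0, ge=0)
    seed: int = 0

    def build(self, seed: Optional[int] = None) -> NoiseModel:
        return NoiseModel(
            self.multiplicative_cv, self.additive_sd,
            self.seed if seed is None else seed,
        )


class ScenarioBlock(_Strict):
    protein_grid_uM: list[float] = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0]
    replicates: int = Field(default=3, ge=1)
    basal: ConditionParams = ConditionParams(
        K1_uM=0.8, k_plus2_per_s=0.05, L0_uM=2.0, condition="basal"
    )
    stimulated: ConditionParams = ConditionParams(
        K1_uM=0.4, k_plus2_per_s=0.1, L0_uM=2.0, condition="plus_PIP"
    )
    duration_s: float = Field(default=600.0, gt=0)
    sampling_hz: float = Field(default=1.0, gt=0)
    temperature_C: float = 15.0

    def build(self, composition: LiposomeComposition) -> ScenarioConfig:
        return ScenarioConfig(
            composition=composition,
            protein_grid=tuple(self.protein_grid_uM),
            basal=self.basal.build(),
            stimulated=self.stimulated.build(),
            duration_s=self.duration_s,
            sampling_hz=self.sampling_hz,
            temperature=self.temperature_C,
        )


class PipelineConfig(_Strict):
    """Top-level run configuration (unknown keys rejected)."""

    composition: CompositionConfig = CompositionConfig(
        total_lipid_uM=200.0,
        components=[
            ComponentConfig(name="DNS-PE", mole_percent=2.5,
                            accessible_fraction=0.5, role="fret_probe"),
            ComponentConfig(name="DHE", mole_percent=5.0,
                            accessible_fraction=1.0, role="cargo"),
        ],
    )
    scenario: ScenarioBlock = ScenarioBlock()
    noise: NoiseConfig = NoiseConfig()
    fit_model: Literal["hyperbolic", "quadratic"] = "quadratic"


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline configuration JSON file."""
    raw = json.loads(Path(path).read_text())
    return PipelineConfig.model_validate(raw)


def config_hash(cfg: PipelineConfig) -> str:
    """SHA-256 of the canonical JSON form, for run provenance."""
    canonical = json.dumps(cfg.model_dump(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Tabular / JSON I/O
# ---------------------------------------------------------------------------

def read_trace_csv(path, signal_column: str = "signal_au") -> FluorescenceTrace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or signal_column not in df.columns:
        raise ValueError(
            f"trace CSV must have columns 'time_s' and {signal_column!r}; "
            f"got {list(df.columns)}"
        )
    return FluorescenceTrace(df["time_s"].to_numpy(float),
                             df[signal_column].to_numpy(float))


def write_trace_csv(path, trace: FluorescenceTrace,
                    signal_column: str = "signal_au") -> None:
    pd.DataFrame({"time_s": trace.times, signal_column: trace.signal}).to_csv(
        path, index=False
    )


def read_calibration_json(path) -> FluorescenceCalibration:
    return CalibrationConfig.model_validate(json.loads(Path(path).read_text())).build()


def write_calibration_json(path, cal: FluorescenceCalibration) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "F0": cal.f0,
                "Fref": cal.fref,
                "accessible_uM": cal.accessible_ligand,
                "assay": cal.assay_kind,
            },
            indent=2,
        )
    )


class _SchemeConfig(_Strict):
    k_plus1: float = Field(ge=0)
    k_minus1: float = Field(ge=0)
    k_plus2: float = Field(ge=0)
    k_minus2: float = Field(default=0.0, ge=0)
    k_plus3: float = Field(default=0.0, ge=0)
    k_minus3: float = Field(default=0.0, ge=0)
    condition: str = "basal"


def read_scheme_json(path) -> KineticScheme:
    cfg = _SchemeConfig.model_validate(json.loads(Path(path).read_text()))
    return KineticScheme(**cfg.model_dump())
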