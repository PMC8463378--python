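"""Model configuration: cohort mix, treatment rates, decay curves, workflow.

Configuration is read from YAML or JSON and validated strictly — unknown
keys are rejected so that a typo cannot silently fall back to a default.
:func:`default_config` ships a complete synthetic parameterisation; the
decay-curve coefficients in it are illustrative placeholders, not
published estimates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .outcome import CohortMix, DecayCurve, TreatmentRates
from .timelines import WorkflowTimes

__all__ = ["ModelConfig", "default_config", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CurveSpec(_Strict):
    kind: Literal["logistic", "linear", "constant"]
    p0: float = Field(ge=0.0, le=1.0)
    p_floor: float = Field(ge=0.0, le=1.0)
    t_max: float = Field(gt=0.0)
    shape: float = Field(default=90.0, gt=0.0)

    def build(self) -> DecayCurve:
        return DecayCurve(self.kind, self.p0, self.p_floor, self.t_max, self.shape)


class CohortMixSpec(_Strict):
    p_lvo: float = 0.6
    p_nlvo: float = 0.3
    p_other: float = 0.1
    p_good_other: float = 0.90
    p_good_lvo_untreated: float = 0.10
    p_good_nlvo_untreated: float = 0.35

    def build(self) -> CohortMix:
        return CohortMix(**self.model_dump())


class TreatmentRatesSpec(_Strict):
    evt_rate: float = 0.90
    ivt_rate: float = 0.80
    ivt_window: float = 270.0

    def build(self) -> TreatmentRates:
        return TreatmentRates(**self.model_dump())


class WorkflowSpec(_Strict):
    onset_to_fmr: float = 30.0
    on_scene: float = 30.0
    dtn_psc: float = 30.0
    ntd_psc: float = 20.0
    dtn_csc: float = 30.0
    dtg_csc: float = 60.0
    dtg_csc_fast: float = 30.0
    reimage_window: float = 90.0
    ntl_dd: float = 10.0
    arr_to_groin_dd: float = 20.0
    imaging_offset_psc: float = 0.0

    def build(self) -> WorkflowTimes:
        return WorkflowTimes(**self.model_dump())


class ModelConfig(_Strict):
    """Top-level model configuration.

    ``delta_mode`` chooses how a reference-route traffic delta generalises
    to other routes: ``"absolute"`` (default) applies the same minutes
    everywhere; ``"proportional"`` scales the delta by the ratio of the
    route's free-flow time to the reference route's free-flow time.
    """

    cohort_mix: CohortMixSpec = CohortMixSpec()
    treatment_rates: TreatmentRatesSpec = TreatmentRatesSpec()
    curves: Dict[str, CurveSpec]
    workflow: WorkflowSpec = WorkflowSpec()
    delta_mode: Literal["absolute", "proportional"] = "absolute"

    @model_validator(mode="after")
    def _check_curves(self) -> "ModelConfig":
        missing = {"evt", "ivt_lvo", "ivt_nlvo"} - set(self.curves)
        if missing:
            raise ValueError(f"missing curve blocks: {sorted(missing)}")
        unknown = set(self.curves) - {"evt", "ivt_lvo", "ivt_nlvo"}
        if unknown:
            raise ValueError(f"unknown curve blocks: {sorted(unknown)}")
        return self

    def build_curves(self) -> Dict[str, DecayCurve]:
        return {k: v.build() for k, v in self.curves.items()}


def default_config() -> ModelConfig:
    """Synthetic default parameterisation (placeholder decay curves)."""
    return ModelConfig(
        curves={
            "evt": CurveSpec(kind="logistic", p0=0.65, p_floor=0.10, t_max=480.0, shape=90.0),
            "ivt_lvo": CurveSpec(kind="logistic", p0=0.30, p_floor=0.10, t_max=270.0, shape=60.0),
            "ivt_nlvo": CurveSpec(kind="logistic", p0=0.60, p_floor=0.35, t_max=270.0, shape=60.0),
        }
    )


def load_config(path) -> ModelConfig:
    """Load and validate a YAML or JSON model configuration file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ModelConfig.model_validate(data)
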