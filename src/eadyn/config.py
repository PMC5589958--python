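"""Run configuration: schema-validated YAML, unknown keys rejected.

All paper-specified protocol values are the defaults (80 pA/pF, 1 ms
pulses, 2000 ms cycle; 1e-8 steady-state criterion; 1% sweep steps); every
tolerance is surfaced.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "build_system"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PacingConfig(_Strict):
    amplitude: float = Field(80.0, ge=0, description="pA/pF")
    duration: float = Field(1.0, gt=0, description="ms")
    cycle_length: float = Field(2000.0, gt=0, description="ms")

    @model_validator(mode="after")
    def _pulse_fits(self):
        if self.duration >= self.cycle_length:
            raise ValueError("duration must be < cycle_length")
        return self


class ModelConfig(_Strict):
    kind: Literal["surrogate", "surrogate_monostable", "forced_linear"] = "surrogate"
    pct_gkr: float = Field(100.0, ge=0)
    pct_gks: float = Field(100.0, ge=0)
    nai_clamp: Optional[float] = None
    pacing: Optional[PacingConfig] = None
    tau: float = Field(1000.0, gt=0, description="forced_linear time constant, ms")


class IntegratorConfig(_Strict):
    rtol: float = Field(1e-8, gt=0)
    atol: float = Field(1e-10, gt=0)
    method: Literal["LSODA", "RK45", "DOP853", "BDF", "Radau"] = "LSODA"
    jac_method: Literal["variational", "fd"] = "fd"


class SimulateConfig(_Strict):
    n_beats: int = Field(10, ge=1)
    to_steady_state: bool = False
    steady_tol: float = Field(1e-8, gt=0)
    max_beats: int = Field(1000, ge=2)


class SweepConfig(_Strict):
    param: str = "pct_gkr"
    start: float
    stop: float
    step: float = Field(1.0, gt=0)
    both_directions: bool = True
    steady_tol: float = Field(1e-8, gt=0)
    max_beats: int = Field(300, ge=2)


class ContinueConfig(_Strict):
    param: str = "pct_gkr"
    start: float
    stop: float
    initial_step: float = Field(0.5, gt=0)
    shoot_tol: float = Field(1e-8, gt=0)
    max_points: int = Field(200, ge=2)
    seed_nai: Optional[float] = None


class CensusConfig(_Strict):
    param: str = "pct_gkr"
    param_values: list[float]
    n_starts: int = Field(22, ge=1)
    seed: int = 0
    steady_tol: float = Field(1e-8, gt=0)
    max_beats: int = Field(250, ge=2)


class ClampScanConfig(_Strict):
    clamp_values: list[float]
    n_starts: int = Field(12, ge=1)
    steady_tol: float = Field(1e-8, gt=0)
    max_beats: int = Field(250, ge=2)


class RunConfig(_Strict):
    model: ModelConfig = ModelConfig()
    integrator: IntegratorConfig = IntegratorConfig()
    simulate: Optional[SimulateConfig] = None
    sweep: Optional[SweepConfig] = None
    continuation: Optional[ContinueConfig] = None
    census: Optional[CensusConfig] = None
    clamp_scan: Optional[ClampScanConfig] = None
    outdir: str = "results"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


def load_config(path) -> tuple[RunConfig, str]:
    """Parse + validate a YAML config; returns (config, raw text)."""
    text = open(path).read()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data), text


def build_system(cfg: RunConfig):
    """Instantiate the configured model behind a stroboscopic flow map."""
    from .pacing_sim import PacedFlowMap
    from .testbed import ForcedLinearModel, _LinearParams
    from .vm_model import MinimalMyocyteModel, ModelParams, PacingProtocol

    pacing = PacingProtocol(
        **(cfg.model.pacing.model_dump() if cfg.model.pacing else {})
    )
    if cfg.model.kind == "forced_linear":
        model = ForcedLinearModel(cfg.model.tau)
        params = _LinearParams(pacing=pacing, tau=cfg.model.tau)
    else:
        overrides = {}
        if cfg.model.kind == "surrogate_monostable":
            overrides["v_f_mid"] = -34.0
        model = MinimalMyocyteModel(**overrides)
        params = ModelParams(
            pct_gkr=cfg.model.pct_gkr,
            pct_gks=cfg.model.pct_gks,
            pacing=pacing,
            nai_clamp=cfg.model.nai_clamp,
        )
    return PacedFlowMap(
        model,
        params,
        rtol=cfg.integrator.rtol,
        atol=cfg.integrator.atol,
        method=cfg.integrator.method,
        jac_method=cfg.integrator.jac_method,
    )
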