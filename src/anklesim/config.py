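"""Configuration schema, loading, and serialization.

A run configuration is a nested YAML/JSON document with sections
``controller``, ``plant``, ``protocol``, ``cohort``, ``stats`` and
``output`` plus a global ``seed`` and ``log_level``.  Unknown keys are
rejected with their full key path; every section materializes its defaults
so an empty file is a complete, valid configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .cohort import TrialConfig
from .controller import ControllerParams
from .errors import ConfigurationError
from .plant import PlantParams
from .training import AssistParams

logger = logging.getLogger("anklesim")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ControllerSection(_Strict):
    Mp: float = 10.0
    Mn: float = 10.0
    Vmin: float = 2.0
    Vmax: float = 20.0
    C: float = 30.0
    theta_p: float = 15.0
    theta_n: float = -30.0
    theta_d: float = 5.0
    hold_pos: float = 5.0
    hold_neg: float = 0.0
    dt: float = 0.0005

    @model_validator(mode="after")
    def _invariants(self):
        ControllerParams(**self.model_dump())  # raises ConfigurationError
        return self

    def to_params(self) -> ControllerParams:
        return ControllerParams(**self.model_dump())


class PlantSection(_Strict):
    preset: str | None = None     # mild / moderate / severe overrides fields
    k1_df: float = 0.5
    k2_df: float = 0.15
    k1_pf: float = 0.4
    k2_pf: float = 0.12
    k_lin: float = 0.6
    theta_slack: float = -5.0
    b: float = 0.02
    g_amp: float = 1.2
    reflex_gain: float = 0.05
    reflex_threshold: float = 5.0
    reflex_severity: float = 1.0
    creep_gain: float = 5e-4
    creep_cap: float = 1.5
    noise_sd: float = 0.02

    def to_params(self) -> PlantParams:
        from .plant import preset_plant
        if self.preset is not None:
            return preset_plant(self.preset)
        data = self.model_dump()
        data.pop("preset")
        return PlantParams(**data)


class ProtocolSection(_Strict):
    stretch_minutes: float = 20.0
    relearn_minutes: float = 15.0
    active_minutes: float = 10.0
    patient_first_delay: float = 2.5
    assist_speed: float = 10.0
    rep_goal: int = 150
    resist_gain: float = 0.0

    def to_assist_params(self) -> AssistParams:
        return AssistParams(patient_first_delay=self.patient_first_delay,
                            assist_speed=self.assist_speed,
                            rep_goal=self.rep_goal,
                            resist_gain=self.resist_gain)


class CohortSection(_Strict):
    n_per_group: int = 9
    sessions_per_week: int = 5
    weeks: int = 3
    study_effect_multiplier: float = 5.0
    control_pf_onset_median: float = 35.0
    control_df_onset_median: float = 100.0
    onset_sigma: float = 0.9
    control_pf_rate: float = 0.08
    control_df_rate: float = 0.03
    pf_capacity_max: float = 3.5
    df_capacity_max: float = 1.2
    noise_sd: float = 0.02

    def to_trial_config(self, seed: int, protocol: ProtocolSection,
                        ) -> TrialConfig:
        return TrialConfig(seed=seed,
                           stretch_minutes=protocol.stretch_minutes,
                           relearn_minutes=protocol.relearn_minutes,
                           active_minutes=protocol.active_minutes,
                           **self.model_dump())


class StatsSection(_Strict):
    alpha: float = 0.05
    rm_correlation: float = 0.5
    effect_f: float = 0.25
    power: float = 0.80
    attrition: float = 0.10


class OutputSection(_Strict):
    directory: str = "anklesim_out"
    log_hz: float = 200.0
    write_session_logs: bool = False


class RunConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    controller: ControllerSection = ControllerSection()
    plant: PlantSection = PlantSection()
    protocol: ProtocolSection = ProtocolSection()
    cohort: CohortSection = CohortSection()
    stats: StatsSection = StatsSection()
    output: OutputSection = OutputSection()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def metadata(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty (or all-comments) file yields all defaults.  Schema violations
    are reported with their dotted key paths.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got "
                                 f"{type(raw).__name__}")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(loc) for loc in err["loc"]) + f": {err['msg']}"
            for err in exc.errors())
        raise ConfigurationError(f"invalid config {path}: {paths}") from exc
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(),
                                      logging.INFO))
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
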