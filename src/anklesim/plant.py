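"""Synthetic viscoelastic/spastic ankle joint.

The plant supplies the resistance torque that the stretching controller and
the training modes consume.  It models, with a handful of parameters:

* a passive torque--angle curve that stiffens exponentially toward both ends
  of the range of motion, with a small linear residual-tone stiffness in the
  mid-range (a spastic hemiplegic ankle is never torque-free even near its
  slack angle);
* velocity-dependent spastic reflex resistance above a velocity threshold;
* viscous damping;
* end-range creep: sustained loading near a torque limit gradually shifts
  the exponential walls outward, the mechanism by which strong stretching
  (and only strong stretching) gains range of motion;
* a gravitational torque component of the foot + foot holder, which the
  robot measures but subtracts before the controller ever sees the torque;
* additive Gaussian torque-sensor noise.

Sign convention (used consistently everywhere): dorsiflexion is the positive
direction, and a *resistance* torque is positive when it opposes motion
toward dorsiflexion.  Viscous drag therefore enters the measured resistance
as ``+b*omega``.  Angles are degrees, torques N·m, time seconds.

The robot's drive is much stiffer than the limb, so the plant is a position
servo: the commanded velocity is enforced exactly and the limb state is the
integrated angle plus internal creep state.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace

from .errors import ConfigurationError, InvalidInputError


@dataclass
class PlantParams:
    """Parameters of the synthetic ankle.

    ``k1_df``/``k2_df`` (gain N·m, rate 1/deg) shape the exponential
    stiffening wall at the dorsiflexion end, ``k1_pf``/``k2_pf`` the
    plantarflexion wall.  ``k_lin`` is the residual-tone stiffness that keeps
    mid-range resistance small but nonzero.  ``creep_gain`` converts
    torque-time of sustained end-range loading into outward shift of the
    wall, capped at ``creep_cap`` per session.
    """

    k1_df: float = 0.5          # Nm, dorsiflexion-end exponential gain
    k2_df: float = 0.15         # 1/deg
    k1_pf: float = 0.4          # Nm, plantarflexion-end exponential gain
    k2_pf: float = 0.12         # 1/deg
    k_lin: float = 0.6          # Nm/deg residual tone stiffness
    theta_slack: float = -5.0   # deg, angle of minimal passive torque
    b: float = 0.02             # Nm·s/deg viscous damping
    g_amp: float = 1.2          # Nm gravitational amplitude of foot+holder
    reflex_gain: float = 0.05   # Nm·s/deg spastic resistance gain
    reflex_threshold: float = 5.0   # deg/s velocity threshold for reflex
    reflex_severity: float = 1.0    # multiplier derived from MAS grade
    creep_gain: float = 5e-4    # deg/(Nm·s)
    creep_cap: float = 1.5      # deg, max cumulative ROM gain per session
    noise_sd: float = 0.02      # Nm torque-sensor noise

    def __post_init__(self) -> None:
        nonneg = (
            "k1_df k2_df k1_pf k2_pf k_lin b g_amp reflex_gain "
            "reflex_threshold reflex_severity creep_gain creep_cap noise_sd"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"plant parameter {name} must be >= 0")


@dataclass
class AnkleState:
    """Kinematic state plus accumulated creep at each end."""

    theta: float = -5.0         # deg
    omega: float = 0.0          # deg/s
    rom_shift_pos: float = 0.0  # deg, creep accrued at dorsiflexion end
    rom_shift_neg: float = 0.0  # deg, creep accrued at plantarflexion end
    time: float = 0.0           # s


def elastic_torque(plant: PlantParams, theta: float,
                   rom_shift_pos: float = 0.0,
                   rom_shift_neg: float = 0.0) -> float:
    """Static passive elastic torque at angle ``theta`` (no damping).

    Linear residual tone about the slack angle plus exponential walls whose
    onset is pushed outward by the accumulated creep shifts.
    """
    x = theta - plant.theta_slack
    tq = plant.k_lin * x
    xe = x - rom_shift_pos
    if xe > 0.0:
        tq += plant.k1_df * math.expm1(plant.k2_df * xe)
    xn = -x - rom_shift_neg
    if xn > 0.0:
        tq -= plant.k1_pf * math.expm1(plant.k2_pf * xn)
    return tq


def passive_torque(plant: PlantParams, state: AnkleState) -> float:
    """Passive resistance: elastic torque plus viscous damping ``+b*omega``."""
    return elastic_torque(plant, state.theta,
                          state.rom_shift_pos, state.rom_shift_neg) \
        + plant.b * state.omega


def reflex_torque(plant: PlantParams, state: AnkleState) -> float:
    """Spastic velocity-dependent resistance.

    Zero below the velocity threshold; above it, grows linearly with the
    excess speed and opposes the motion.  Scaled by the MAS-derived severity
    multiplier.
    """
    excess = abs(state.omega) - plant.reflex_threshold
    if excess <= 0.0:
        return 0.0
    mag = plant.reflex_gain * plant.reflex_severity * excess
    return math.copysign(mag, state.omega)


def gravity_torque(plant: PlantParams, theta: float) -> float:
    """Gravitational torque of foot + holder; measured then subtracted."""
    return plant.g_amp * math.sin(math.radians(theta))


def step_plant(plant: PlantParams, state: AnkleState, velocity_command: float,
               voluntary_torque: float, dt: float,
               torque_limits: tuple[float, float] | None = None,
               rng: random.Random | None = None) -> tuple[AnkleState, float]:
    """Advance the plant one tick under a commanded velocity.

    Returns ``(new_state, m_res)`` where ``m_res`` is the measured resistance
    torque with the gravitational component already subtracted (the robot
    measures the raw torque, removes gravity, and hands the remainder to the
    controller).

    Creep accrues while the measured torque magnitude stays above 90% of the
    relevant active torque limit at the corresponding end, at rate
    ``creep_gain * |torque| * dt``, capped at ``creep_cap``.  Pass
    ``torque_limits=(Mp, Mn)`` to enable it; with ``None`` no creep accrues.
    """
    if dt <= 0.0:
        raise ConfigurationError("dt must be > 0")
    theta = state.theta + velocity_command * dt
    omega = velocity_command
    new = AnkleState(theta=theta, omega=omega,
                     rom_shift_pos=state.rom_shift_pos,
                     rom_shift_neg=state.rom_shift_neg,
                     time=state.time + dt)
    m = passive_torque(plant, new) + reflex_torque(plant, new) - voluntary_torque
    if plant.noise_sd > 0.0 and rng is not None:
        m += rng.gauss(0.0, plant.noise_sd)
    if torque_limits is not None:
        mp, mn = torque_limits
        if theta > plant.theta_slack and m >= 0.9 * mp:
            new.rom_shift_pos = min(plant.creep_cap,
                                    new.rom_shift_pos + plant.creep_gain * m * dt)
        elif theta < plant.theta_slack and m <= -0.9 * mn:
            new.rom_shift_neg = min(plant.creep_cap,
                                    new.rom_shift_neg + plant.creep_gain * (-m) * dt)
    return new, m


class AnklePlant:
    """A plant parameter set bound to an evolving state and noise stream."""

    def __init__(self, params: PlantParams | None = None,
                 state: AnkleState | None = None,
                 seed: int | None = None) -> None:
        self.params = params if params is not None else PlantParams()
        self.state = state if state is not None else AnkleState(
            theta=self.params.theta_slack)
        self.rng = random.Random(seed)

    def step(self, velocity_command: float, voluntary_torque: float, dt: float,
             torque_limits: tuple[float, float] | None = None) -> float:
        """Advance one tick; returns the measured resistance torque."""
        self.state, m = step_plant(self.params, self.state, velocity_command,
                                   voluntary_torque, dt, torque_limits,
                                   self.rng)
        return m

    def measured_resistance(self, voluntary_torque: float = 0.0) -> float:
        """Measured resistance at the current state without advancing time."""
        m = passive_torque(self.params, self.state) \
            + reflex_torque(self.params, self.state) - voluntary_torque
        if self.params.noise_sd > 0.0:
            m += self.rng.gauss(0.0, self.params.noise_sd)
        return m

    def reset_creep(self) -> None:
        self.state.rom_shift_pos = 0.0
        self.state.rom_shift_neg = 0.0

    def copy(self) -> "AnklePlant":
        other = AnklePlant(self.params, replace(self.state))
        other.rng = random.Random()
        other.rng.setstate(self.rng.getstate())
        return other


def estimate_creep_gain(frame, plant: PlantParams, torque_limit: float,
                        min_samples: int = 20) -> float:
    """Recover the creep gain from the hold segments of a session log.

    During a dorsiflexion-end hold the angle is fixed, so the logged torque
    relaxation is entirely due to the creep shift.  Inverting the elastic
    law at constant angle gives the shift trajectory

        s(t) = x - log1p((m(t) - k_lin*x) / k1_df) / k2_df,   x = theta - theta_slack,

    and since ds/dt = creep_gain * m while the load stays above 90% of the
    torque limit, the gain is the total shift over the integrated
    torque-time of the segment.  Returns the mean estimate over all
    admissible hold segments of a (noise-free) log ``frame`` with columns
    ``time_s``, ``theta_deg``, ``torque_nm``, ``velocity_cmd_dps``,
    ``phase``, ``direction``.
    """
    import numpy as np

    hold = (frame["phase"] == "holding").to_numpy() \
        & (frame["direction"].to_numpy() == 1) \
        & (frame["velocity_cmd_dps"].to_numpy() == 0.0) \
        & (frame["torque_nm"].to_numpy() >= 0.9 * torque_limit)
    # split into contiguous segments
    idx = np.nonzero(hold)[0]
    if idx.size == 0:
        raise InvalidInputError("log contains no admissible hold segments")
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    segments = np.split(idx, breaks + 1)
    gains = []
    for seg in segments:
        if len(seg) < min_samples:
            continue
        t = frame["time_s"].to_numpy()[seg]
        m = frame["torque_nm"].to_numpy()[seg]
        x = frame["theta_deg"].to_numpy()[seg].mean() - plant.theta_slack
        arg = (m - plant.k_lin * x) / plant.k1_df
        s = x - np.log1p(arg) / plant.k2_df
        torque_time = np.trapezoid(m, t)
        if torque_time > 0:
            gains.append((s[-1] - s[0]) / torque_time)
    if not gains:
        raise InvalidInputError("no hold segment long enough for estimation")
    return float(np.mean(gains))


def preset_plant(severity: str = "moderate") -> PlantParams:
    """Preset 'mild' / 'moderate' / 'severe' spastic ankle parameter sets."""
    presets = {
        "mild": dict(k1_df=0.35, k1_pf=0.3, k_lin=0.4,
                     reflex_severity=0.5, noise_sd=0.02),
        "moderate": dict(),
        "severe": dict(k1_df=0.8, k1_pf=0.6, k_lin=0.9,
                       reflex_severity=2.0, noise_sd=0.02),
    }
    if severity not in presets:
        raise ConfigurationError(
            f"unknown plant preset {severity!r}; expected one of {sorted(presets)}")
    return PlantParams(**presets[severity])
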