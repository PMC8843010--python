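"""Patient-facing training modes.

Three modes are simulated:

* **Isometric motor relearning** — the robot locks the ankle, the patient
  attempts maximal effort, and the (amplified) torque trace is displayed as
  real-time feedback.  For severe hemiplegia this detects faint re-emerging
  motor output long before any visible movement.
* **Assist-as-needed active movement** — the robot cues a target, waits a
  2–3 s window for the patient to try on their own, then either assists the
  movement (if an attempt was sensed) or demonstrates it.
* **Control-arm session** — passive sinusoidal movement confined to the
  central half of the manually measured ROM (never loading the stiff ends,
  so no creep-driven ROM gain accrues), followed by unassisted active
  attempts with interval breaks.

Patient objects are duck-typed: anything with ``capacity(muscle, day)``
returning a voluntary torque capacity in N·m works (see
:class:`anklesim.cohort.PatientProfile`).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import pandas as pd
from scipy.optimize import brentq

from .controller import SessionLog
from .errors import ConfigurationError
from .plant import AnklePlant, elastic_torque

DEADBAND_DEG = 1.0          # target discrepancy below which no action is taken
ATTEMPT_DETECT_MULT = 3.0   # attempt threshold = mult * torque noise SD


@dataclass
class AssistParams:
    """Assist-as-needed settings for game-based active movement."""

    patient_first_delay: float = 2.5   # s in [2, 3]: patient tries alone first
    assist_speed: float = 10.0         # deg/s toward the target
    resist_gain: float = 0.0           # Nm/deg opposing load (resistance games)
    target_trajectory: Sequence[tuple[float, float]] | None = None
    rep_goal: int = 150                # repetitions per session
    detect_mult: float = ATTEMPT_DETECT_MULT

    def __post_init__(self) -> None:
        if not (2.0 <= self.patient_first_delay <= 3.0):
            raise ConfigurationError("patient_first_delay must lie in [2, 3] s")
        if self.rep_goal <= 0:
            raise ConfigurationError("rep_goal must be > 0")
        if self.assist_speed <= 0:
            raise ConfigurationError("assist_speed must be > 0")


@dataclass(frozen=True)
class FeedbackSample:
    """One sample of the on-screen feedback stream."""

    time: float              # s
    displayed_signal: float  # display units = display_gain * raw torque
    raw_torque: float        # Nm


class RobotAction(NamedTuple):
    kind: Literal["none", "assist", "demonstrate"]
    velocity: float  # deg/s, 0 for "none"


def _effort_envelope(t: float, ramp: float = 1.0) -> float:
    """Voluntary effort builds over ~1 s then plateaus."""
    return min(1.0, t / ramp) if t > 0 else 0.0


def isometric_relearning_trial(plant: AnklePlant, patient, direction: str,
                               duration: float = 5.0, day: float = 0.0,
                               lock_angle: float = 0.0, display_gain: float = 50.0,
                               sample_hz: float = 100.0,
                               rng: random.Random | None = None,
                               ) -> tuple[float, list[FeedbackSample]]:
    """One locked-ankle maximal-effort trial with visual feedback.

    The ankle is held isometric at ``lock_angle`` (velocity forced to zero),
    the patient pushes in ``direction`` ("dorsiflex" or "plantarflex"), and
    the voluntary torque — capacity times an effort envelope, plus sensor
    noise — is sampled at ``sample_hz``.  Returns the peak detected torque
    magnitude in the commanded direction and the feedback stream.
    """
    if direction not in ("dorsiflex", "plantarflex"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    muscle = "df" if direction == "dorsiflex" else "pf"
    rng = rng if rng is not None else plant.rng
    cap = float(patient.capacity(muscle, day))
    noise_sd = plant.params.noise_sd
    n = max(1, int(round(duration * sample_hz)))
    dt = 1.0 / sample_hz
    samples: list[FeedbackSample] = []
    peak = 0.0
    for i in range(n):
        t = (i + 1) * dt
        raw = cap * _effort_envelope(t)
        if noise_sd > 0:
            raw += rng.gauss(0.0, noise_sd)
        samples.append(FeedbackSample(time=t,
                                      displayed_signal=display_gain * raw,
                                      raw_torque=raw))
        if raw > peak:
            peak = raw
    return peak, samples


def assist_as_needed_step(params: AssistParams, plant_state, target: float,
                          elapsed_since_cue: float, patient_torque: float,
                          noise_sd: float = 0.02) -> RobotAction:
    """Decide the robot's action for the current target.

    While ``elapsed_since_cue`` is inside the patient-first window the robot
    does nothing.  Afterwards, if an attempted torque above the detection
    threshold was sensed during the window, the robot assists toward the
    target at ``assist_speed``; otherwise it demonstrates the movement at
    the same speed.  A target discrepancy inside the dead-band needs no
    action at all.
    """
    discrepancy = target - plant_state.theta
    if abs(discrepancy) <= DEADBAND_DEG:
        return RobotAction("none", 0.0)
    if elapsed_since_cue < params.patient_first_delay:
        return RobotAction("none", 0.0)
    vel = math.copysign(params.assist_speed, discrepancy)
    if abs(patient_torque) >= params.detect_mult * noise_sd:
        return RobotAction("assist", vel)
    return RobotAction("demonstrate", vel)


def assisted_game_session(plant: AnklePlant, patient, params: AssistParams,
                          duration: float, day: float = 0.0,
                          seed: int | None = None, dt: float = 0.01,
                          targets: tuple[float, float] | None = None,
                          ) -> SessionLog:
    """Full assist-as-needed game session (coarse 10 ms tick).

    Targets alternate between the two ends of the passive ROM (or the given
    pair); each reach counts one repetition; the session stops at
    ``min(duration, rep_goal reps)``.
    """
    rng = random.Random(seed)
    plant.rng = rng
    pl = plant.params
    if targets is None:
        lo, hi = manual_rom(plant, push_torque=5.0)
        targets = (lo + 2.0, hi - 2.0)
    target_idx = 1
    target = targets[target_idx]
    elapsed = 0.0
    reps = 0
    attempt_peak = 0.0
    rows = []
    t = 0.0
    n = int(round(duration / dt))
    for i in range(n):
        cap = patient.capacity("df" if target > plant.state.theta else "pf", day)
        vol = cap * _effort_envelope(elapsed) * (
            1.0 if target > plant.state.theta else -1.0)
        sensed = vol + (rng.gauss(0.0, pl.noise_sd) if pl.noise_sd > 0 else 0.0)
        if elapsed < params.patient_first_delay:
            attempt_peak = max(attempt_peak, abs(sensed))
        action = assist_as_needed_step(params, plant.state, target, elapsed,
                                       attempt_peak, pl.noise_sd)
        v = action.velocity
        if action.kind == "none" and elapsed < params.patient_first_delay:
            # back-drivable: overdamped voluntary motion against the plant
            net = vol - elastic_torque(pl, plant.state.theta,
                                       plant.state.rom_shift_pos,
                                       plant.state.rom_shift_neg)
            v = max(-params.assist_speed,
                    min(params.assist_speed, net / max(pl.b, 0.05)))
        plant.step(v, vol, dt)
        t += dt
        elapsed += dt
        if i % 10 == 0:
            rows.append((t, plant.state.theta, sensed, v, action.kind,
                         reps, "assisted_game"))
        if abs(target - plant.state.theta) <= DEADBAND_DEG:
            reps += 1
            if reps >= params.rep_goal:
                break
            target_idx = 1 - target_idx
            target = targets[target_idx]
            elapsed = 0.0
            attempt_peak = 0.0
    frame = pd.DataFrame(rows, columns=[
        "time_s", "theta_deg", "torque_nm", "velocity_cmd_dps",
        "robot_action", "rep_index", "mode"])
    return SessionLog(frame=frame, meta={
        "seed": seed, "mode": "assisted_game", "reps": reps,
        "duration_s": t})


def manual_rom(plant: AnklePlant, push_torque: float = 5.0) -> tuple[float, float]:
    """ROM estimate from manually pushing the joint to a given torque.

    Returns the angles at which the static elastic torque reaches
    ``±push_torque``, the way a therapist gauges ROM at the start of a
    control-arm session.
    """
    pl = plant.params
    s = plant.state

    def f_pos(th):
        return elastic_torque(pl, th, s.rom_shift_pos, s.rom_shift_neg) - push_torque

    def f_neg(th):
        return elastic_torque(pl, th, s.rom_shift_pos, s.rom_shift_neg) + push_torque

    hi = brentq(f_pos, pl.theta_slack, pl.theta_slack + 80.0)
    lo = brentq(f_neg, pl.theta_slack - 80.0, pl.theta_slack)
    return float(lo), float(hi)


def mid_rom_interval(rom: tuple[float, float]) -> tuple[float, float]:
    """Central interval of half the ROM width (the control-arm excursion)."""
    lo, hi = rom
    center = 0.5 * (lo + hi)
    quarter = 0.25 * (hi - lo)
    return center - quarter, center + quarter


def control_group_session(plant: AnklePlant, patient, duration: float,
                          day: float = 0.0, seed: int | None = None,
                          passive_fraction: float = 0.6,
                          passive_freq: float = 0.25, dt: float = 0.01,
                          torque_limits: tuple[float, float] = (10.0, 10.0),
                          ) -> SessionLog:
    """Control-arm session: mid-ROM passive movement, then unassisted attempts.

    The passive phase moves the ankle sinusoidally over the central half of
    the manually measured ROM, never loading the stiff ends (so the creep
    state cannot accrue).  The active phase alternates 3 s attempt / 3 s
    rest with the robot back-drivable and providing no assistance.
    """
    rng = random.Random(seed)
    plant.rng = rng
    pl = plant.params
    lo, hi = mid_rom_interval(manual_rom(plant))
    center, amp = 0.5 * (lo + hi), 0.5 * (hi - lo)
    n = int(round(duration / dt))
    n_passive = int(n * passive_fraction)
    rows = []
    reps = 0
    t = 0.0
    for i in range(n):
        if i < n_passive:
            mode = "passive_mid_rom"
            phase_angle = 2.0 * math.pi * passive_freq * t
            target_v = -amp * 2.0 * math.pi * passive_freq * math.sin(phase_angle)
            # first-order pull toward the sinusoid to absorb the initial offset
            want = center + amp * math.cos(phase_angle)
            v = target_v + (want - plant.state.theta) * 2.0
            vol = 0.0
        else:
            mode = "active_unassisted"
            cyc = (t - n_passive * dt) % 6.0
            attempting = cyc < 3.0
            direction = 1.0 if ((t - n_passive * dt) // 6.0) % 2 == 0 else -1.0
            cap = patient.capacity("df" if direction > 0 else "pf", day)
            vol = direction * cap * _effort_envelope(cyc) if attempting else 0.0
            net = vol - elastic_torque(pl, plant.state.theta,
                                       plant.state.rom_shift_pos,
                                       plant.state.rom_shift_neg)
            v = max(-15.0, min(15.0, net / max(pl.b, 0.05)))
            if attempting and cyc < dt * 1.5:
                reps += 1
        m = plant.step(v, vol, dt, torque_limits=torque_limits)
        t += dt
        if i % 10 == 0:
            rows.append((t, plant.state.theta, m, v, "none", reps, mode))
    frame = pd.DataFrame(rows, columns=[
        "time_s", "theta_deg", "torque_nm", "velocity_cmd_dps",
        "robot_action", "rep_index", "mode"])
    return SessionLog(frame=frame, meta={
        "seed": seed, "mode": "control_session", "reps": reps,
        "mid_rom_lo": lo, "mid_rom_hi": hi, "duration_s": t})
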