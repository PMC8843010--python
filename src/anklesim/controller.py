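"""Resistance-adaptive ("intelligent") stretching velocity controller.

A discrete-time state machine updated every ``dt`` (default 0.5 ms):

* in the mid range of motion the commanded speed is ``C / |M_res|`` clipped
  to ``[Vmin, Vmax]`` — fast where the muscles are slack, proportionally
  slower as resistance builds;
* when the resistance reaches the torque limit for the current travel
  direction (``Mp`` dorsiflexing, ``Mn`` plantarflexing), or the angle
  passes the position limit plus the allowance ``theta_d``, the motor stops
  and holds the extreme position for a configured duration so that stress
  relaxation can occur;
* once the hold has elapsed the direction reverses at ``Vmax``.

Direction is explicit controller state, toggled only at completed holds:
the piecewise velocity law is ambiguous when the measured resistance is
near zero or transiently carries the "wrong" sign just after a reversal,
so the sign of the command comes from the direction state and only the
magnitude from ``|M_res|``.  ``M_res = 0`` commands ``Vmax`` (the
``C/|M|`` magnitude is treated as +inf and clipped).

Holds are per-end (clinically, strong holding is done at the extreme
dorsiflexion position only, hence ``hold_pos=5 s`` and ``hold_neg=0`` by
default).  While a hold is in progress the command stays 0 even if creep
lets the resistance relax below the limit; the hold timer is never reset by
such relaxation, so the measured hold duration equals the configured one to
within one tick.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, SensorFaultError, SimulationFaultError
from .plant import AnklePlant, step_plant

PHASE_MOVING = "moving"
PHASE_HOLDING = "holding"

_HARD_ANGLE_BOUND = 90.0  # deg; beyond this the simulation is declared faulty


@dataclass(frozen=True)
class ControllerParams:
    """Stretching-controller parameters (angles deg, torques N·m, times s)."""

    Mp: float = 10.0        # torque limit at the dorsiflexion (+) end
    Mn: float = 10.0        # torque limit at the plantarflexion (−) end
    Vmin: float = 2.0       # minimum speed magnitude, deg/s
    Vmax: float = 20.0      # maximum speed magnitude, deg/s
    C: float = 30.0         # Nm·deg/s; maps 1/|M_res| to speed
    theta_p: float = 15.0   # positive position limit, deg
    theta_n: float = -30.0  # negative position limit, deg
    theta_d: float = 5.0    # allowed rotation beyond the position limits, deg
    hold_pos: float = 5.0   # hold duration at the + end, s
    hold_neg: float = 0.0   # hold duration at the − end, s
    dt: float = 0.0005      # control update interval, s

    def __post_init__(self) -> None:
        if not (self.Mp > 0 and self.Mn > 0):
            raise ConfigurationError("torque limits Mp, Mn must be > 0")
        if not (0 < self.Vmin <= self.Vmax):
            raise ConfigurationError("need 0 < Vmin <= Vmax")
        if self.C <= 0:
            raise ConfigurationError("C must be > 0")
        if not self.theta_n < self.theta_p:
            raise ConfigurationError("need theta_n < theta_p")
        if self.theta_d < 0:
            raise ConfigurationError("theta_d must be >= 0")
        if self.hold_pos < 0 or self.hold_neg < 0:
            raise ConfigurationError("hold durations must be >= 0")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")


@dataclass
class ControllerState:
    direction: int = 1            # +1 toward dorsiflexion, −1 toward plantarflexion
    phase: str = PHASE_MOVING
    hold_elapsed: float = 0.0     # s
    cycle_count: int = 0          # completed end-to-end half-cycles


@dataclass(frozen=True)
class ControllerInput:
    theta: float   # deg, dorsiflexion positive
    m_res: float   # Nm, gravity already subtracted; + opposes dorsiflexion


def _step(p: ControllerParams, direction: int, holding: bool,
          hold_elapsed: float, cycle_count: int,
          theta: float, m_res: float):
    """Primitive single tick on scalars.

    Returns (velocity, direction, holding, hold_elapsed, cycle_count).
    Kept allocation-free so session loops can run millions of ticks.
    """
    if direction > 0:
        end_met = m_res >= p.Mp or theta >= p.theta_p + p.theta_d
        hold_dur = p.hold_pos
    else:
        end_met = m_res <= -p.Mn or theta <= p.theta_n - p.theta_d
        hold_dur = p.hold_neg
    if holding or end_met:
        if hold_elapsed < hold_dur:
            return 0.0, direction, True, hold_elapsed + p.dt, cycle_count
        direction = -direction
        return direction * p.Vmax, direction, False, 0.0, cycle_count + 1
    am = abs(m_res)
    if am * p.Vmax <= p.C:           # includes m_res == 0
        speed = p.Vmax
    else:
        speed = p.C / am
        if speed < p.Vmin:
            speed = p.Vmin
    return direction * speed, direction, holding, hold_elapsed, cycle_count


def controller_step(params: ControllerParams, state: ControllerState,
                    inp: ControllerInput) -> tuple[float, ControllerState]:
    """One control tick: returns the velocity command and the new state.

    Exactly one branch of the velocity law applies: hold (0), reversal
    (±Vmax with the direction flipped and the cycle counter incremented),
    or the mid-ROM resistance-proportional command
    ``direction * clip(C/|M_res|, Vmin, Vmax)``.
    """
    if not (math.isfinite(inp.theta) and math.isfinite(inp.m_res)):
        raise SensorFaultError("non-finite controller input (theta or M_res)")
    v, d, holding, he, cc = _step(
        params, state.direction, state.phase == PHASE_HOLDING,
        state.hold_elapsed, state.cycle_count, inp.theta, inp.m_res)
    new_state = ControllerState(
        direction=d, phase=PHASE_HOLDING if holding else PHASE_MOVING,
        hold_elapsed=he, cycle_count=cc)
    return v, new_state


@dataclass
class CycleSummary:
    """One half-cycle of stretching: travel toward an end plus its hold."""

    direction: int        # direction of travel of this half-cycle
    end_angle: float      # deg reached at reversal
    peak_torque: float    # max |M_res| seen during the half-cycle, Nm
    hold_time: float      # s actually spent holding


@dataclass
class SessionLog:
    """Decimated time series of one simulated session plus summaries."""

    frame: pd.DataFrame                 # time_s, theta_deg, torque_nm, ...
    cycles: list[CycleSummary] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        """Write the time series with a metadata comment header."""
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}={val}\n")
            self.frame.to_csv(fh, index=False)

    @staticmethod
    def read_csv(path) -> "SessionLog":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh)
        return SessionLog(frame=frame, meta=meta)

    def end_range_angles(self, direction: int = 1) -> list[float]:
        return [c.end_angle for c in self.cycles if c.direction == direction]

    def peak_torques(self) -> list[float]:
        return [c.peak_torque for c in self.cycles]


def run_stretch_session(params: ControllerParams, plant: AnklePlant,
                        duration: float, seed: int | None = None,
                        log_hz: float = 200.0) -> SessionLog:
    """Closed-loop intelligent-stretching session.

    The plant integrates at the control interval ``dt``; the log is
    decimated to ``log_hz``.  Raises :class:`SimulationFaultError` if the
    angle diverges beyond a hard bound.
    """
    p = params
    if seed is not None:
        plant.rng = random.Random(seed)
    if not (p.theta_n <= plant.state.theta <= p.theta_p):
        raise ConfigurationError(
            "plant must start inside [theta_n, theta_p]")
    n_steps = int(round(duration / p.dt))
    decim = max(1, int(round(1.0 / (log_hz * p.dt))))
    direction, holding, hold_elapsed, cycle_count = 1, False, 0.0, 0
    pl, st = plant.params, plant.state
    m = plant.measured_resistance()
    limits = (p.Mp, p.Mn)
    t_log, th_log, tq_log, v_log, ph_log, dir_log = [], [], [], [], [], []
    cycles: list[CycleSummary] = []
    peak = abs(m)
    hold_time = 0.0
    for i in range(n_steps):
        v, direction, holding, hold_elapsed, new_cc = _step(
            p, direction, holding, hold_elapsed, cycle_count,
            st.theta, m)
        if new_cc != cycle_count:
            cycles.append(CycleSummary(direction=-direction,
                                       end_angle=st.theta,
                                       peak_torque=peak,
                                       hold_time=hold_time))
            cycle_count = new_cc
            peak = 0.0
            hold_time = 0.0
        if holding and v == 0.0:
            hold_time += p.dt
        st, m = step_plant(pl, st, v, 0.0, p.dt, limits, plant.rng)
        am = abs(m)
        if am > peak:
            peak = am
        if abs(st.theta) > _HARD_ANGLE_BOUND:
            raise SimulationFaultError(
                f"plant diverged: theta={st.theta:.1f} deg at t={st.time:.3f} s")
        if i % decim == 0:
            t_log.append(st.time)
            th_log.append(st.theta)
            tq_log.append(m)
            v_log.append(v)
            ph_log.append(PHASE_HOLDING if holding else PHASE_MOVING)
            dir_log.append(direction)
    plant.state = st
    frame = pd.DataFrame({
        "time_s": t_log, "theta_deg": th_log, "torque_nm": tq_log,
        "velocity_cmd_dps": v_log, "phase": ph_log, "direction": dir_log,
    })
    meta = {"seed": seed, "duration_s": duration, "mode": "stretch",
            "dt_s": p.dt, "log_hz": log_hz}
    return SessionLog(frame=frame, cycles=cycles, meta=meta)
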