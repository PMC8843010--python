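"""Outcome measurements: isometric MVC, active ROM, and recovery-time detection.

Each biomechanical measure is taken three times with rest breaks and the
mean of the three is the reported outcome, mirroring standard clinical
robot-assessment practice.  Motor-recovery time is the first training day
on which the measured MVC peak crosses a detection threshold; patients who
never cross are censored at their last training day.
"""

from __future__ import annotations

import random
import statistics
from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import brentq

from .errors import InvalidInputError
from .plant import AnklePlant, elastic_torque
from .training import isometric_relearning_trial

DETECTION_MULT = 3.0        # detection margin = DETECTION_MULT * noise_sd
EFFORT_VARIABILITY = 0.10   # within-trial multiplicative SD of maximal effort


@dataclass
class OutcomeRecord:
    """One patient's outcomes at one assessment point."""

    patient_id: str
    session_index: int
    arom: float               # deg, >= 0
    pf_mvc: float             # Nm, >= 0
    df_mvc: float             # Nm, >= 0
    fmle: int                 # 0..34
    mas: int                  # 0..5
    pf_recovery_day: float | None = None   # None until determined
    df_recovery_day: float | None = None
    pf_event: bool = False
    df_event: bool = False

    def __post_init__(self) -> None:
        if self.arom < 0 or self.pf_mvc < 0 or self.df_mvc < 0:
            raise InvalidInputError("arom and MVC values must be >= 0")
        if not 0 <= self.fmle <= 34:
            raise InvalidInputError("FMLE must lie in [0, 34]")
        if not 0 <= self.mas <= 5:
            raise InvalidInputError("MAS must lie in [0, 5]")


def measure_mvc(plant: AnklePlant, patient, direction: str, day: float = 0.0,
                n_trials: int = 3, trial_duration: float = 5.0,
                effort_variability: float = EFFORT_VARIABILITY,
                rng: random.Random | None = None) -> float:
    """Isometric MVC at the 0° locked footplate: mean of ``n_trials`` peaks.

    Each maximal effort varies multiplicatively (SD ``EFFORT_VARIABILITY``)
    around the patient's capacity; rest breaks between efforts are assumed
    long enough that no fatigue carries over.  Negative peaks (pure noise in
    a patient with no output) are floored at zero.
    """
    rng = rng if rng is not None else plant.rng
    peaks = []
    muscle = "df" if direction == "dorsiflex" else "pf"
    for _ in range(n_trials):
        base = float(patient.capacity(muscle, day))
        effort = max(0.0, base * (1.0 + rng.gauss(0.0, effort_variability)))
        peak, _ = isometric_relearning_trial(
            plant, _FixedCapacity(effort), direction,
            duration=trial_duration, lock_angle=0.0, rng=rng)
        peaks.append(max(0.0, peak))
    return statistics.fmean(peaks)


class _FixedCapacity:
    """Adapter presenting a fixed capacity through the patient interface."""

    def __init__(self, value: float) -> None:
        self._value = value

    def capacity(self, muscle: str, day: float) -> float:
        return self._value


def measure_arom(plant: AnklePlant, patient, day: float = 0.0,
                 n_trials: int = 3,
                 effort_variability: float = EFFORT_VARIABILITY,
                 rng: random.Random | None = None) -> float:
    """Active ROM: mean over trials of the voluntary excursion.

    With the robot back-drivable, the patient pushes each way and the ankle
    settles where the voluntary torque balances the passive elastic torque;
    the trial excursion is (max dorsiflexion − max plantarflexion).  Effort
    varies between trials exactly as in the MVC measure.
    """
    rng = rng if rng is not None else plant.rng
    pl = plant.params
    st = plant.state
    trials = []
    for _ in range(n_trials):
        cap_df = max(0.0, patient.capacity("df", day)
                     * (1.0 + rng.gauss(0.0, effort_variability)))
        cap_pf = max(0.0, patient.capacity("pf", day)
                     * (1.0 + rng.gauss(0.0, effort_variability)))
        hi = _static_balance(pl, st, cap_df)
        lo = _static_balance(pl, st, -cap_pf)
        trials.append(hi - lo)
    return statistics.fmean(trials)


def _static_balance(pl, st, torque: float) -> float:
    """Angle at which the passive elastic torque equals ``torque``."""
    if torque == 0.0:
        return pl.theta_slack

    def f(th):
        return elastic_torque(pl, th, st.rom_shift_pos, st.rom_shift_neg) - torque

    lo, hi = (pl.theta_slack, pl.theta_slack + 85.0) if torque > 0 \
        else (pl.theta_slack - 85.0, pl.theta_slack)
    return float(brentq(f, lo, hi))


def detect_recovery_day(torque_peaks_by_session: Sequence[tuple[float, float]],
                        threshold: float, last_day: float,
                        ) -> tuple[float, bool]:
    """First day whose MVC peak exceeds ``threshold``.

    Returns ``(day, True)`` for the first crossing, else
    ``(last_day, False)`` — censoring at the last training day.  Sessions
    must already be in chronological order.
    """
    if len(torque_peaks_by_session) == 0:
        raise InvalidInputError("need at least one session")
    days = [d for d, _ in torque_peaks_by_session]
    if any(b < a for a, b in zip(days, days[1:])):
        raise InvalidInputError("sessions must be in chronological order")
    for day, peak in torque_peaks_by_session:
        if peak > threshold:
            return day, True
    return last_day, False
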