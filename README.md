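# anklesim

A simulator for **robot-guided in-bed ankle rehabilitation** of stroke
survivors with severe hemiplegia. It targets researchers in
neurorehabilitation robotics and biostatistics who want to study — without
hardware or patients — how a wearable ankle robot's control strategies and
a two-arm clinical protocol interact with a spastic, viscoelastic ankle and
a slowly recovering motor system.

The package contains, end to end:

* the **"intelligent stretching" velocity controller**: a discrete-time
  state machine updated every 0.5 ms that commands

  ```
  V(t) = direction · clip( C / |M_res(t)|, Vmin, Vmax )
  ```

  in the mid range of motion — fast where the muscles are slack, slowing
  in proportion to the rising resistance torque `M_res` — stops when
  `M_res` reaches the torque limit (`Mp` dorsiflexing, `Mn`
  plantarflexing) or the angle passes the position limit `θp/θn` plus the
  allowance `θd`, holds the extreme for a configured time (default 5 s at
  the dorsiflexion end) so stress relaxation can occur, then reverses at
  `Vmax`;
* a **synthetic ankle plant**: exponential passive stiffening toward both
  ROM ends with a linear residual-tone term, velocity-dependent spastic
  reflex, viscous damping, torque-sensor noise, and **end-range creep** —
  sustained loading near a torque limit gradually gains range of motion,
  the mechanism that distinguishes strong stretching from mid-ROM movement;
* the three **training modes**: isometric motor relearning under amplified
  real-time torque feedback, assist-as-needed game movement (a 2–3 s
  patient-first window, then assistance if an attempt was sensed, else
  demonstration), and the control-arm protocol (passive movement confined
  to the central half of the manually measured ROM plus unassisted active
  attempts);
* the **assessments**: 3-trial averaged isometric MVC at the locked 0°
  footplate, 3-trial active ROM, and motor-recovery-day detection with
  censoring at the last training session;
* a **synthetic two-arm cohort** (default 9 vs 9): log-normal latent
  recovery-onset days and saturating post-onset capacity growth, with the
  study intervention multiplying the onset hazard and growth rate;
* the **statistics suite**, implemented from first principles over scipy
  distribution functions: Welch t from summary statistics, Fisher's exact
  test (probability-mass two-sided rule), 2×2 mixed repeated-measures
  ANOVA with partial η² (`η²p = F·df1/(F·df1 + df2)`) and Bonferroni
  post-hocs, Kaplan–Meier with log(−log) confidence limits, the
  Gehan–Breslow generalized Wilcoxon test (asymptotic, Monte-Carlo
  permutation, and exact-enumeration p), and repeated-measures interaction
  sample size via the noncentral F with `λ = f²·N·m/(1−ρ)`.

## Worked example

Simulate a 9-vs-9 trial and render its Table-1-style report:

```sh
anklesim simulate-trial --seed 7 --out demo
anklesim report --trial-dir demo
```

```
                                       Study         Control       p
n                                          9               9
Gender (men/women)                       5/4             6/3   1.000
Affected side (L/R)                      8/1             6/3   0.576
Age (year)                       54.36±13.96      55.88±9.78   0.793
FMLE pre                           5.56±1.24       4.33±1.00
FMLE post                         14.00±6.28       5.11±2.15   0.003
AROM pre (deg)                     0.19±0.10       0.20±0.08
AROM post (deg)                    3.18±1.79       0.32±0.29   0.000
PF MVC pre (Nm)                    0.12±0.04       0.12±0.05
PF MVC post (Nm)                   1.92±1.03       0.21±0.20   0.000
DF MVC pre (Nm)                    0.12±0.04       0.13±0.04
DF MVC post (Nm)                   0.26±0.19       0.12±0.03   0.058
PF recovery (KM median)                8.0 d          15.0 d   0.012
DF recovery (KM median)          not reached     not reached   0.143
```

Reading the output: both arms start with essentially no voluntary ankle
output (AROM ≈ 0.2°, MVC ≈ 0.12 N·m — faint isometric torque only). After
~3 weeks of sessions the study arm shows large plantarflexor MVC and AROM
gains and a significant group×time interaction (the `p` column on the
post rows), while the control arm barely moves; plantarflexion motor
output re-emerges earlier in the study arm (Kaplan–Meier median 8 days,
Gehan–Breslow p = 0.012), and dorsiflexion recovers later and less often
in both arms. Baseline rows show the arms are comparable (Fisher/Welch
p > 0.05).

Single closed-loop sessions are available too:

```sh
anklesim simulate-session --seed 1 --mode stretch --duration 300 --out stretch.csv
```

which logs `time_s, theta_deg, torque_nm, velocity_cmd_dps, phase,
direction` at 200 Hz, with the config hash and seed in `#` header lines.

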