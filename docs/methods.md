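# Methods

This note documents the models behind `anklesim`, the defaults and why
they were chosen, the numerical choices, and what the synthetic data can
and cannot tell you about real patients.

## 1. The stretching controller

The controller is a discrete-time state machine on a 0.5 ms tick
(`ControllerParams.dt`). Its velocity law has three regimes:

1. **mid-ROM**: command magnitude `clip(C/|M_res|, Vmin, Vmax)` in the
   current travel direction. The reciprocal form is what produces
   "fast when slack, slower as resistance rises"; `M_res = 0` is treated
   as the `Vmax` case (`C/0⁺ → ∞`, clipped), which avoids a division
   fault and is the physically sensible limit.
2. **end reached**: when the signed resistance reaches the limit for the
   travel direction (`M_res ≥ Mp` dorsiflexing, `M_res ≤ −Mn`
   plantarflexing) or the angle passes `θp + θd` / `θn − θd`, the command
   is 0 and a hold timer runs.
3. **hold complete**: the direction flips and the command is `Vmax` in
   the new direction; the half-cycle counter increments.

Design choices that the piecewise law alone does not fix:

* **Direction is explicit state**, toggled only at completed holds. Right
  after a reversal the measured resistance can transiently carry the
  "wrong" sign (damping, reflex, noise); taking the command's sign from
  `sign(M_res)` would chatter. Branch magnitudes still come from
  `|M_res|`.
* **The `Vmax` cap is applied symmetrically** with the `Vmin` floor
  (`clip`), since `Vmax` is defined as the mid-ROM maximum speed.
* **Holds are per-end** (`hold_pos = 5 s`, `hold_neg = 0 s` by default):
  clinically, strong stretch-and-hold is done at the extreme dorsiflexion
  position, while the plantarflexion end just reverses.
* **Hold timing is never reset by stress relaxation.** During a hold the
  creep state lets the measured torque fall below the limit; the command
  stays 0 and the timer keeps running, so the realized hold equals the
  configured hold to within one tick (verified in the tests).

Units are degrees, N·m and seconds throughout, dorsiflexion positive; no
internal unit conversion leaks into logs.

Safety envelope (measured, not designed-in): because the approach speed
near a torque limit is `clip(C/Mp, Vmin, Vmax)` (3 °/s at the defaults),
the worst torque overshoot is one tick of travel times the local elastic
stiffness — ~1.3 mN·m at the defaults over a 20-minute session — and the
angle can pass `θp + θd` by at most `Vmax·dt` (0.01°).

## 2. The ankle plant

A position-servo abstraction: the drive is much stiffer than the limb, so
the commanded velocity is enforced exactly and the plant integrates the
angle. (The real device also closes a velocity loop through a geared
servomotor; motor dynamics are out of scope.) The measured resistance is

```
M_res = elastic(θ) + b·ω + reflex(ω) − voluntary + N(0, noise_sd)
```

with the gravitational torque of foot + holder modeled (`g_amp·sin θ`)
but subtracted before the controller sees the signal, as the robot does.

**Elastic torque.** Linear residual tone plus exponential walls:

```
elastic(θ) = k_lin·x + k1_df·(exp(k2_df·(x − s_pos)) − 1)   for x − s_pos > 0
                     − k1_pf·(exp(k2_pf·(−x − s_neg)) − 1)  for −x − s_neg > 0
x = θ − θ_slack
```

The linear term (`k_lin = 0.6 N·m/deg`) is deliberate: a purely
exponential curve is numerically flat in mid-ROM, which would let any
nonzero voluntary torque produce an arbitrarily large active ROM. A
severely spastic ankle is never torque-free; with the default `k_lin`, a
0.13 N·m voluntary capacity yields an AROM of ~0.4°, matching the
near-zero baselines such patients present. Defaults
(`k1_df = 0.5 N·m, k2_df = 0.15/deg, k1_pf = 0.4, k2_pf = 0.12,
θ_slack = −5°`) put the 10 N·m torque limits at roughly +7.5° and −19°,
inside the ±(15°..30°) position limits, so stretching is torque-limited —
the intended operating mode — with the position limits as the safety
backstop.

**Spastic reflex.** Zero below a velocity threshold (5 °/s), then linear
in the excess speed (`0.05 N·m·s/deg`), opposing motion, scaled by a
severity multiplier derived from the MAS grade (`mas/2`). This is a
deliberately minimal tonic-stretch-reflex surrogate; it has no dynamics.

**Creep.** While the measured torque magnitude stays above 90% of the
relevant torque limit on the corresponding side of slack, the ROM shift
grows at `creep_gain·|M|·dt` (default `5·10⁻⁴ deg/(N·m·s)`), capped at
`creep_cap = 1.5°` per session. Creep stands in for viscoelastic stress
relaxation *and* plastic ROM gain with a single parameter; the key
property is that only end-range loading produces it, so the control-arm
protocol (mid-ROM only) gains nothing — this is the mechanistic contrast
between the arms. The per-session cap is the calibration knob for total
PROM gain (~1.5°/session × ~13 sessions ≈ 20°, a strong but plausible
course of intensive stretching).

Sign convention: a resistance torque is positive when it opposes motion
toward dorsiflexion, hence viscous drag enters as `+b·ω`. One convention
is used everywhere (plant, controller, logs).

## 3. Training modes

* **Isometric relearning**: ankle locked, voluntary torque = capacity ×
  a 1 s ramp-to-plateau envelope + sensor noise, sampled at 100 Hz; the
  displayed feedback is a pure gain (default 50×) on the raw torque.
  Detection sensitivity is limited only by `noise_sd`.
* **Assist-as-needed**: no action inside the patient-first window
  (`patient_first_delay ∈ [2, 3] s`, default 2.5); afterwards the robot
  assists at `assist_speed` toward the target if the attempt torque
  sensed during the window exceeded `3 × noise_sd`, else it demonstrates
  the movement at the same speed. A 1° dead-band suppresses action when
  the target is already reached. Sessions stop at
  `min(duration, rep_goal)` with `rep_goal = 150`. The assistive action
  is a velocity servo; a torque-mode variant (`resist_gain`) exists for
  resistance games but is disabled in the default severe-hemiplegia
  protocol.
* **Control-arm session**: the therapist's manual ROM is estimated by
  pushing the joint to ±5 N·m; the passive phase is a 0.25 Hz sinusoid
  confined to the central half of that ROM ("mid-ROM" is operationalized
  as the central interval of half the ROM width — the least-biased
  reading of "about half of the ROM"); the active phase alternates 3 s
  unassisted attempts and 3 s rests with the robot back-drivable
  (overdamped first-order voluntary motion). Mid-ROM torques stay far
  below the creep threshold, so the control arm accrues no ROM gain.

## 4. Assessments

MVC: three maximal efforts at the locked 0° footplate, each with 10%
multiplicative effort variability, peak over a 5 s window, mean of the
three (rest breaks are assumed fully restorative — no fatigue model).
Because the peak is taken over ~450 noisy samples, a pure-noise patient
still measures ~3σ of sensor noise (~0.06 N·m); this noise floor is part
of the measurement model, and is why baseline MVC readings are nonzero
even when true capacity is ~0.

AROM: three trials of quasi-static balance — the ankle settles where the
voluntary capacity (with the same effort variability) equals the passive
elastic torque; the trial value is the dorsiflexion-to-plantarflexion
excursion, and the outcome is the 3-trial mean.

Recovery day: first training day whose session MVC peak exceeds a
threshold, otherwise censored at the last session day. The threshold is
**change-from-baseline**: the patient's baseline MVC plus a `3 × noise_sd`
margin. An absolute `3 × noise_sd` threshold would fire immediately on
the nonzero baseline noise floor; referencing baseline makes "recovery"
mean *new* motor output, which is the clinical intent. A single
supra-threshold session counts as recovery (no sustained-detection
requirement).

## 5. The synthetic cohort

Each patient carries, per muscle group (plantarflexors PF, dorsiflexors
DF): a latent recovery-onset day, log-normal with log-scale SD 0.9; a
post-onset capacity curve `c(t) = c₀ + (c_max − c₀)(1 − e^{−r·Δt/(c_max−c₀)})`
whose initial slope is the capacity rate `r` (N·m/day); and a baseline
capacity `c₀ ~ |N(0.07, 0.05)|` N·m (PF). Control-arm defaults: onset
medians 35 d (PF) and 100 d (DF), rates 0.08 / 0.03 N·m/day; the study
intervention multiplies the onset hazard and the rate by
`study_effect_multiplier = 5`. Plantarflexors get the larger
`c_max` (3.5 vs 1.2 N·m), encoding their larger muscle volume — this is
what makes PF recovery earlier and more frequent than DF in both arms.
Planned sessions are truncated-normal (study 13±3, control 10±9, clipped
to [1, 15]), five weekday sessions per week; censoring happens at the
last session day.

FMLE (0–34) is a monotone noisy map of the mean normalized capacity
(`4 + 28·frac + N(0, 1.5)`, rounded and clipped); MAS (baseline 2–3)
drops by one with probability proportional to accumulated ROM gain, with
a small random worsening probability. Neither scale has a mechanistic
model — they are generated from the latent state only.

**Session granularity.** Trial-level simulation uses a summary step per
session: creep accrues by the closed-form per-hold integral
(`creep_gain · 0.95·Mp · hold_s` per cycle, cycles every
`travel + hold` seconds, capped per session), and assessment peaks are
drawn from their exact sampling distribution (max-of-n Gaussian noise via
inverse-transform). This keeps a full 9-vs-9 trial at ~15 ms, so the
replicate studies (200 mechanism-contrast replicates, 500 null
replicates) run in seconds. The full 0.5 ms closed-loop physics is used
for everything session-level (controller safety, creep identification)
and is validated separately; the summary creep model is the closed form
of the same law the tick-level plant integrates.

**What the generator does not emulate**: co-interventions of standard
care, fatigue and day-to-day motivation, ischemic/hemorrhagic subtype,
non-monotone recovery, assessment learning effects, and any neural
mechanism — onsets and rates are latent draws, not biology. Passing
tests therefore show that the *pipeline* (control, measurement,
statistics) behaves correctly under a plausible recovery structure, not
that the clinical effect sizes are predicted.

## 6. Statistics

* **Welch t from summaries** with Satterthwaite df; the summary interface
  exists because published tables carry only mean ± SD. Zero variance in
  both groups with equal means returns p = 1 by convention.
* **Fisher exact, probability-mass rule**: two-sided p is the sum of
  hypergeometric probabilities ≤ the observed table's (with a 1e−7
  relative tolerance on the comparison). This convention — the one
  mainstream software uses — reproduces both published baseline Fisher
  values to 3 d.p.; mid-p and tail-doubling variants do not.
* **Mixed 2×2 ANOVA** via the change/average decomposition: change
  scores carry the time and interaction effects, subject averages the
  group effect. For one-df effects `η²p = F/(F + df₂)` exactly, and the
  interaction F equals the squared pooled change-score t (identity
  verified to 1e−10). Unbalanced groups use unweighted (Type III)
  effects with harmonic-mean cell size. Post-hocs are paired t per group,
  Bonferroni ×2.
* **Kaplan–Meier**: product-limit with Greenwood variance on the
  log(−log) scale for pointwise CIs; median = first time S(t) ≤ 0.5,
  `None` when never reached; median CI Brookmeyer–Crowley style (first
  times the upper/lower confidence limits reach 0.5).
* **Gehan–Breslow**: weighted log-rank with weight = number at risk and
  hypergeometric variance, χ² on 1 df — this matches what survival
  software calls the Breslow test (verified against lifelines'
  `weightings="wilcoxon"` to 1e−8). Because the χ²(1) approximation is
  anticonservative at very small n (deviations up to ~0.18 from the
  exact permutation p at n ≤ 8), the module also provides
  `breslow_permutation_p` (vectorized label-shuffling Monte-Carlo) and
  `breslow_exact_p` (full enumeration, feasible up to a few hundred
  thousand label assignments). For n = 9 + 9 trials the asymptotic p is
  adequate and is what the pipeline reports.
* **Sample size**: smallest group-divisible N whose interaction power
  under the noncentral F with `λ = f²·N·m/(1−ρ)` reaches the target,
  then inflated by attrition. The repeated-measures correlation ρ is an
  explicit argument because published power statements typically omit
  it; at f = 0.25, α = 0.05, power = 0.80 and 10% attrition the required
  total is 38 at ρ = 0.5 and 18 at ρ = 0.8 — i.e., a published
  requirement of 18 is internally consistent with a high pre-post
  correlation, which severe-baseline cohorts plausibly have.

**Type-I calibration.** Under an exchangeable null (effect multiplier 1
*and* matched session-count distributions — unequal planned sessions are
a protocol asymmetry, not a treatment effect), the interaction test on
FMLE is nominal within binomial error (0.042 over 600 replicates).
On AROM and PF MVC the empirical level is conservative (0.020, 0.010):
their null change scores are zero-inflated and heavy-tailed (measurement
jitter plus rare recovery outliers), where t-type tests under-reject.
This is a property of the outcome distributions the cohort model
produces, documented rather than "fixed".

## 7. Numerical choices and degenerate inputs

* Control tick 0.5 ms; session logs decimated to 200 Hz (≥ 100 Hz).
* The plant integrates at the control tick (no sub-stepping needed at
  these speeds); a hard ±90° bound raises a simulation fault.
* Static-balance angles are found with Brent's method on the elastic
  curve (bracketed by construction, monotone integrand).
* Creep-gain identification inverts the elastic law on logged hold
  segments (`s(t) = x − log1p((m − k_lin·x)/k1_df)/k2_df`) and divides
  the total shift by the trapezoid-integrated torque-time; on noise-free
  logs it recovers the gain to ~1e−7 relative error.
* Capacity-rate recovery fits the saturating growth model per patient
  (scipy `curve_fit`, rate bounded to [1e−4, 10]) on patients whose
  onset falls at least 2 days before censoring with ≥ 4 post-onset
  assessments, then averages.
* Empty survival input, zero events, empty assessment sequences,
  non-chronological sessions, non-finite sensor readings, and parameter
  invariant violations all raise typed exceptions
  (`InvalidInputError`, `SensorFaultError`, `ConfigurationError`).
* Determinism: every stochastic component takes a seed or RNG; the CLI
  and trial simulator are byte-reproducible under a fixed `--seed`.

## 8. Known limitations

* The position-servo plant cannot express drive compliance, so
  torque-mode assistance is only approximated by its velocity-servo
  equivalent.
* Creep conflates stress relaxation and plastic ROM gain; relaxation
  time constants are not separately identifiable from the logs it
  produces.
* The MAS/FMLE maps are ordinal conveniences, not validated scales.
* Exact clinical effect sizes are not reproducible from published group
  summaries; the cohort defaults are calibrated to direction, baseline
  scale, recovery counts and the KM median only.
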