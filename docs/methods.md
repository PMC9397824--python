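# Methods

This note documents the models implemented in `texdisc`, the choices made
where the design was genuinely open, and what the simulated components do
and do not stand for.

## Stimuli and task

A grating stimulus is fully described by its spatial frequency *f* (m⁻¹);
its spatial period is 1/*f*. The default assessment set uses a standard at
164 m⁻¹ with four more-coarse comparisons {100, 116, 132, 148} and four
less-coarse {180, 196, 212, 228} m⁻¹ — constant 16 m⁻¹ spacing per side,
standard equal to the mean of the eight comparisons so neither roughness
direction is favoured. The stimulus-intensity axis of all psychometric
computation is the difference ratio x = |f_Co − f_St| / f_St, spanning
16/164 ≈ 0.0976 to 64/164 ≈ 0.3902 for the default set.

Trials follow the triangle test: the six position arrangements
(St/St/Co … St/Co/Co) are drawn uniformly and independently per trial, so
the odd texture's position and identity (comparison in St-majority sets,
standard in Co-majority sets) are unpredictable; chance is exactly 1/3.
Assessment blocks present each comparison `repetitions` times (default 5,
hence 40 trials) in a seeded random permutation. Training repeats the first
block's comparison sequence in blocks 2–3 but re-draws the arrangement per
trial — repeating only the stimulus order preserves the intended difficulty
progression without letting positions be memorised.

Degenerate inputs are rejected eagerly: non-positive frequencies, equal
standard/comparison in a triangle trial, empty comparison pools. Stimulus
sets that break the even-spacing or centred-standard properties (as adapted
training sets generally do) are accepted with a logged warning.

## Haptic rendering and the simulated exploration loop

Forces follow the rendering laws given in the README: gated grating force
along y, PD virtual wall along z, PD guidance with inertial feedforward
along y in the passive condition, transparency along x. Contact requires
the end effector below the table height (z_tbl = 1 mm) and strictly inside
one of three 0.176 × 0.02 m texture rectangles separated by 0.01 m gaps,
the middle one centred at the origin (side textures at x = ∓0.03 m). A
1 pm tolerance keeps mathematical edge points out of contact despite float
rounding.

The guidance law adds a reference acceleration to stiffness/damping force
terms; it is implemented as a feedforward inertial term m_v·ÿ_R with
virtual mass m_v = 1 kg, which is numerically identical while keeping units
explicit. m_v is configurable.

The guidance reference follows the cycloidal motion law
y_R(t) = y_start + Δ·(t/T − sin(2πt/T)/(2π)) with analytic derivatives;
velocity and acceleration vanish at segment boundaries, so concatenated
sweeps are C²-smooth and position is monotone within a sweep.

No physical robot or hand exists here, so trials are closed with a
point-mass plant: m_h·ẍ = F_rendered + F_hand − b_h·ẋ with hand mass
m_h = 1 kg and viscous hand impedance b_h = 5 N·s/m, integrated with
semi-implicit Euler at 1 kHz (the typical haptic servo rate; all four
values configurable). The scripted policy visits the three textures left to
right; per texture it presses down with 2 N and performs two full-length
sweeps whose cycloid duration is set for a 0.17 m/s peak speed — a
realistic scanning speed for this task scale. In passive mode the guidance
controller does the sweeping (the "participant" exerts no voluntary y
force); in active mode a voluntary PD controller tracks the same class of
scanning target. With the default gains the passive tracking error stays
below 10 mm (≈7 mm peak) and decreases monotonically as guidance stiffness
grows; halving the timestep moves the final state by <0.1 mm.

The wall + hand-damping subsystem is dissipative: in simulation, mechanical
energy is non-increasing at every step away from contact transitions; at
the contact-onset step the discretisation can create at most
½K_z(v·dt)² ≈ 10 µJ of spurious spring energy, an artefact of sampling the
spring mid-penetration, not of the control law.

The robot's 0.02 mm position resolution is modelled only as an optional
quantisation of *reported* positions (off by default); integrating on a
quantised grid would add artificial limit cycles.

## Simulated observers

Observers answer trials via a logistic ground truth, the generative mirror
of the fitted model, which makes parameter recovery well-posed. The default
is the plain logistic with α = −ln 2 (so p(0) = 1/3 exactly, matching
triangle-test chance) and β = 10. A `guess_floored` variant
p = 1/3 + (2/3)·logistic(α+βx) is provided for robustness experiments: the
fitted model family is a plain logistic, and fitting it to guess-floored
data probes misspecification. Incorrect responses choose uniformly between
the two non-odd positions. Observers are stateless; training-induced gains
are represented by a second observer with the slope scaled up
(`training_beta_gain`, default 1.5) used for retention blocks, emulating
short-term retention without modelling learning dynamics.

What the simulation does *not* emulate: lapses and attention drift,
sequential effects, vibration-coding mechanisms, learning within a block,
or any coupling between exploration kinematics and the response. Passing
parameter-recovery and reliability tests therefore shows the *analysis
chain* is correct and unbiased under the stated generative model — not that
human data will be this clean.

## Psychometric analysis

Fits are ordinary Bernoulli-logistic maximum likelihood (per coarseness
side, never pooled across sides or conditions). Non-convergence is a data
state, not an error: perfect separation (e.g. all-correct data), non-finite
estimates, a non-positive slope, or a PSE outside the assessed intensity
range all mark the fit unusable. The convergence interval and the
all-correct floor use the exact design ratios 16/164 and 64/164 (printed
elsewhere as 0.098 and 0.39) with inclusive endpoints; using the rounded
prints would spuriously exclude the design's own minimum ratio.

The phase PSE score is the mean of the two side PSEs. If every trial of the
phase was answered correctly the score is floored at the minimum assessed
ratio (0.098); a per-side variant of this rule is available behind
`all_correct_rule="side"`. By default a phase with either side unusable
yields no PSE (`require_both_sides=True`), and downstream reliability
analyses drop the paired case; single-side averaging is available behind a
flag. Both defaults follow the stricter reading of the scoring rules; the
flags exist because the alternatives are defensible.

**Adaptive training sets.** For each side whose baseline fit converged, the
four training intensities are {PSE ± 0.5Δ, PSE ± 1.5Δ} with Δ the baseline
spacing (16/164) — a symmetric, equally spaced span centred on the
participant's threshold, which reduces to the baseline side exactly when
the PSE sits at that side's centre (0.2439). Intensities are clipped below
at one robot-resolution step (0.02 mm ↔ ratio 0.00328) above zero and above
at the baseline maximum 64/164; values that collide at a clip boundary are
separated by one resolution step to keep frequencies strictly ordered.
Ratios map to frequencies as f_St(1 − r) (more coarse) and f_St(1 + r)
(less coarse). A non-converged side keeps its baseline comparisons. This
construction is a principled reconstruction from the procedure's stated
inputs and is isolated in one function so an alternative rule can be
swapped in.

## Kinematic outcomes

From a trace: scanning duration = time in contact moving faster than
0.01 m/s, per texture, averaged over the three textures; path length =
Σ|Δy| over contact samples per texture, averaged likewise (the speed gate
deliberately does not apply — brief slow segments still cover distance);
mean scanning speed = mean |ẏ| over above-threshold contact samples. Speed
uses the y-component (the scanning axis); a full-3D variant sits behind a
flag. Unvisited textures contribute zero to the averages. A no-contact
trace returns zeros with a warning rather than failing.

## Reliability and design statistics

ICC(2,k) is computed from the two-way ANOVA mean squares,
(MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n), with the standard F-based
confidence interval (Satterthwaite df on the single-measure interval,
stepped up to average measures) and the F = MS_R/MS_E significance test —
the McGraw–Wong absolute-agreement, average-measures form. Zero residual
variance short-circuits to a degenerate interval; zero total variance is
undefined and flagged. Qualitative bands: excellent > 0.90,
good 0.75–0.90, moderate 0.50–0.75, poor otherwise. The test suite verifies
equality with a longhand ANOVA oracle (1e-10) and with an independent
mainstream implementation.

Bland–Altman limits are mean ± 1.96 × sample SD (ddof = 1) of paired
differences, with the count of pairs outside the limits reported.

Triangle-test power is exact: critical count
c = min{k : P(X ≥ k | n, 1/3) ≤ α}, power = P(X ≥ c | n, p_alt). The
sample-size scan returns the first n reaching the target power (the common
convention); because the discrete power curve is a sawtooth, a `stable`
mode returning the first n after which power never again dips below target
is provided. At the pilot effect size 25/40 with α = 0.05 and target 0.95
the first crossing is n = 34.

## Protocol simulation

Session 1 comprises one familiarization trial (triplet 228/228/100 m⁻¹)
plus two 40-trial initial baselines, active/passive order counterbalanced
over participants; sessions 2–3 each run baseline → three 40-trial adaptive
training blocks → retention, with the session-2 condition counterbalanced
and crossed over in session 3. Familiarization is logged but excluded from
every analysis. All randomness (counterbalancing, observer draws, block
orders, responses) descends from one master seed through spawned child
streams, so studies are byte-reproducible; `n_participants` must be even so
both splits are exact halves.

Between-subject spread is modelled by drawing each participant's true slope
uniformly from `baseline_beta_range` (default 5–20); `between_day_jitter`
adds optional day-to-day slope noise (default 0 = identical across days,
the configuration under which reliability recovery is testable). Terminal
visual feedback during training has no effect on the stateless observer; a
learning observer could consume it, and the retention-observer hook is
where such a model would plug in.

Trace simulation during protocol runs is optional (`simulate_traces`,
default off): assessment scores, PSEs and reliability need only trial
records, and the study-level analyses stay in seconds. When enabled, the
first `traces_per_phase` trials of each assessment block are simulated and
written per trial; `analyze_study` then adds a kinematics table.

Problem sizes used by the test suite — e.g. 200 simulated observers at 400
trials/side for parameter recovery, 100k trials for the chance-level check,
a 50-participant cohort for reliability recovery — were chosen as the
smallest sizes at which the statistical assertions have comfortable margins
under their stated tolerances.

## Known limitations

- The exploration policy is scripted and deterministic; it produces
  representative, not human-like, kinematics (no speed variability, no
  re-exploration, no strategy differences between conditions beyond the
  guidance itself).
- The observer is stationary within a session; improvements appear only as
  the discrete baseline→retention slope change.
- Guidance is gated off outside contact, so between-texture transport in
  passive mode is performed by the scripted hand, not the robot.
- The logistic family is both generator and fitted model by default; model
  misspecification is only probed via the guess-floored observer.
- ICC confidence intervals assume the balanced two-way normal model; with
  very small groups (n = 5 per condition in a 10-participant study) they
  are extremely wide, exactly as the formulas dictate.
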