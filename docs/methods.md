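# Methods

This note documents the models, conventions and numerical choices behind
`spindlesee`: the synthetic series-elastic MTU + spindle generator, the
signal-conditioning chain, the stiffness/RFD and firing-feature estimators,
and the statistical contrasts.

## The experimental structure being modelled

A relaxed muscle–tendon unit (MTU) is stretched by a servomotor under three
protocols — 2 mm, 2 Hz sinusoids; 3 mm ramp–hold–release at 20 mm/s with a
1 s hold; three 3 mm triangles at 3.5 mm/s — while MTU length and force,
fascicle length (sonomicrometry) and single Ia afferent spikes are recorded
at 17.8 kHz. Two conditions are compared: CTRL (tendon only in series) and
SEE (an elastic element added between tendon and motor, lowering the
effective series stiffness; in SEE trials "MTU" means the muscle + tendon +
added spring as one unit). Because muscle and series element carry the same
force, a softer series element takes up more of the imposed stretch, so the
fascicle — and the spindles inside it — see less.

## Synthetic trial generator

The generator exists so every pipeline stage has a test surface with known
ground truth. It is deliberately the *simplest* structure that reproduces
the phenomenology the analysis is designed to measure; it is not a
biophysical intrafusal model.

**Mechanics.** The fascicle is a quasi-static nonlinear spring with a
viscous damper and one Maxwell branch, in series with a Hookean element:

    F_fas = k_lin·x + k_quad·x² + c_damp·ẋ + q,   q̇ = k_relax·ẋ − q/τ_relax
    F_fas = k_series·(L_MTU − x)                    (force balance)

with k_series = k_tendon (CTRL) or (1/k_tendon + 1/k_see)⁻¹ (SEE). The
Maxwell branch produces hold-phase stress relaxation *and* fascicle creep
(as q decays at constant MTU length, the fascicle lengthens while force
falls); the damper makes force rise faster than its quasi-static value at
stretch onset, which is what drives the initial burst in the rate model
below. No active (Hill-type) element is included: all trials are passive.

Integration is per-sample implicit Euler; substituting the Maxwell update
into the balance leaves one quadratic in x per step, solved in closed form
(the smaller-compliance root). When damping and relaxation are zero the
scheme degenerates to the exact algebraic spring-in-series solution at
every sample, which is what the analytic recovery tests exploit. A
negative discriminant (unreachable with physical parameters) raises an
error naming the failing time index. The property "fascicle force equals
series-element force to ≤ 1e-6 N at every sample" is checked by an
independent reconstruction of the damper and Maxwell forces from the
solved trajectory.

**Firing.** A rectified force/yank rate model:

    r(t) = max(0, r0 + kF·F(t) + kY·[dF/dt]₊·g(t))

where g = 1 on the first stretch (or first sinusoid cycle) of a trial and
1 − slack_gain afterwards. The g-gate is a phenomenological stand-in for
history-dependent (thixotropic) intrafusal stiffness: it removes most of
the yank sensitivity on repeated stretches, abolishing the second-stretch
burst and attenuating the second-stretch response. It resets between
trials. Spikes come from deterministic integrate-to-threshold on the rate
trace (spike when ∫r dt crosses each successive integer, crossing times
linearly interpolated), with optional Gaussian rate noise (noise_sd,
seeded) added before integration. Identical seeds give bit-identical
trials.

**Default parameters** (the generator's study conditions, chosen once at
rat medial-gastrocnemius scale):

| parameter | default | unit | why |
|---|---|---|---|
| k_lin | 0.25 | N/mm | passive fascicle stiffness; with k_quad the force at full 3 mm stretch is ≈1.1 N, comfortably crossing the 0.5/0.4 N tangent thresholds |
| k_quad | 0.08 | N/mm² | engages nonlinear elasticity at longer stretch |
| c_damp | 0.08 | N·s/mm | onset time-constant c/(k_f+k_s) ≈ 33 ms: long enough that the onset yank transient spans several inter-spike intervals (a measurable burst), short enough to decay within the ramp burst window |
| k_tendon | 2.0 | N/mm | series (tendon) stiffness, ≈8× fascicle stiffness |
| k_see | 2.0 | N/mm | added spring equal to the tendon: SEE halves the series stiffness |
| k_relax, τ_relax | 0.15 N/mm, 0.4 s | hold-phase force relaxation of ≈0.2–0.3 N over the 1 s hold, with concurrent fascicle creep |
| kF | 6 | pps/N | static sensitivity: hold-phase rate ≈ 12 pps |
| kY | 16 | pps·s/N | yank sensitivity: ramp-onset burst in the hundreds of pps |
| r0 | 5 | pps | background drive so firing never ceases in sinusoids |
| slack_gain | 0.85 | – | second-stretch yank attenuation; see below |
| noise_sd | 2 | pps | per-sample rate noise (averages out over an ISI) |

The burst must *out-rate* the rest of the lengthening by the 2×-median
discernibility rule (below). The ratio of onset yank (k_s·v) to late-ramp
yank (≈k_MTU·v) is (k_f+k_s)/k_f, so the balance between kY and kF decides
whether slow (3.5 mm/s) triangle stretches produce a discernible burst at
all; the defaults were set so that CTRL triangles burst on the first
stretch and not the second. Two knock-on behaviours are worth knowing:

- Under SEE the onset yank halves and the damping transient doubles, which
  pushes the SEE burst below the discernibility rule — the synthetic SEE
  effect on IB is therefore *stronger* (reduction to 0) than real data
  shows (reduction, not abolition).
- At small slack_gain (≲0.3) the Maxwell branch's carryover (the second
  stretch starts from a pre-stressed state and develops more yank) can
  outweigh the attenuation, making the mean-IFR history dependence
  slightly negative; it is positive and monotone increasing from
  slack_gain ≈ 0.4 upward, and clearly positive at the default 0.85.
- The "SEE fascicle displacement ≤ CTRL" ordering holds through
  lengthening and hold; after release the two conditions recoil along
  different viscoelastic transients and the ordering can transiently
  invert. The property test covers onset through end-of-hold (all samples,
  strictly, in the purely elastic case).

**Between-unit variability.** `generate_dataset` scales mechanical
stiffnesses by a per-animal log-normal factor (σ = 0.15), rate gains by a
per-afferent factor (σ = 0.2) and adds a small per-trial gain jitter
(σ = 0.05), giving the random-intercept structure the mixed models assume.

**What the generator does not emulate.** Measurement noise on the
mechanical channels (force/sonomicrometry records are clean, so the
force-SNR exclusion rule only fires on deliberately corrupted fixtures);
intrafusal/extrafusal force sharing and extramysial tissue loads; phase
shifts between firing and kinematics; real thixotropic stiffness recovery
(the g-gate is binary per trial); occlusion and partial activation.
Passing tests therefore demonstrate that the *estimators* recover known
structure through the full conditioning chain — not that the generator's
firing statistics match in-vivo afferents.

## Signal conditioning

Fixed order: (1) decimate by 20 (17.8 kHz → 890 Hz) with a zero-phase FIR
anti-alias prefilter; (2) fourth-order Butterworth low-pass at 100 Hz,
applied forward–backward (zero phase); (3) second-order Savitzky–Golay
filter, window 21 samples (≈24 ms), for smoothing and first derivatives
(velocities and yank all use the same operator, for internal consistency).
Zero-phase filtering matters because the regressions align firing with
kinematic channels sample-by-sample. Savitzky–Golay of order 2 reproduces
polynomials up to quadratics exactly, which pins the derivative channels to
closed forms in tests. Records shorter than the filter warm-up raise rather
than silently truncate. Sonomicrometry is calibrated linearly (mm/V) with
only the trial's initial value subtracted (displacement convention).

Exclusion rules: trials flagged as having undiscriminable action
potentials are dropped; trials whose force SNR — peak-to-peak force during
the motion over twice the RMS of the mean-subtracted pre-stretch baseline —
falls below 2 are dropped. Every exclusion is logged with its reason; a
missing baseline skips the SNR rule with a warning.

## Stiffness and RFD estimation

Least-squares quadratic fit over the *lengthening phase only* (hysteresis
makes one polynomial over the full loop ill-posed), tangent evaluated where
the fitted curve crosses the force threshold — the first crossing on the
rising limb when two roots are admissible. RFD is the slope of the
quadratic fascicle-vs-MTU displacement fit evaluated at the MTU
displacement where *force* crosses the threshold, so all three numbers
refer to the same mechanical state. Thresholds: 0.5 N (ramps), 0.4 N
(triangles, sinusoids — slower/smaller stretches develop less force).
Unreached thresholds raise a typed error; the study level logs and skips
the trial's stiffness row. Residual RMS per fit is kept as a diagnostic.
Note that at ramp speed the damper contributes to the measured tangent
(dynamic stiffness exceeds the quasi-static value, and k_FAS acquires a
small condition dependence through the different fascicle velocities);
the closed-form recovery checks therefore use purely elastic parameters.

## Firing features

IFR convention: 1/ISI assigned to the later spike of each pair (causal).
Windowed *means* include only intervals fully contained in the window —
an anchor just after a silent gap carries the reciprocal of the whole gap
and would bias the stretch mean low (it is exactly what breaks the
identical-stretches → zero-history-dependence identity). Max-type features
(peak IFR, DR, IB) use anchor-in-window selection.

- **Initial burst**: max IFR in the first 25% of lengthening, counted only
  if it exceeds 2.0× the median IFR over the remaining lengthening, else 0.
  Window fraction and ratio are configurable and echoed into every output,
  since "discernible" has no standard operationalization.
- **DR**: max IFR in the last 20 ms of lengthening ("peak firing at the end
  of lengthening" with tolerance for spike discretization).
- **SR**: mean IFR in a ±50 ms window centred 0.5 s into the hold (a single
  spike at exactly 0.5 s would be noise-sensitive); empty windows fall back
  to the nearest spike within ±150 ms, flagged.
- **DI** = DR − SR, an exact identity by construction.
- Triangles: per-stretch mean IFR and spike count over each lengthening,
  burst rule evaluated on stretches 1 and 2 (the headline IB is stretch 1),
  history dependence = stretch 1 − stretch 2.
- Sinusoids: peak and mean IFR over cycles 2..end (cycle 1 excluded to
  ignore first-cycle history effects).

Mean IFR is the unweighted mean over spikes by default; the
count/duration (time-average) alternative is exposed as
`FeatureConfig(mean_mode="rate")` and is the convention under which the
windowed mean equals ∫r dt / T up to quantization.

Segmentation uses the commanded trajectory's exact breakpoints for
generated trials. For measured data the onset is detected on the *raw*
servo channel (finite-difference velocity exceeding 5% of the protocol
peak velocity, sustained 10 ms) and the protocol template is anchored
there; detection on the conditioned velocity would be biased ~8 ms early
by the zero-phase filters' symmetric edge smear.

## Statistics

Per-trial OLS regresses per-spike IFR on a predictor linearly interpolated
to spike times. Analysis windows follow the stretch type: sinusoid cycles
2..end, triangle stretches 2–3, ramp hold phase only (mechanical channels
are not expected to predict the dynamic components). Fewer than 3 spikes or
a constant predictor yields a flagged, undefined result rather than an
error. No phase shifts between firing and kinematics are applied.

The SEE contrast is a random-intercept linear mixed model
`y ~ see + (1 | group)` fitted by REML (statsmodels MixedLM), grouped by
animal for stiffness/RFD responses and by afferent for firing responses.
P-values are Wald z on the SEE coefficient — mildly anticonservative with
few groups compared with Satterthwaite-type degrees of freedom, which is
why the acceptance calibration tolerates a type-I rate up to 7% at nominal
5%. Singular fits (zero between-group variance) fall back to pooled OLS
with a warning; a response with no variance at all is reported as a
degenerate zero effect with p = 1. No multiple-testing correction is
applied; each metric carries its own p.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own desk-scale study conditions: analytic checks
run on single noise-free trials and 10-point stiffness grids; feature
recovery uses 100 seeded ramp trials; mixed-model calibration uses 200
replicates of 5 groups × 40 trials (balanced, intercept SD 1, residual SD
0.02, injected effect −0.083); the end-to-end synthetic study uses
5 animals × 2 afferents × 3 protocols × 2 conditions × 2 trials
(120 trials). The full in-vivo reproduction path expects the deposited
dataset converted to the CSV trial dialect (441 ramp / 120 triangle / 77
sinusoid stretches) and is reported as unavailable when absent.

## Known limitations

- The generator's firing model is linear in force and yank with a binary
  history gate; real Ia afferents show occlusion, partial recovery between
  stretches, and negative hold-phase relationships to fascicle length that
  the pipeline can *measure* but the generator only partially reproduces.
- Stiffness at ramp speeds includes a viscous component; the estimators
  report tangent slopes of what was measured, not corrected quasi-static
  stiffness.
- Spike2-native files are not read; external data enter via generic CSV
  exports plus JSON sidecars.
- Wald inference on REML fits with ≤5 groups is approximate (documented
  above); exact small-sample inference is out of scope.
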