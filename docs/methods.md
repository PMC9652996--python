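# Methods

`errp_exo` is a desk-scale simulation and analysis package for the
neuro-cognitive assessment of a soft pneumatic elbow exosuit.  It has three
layers: (i) a physical/control simulator of the exosuit's two
intention-decoding schemes and its low-level pneumatic valve controller,
(ii) a synthetic multimodal session generator (EEG/EOG, biceps/triceps EMG,
elbow kinematics) whose event-locked morphology is calibrated to the
grand-average error-related-potential and motor responses such a device
elicits, and (iii) the full decoding and statistics pipeline that detects
when the device violates the wearer's expectations.  This note documents the
models, the tunable parameters, and the design choices made where the design
was genuinely open.

## Control simulator

**High-level decoders.**  The gravity-compensation scheme decodes the
required elbow torque from the single-joint gravitational profile
τ_r = m·g·l_c·sin(π − θ_e), independent of the shoulder angle (flexion
assistance can only be applied at the elbow).  Defaults: m = 2.0 kg
(forearm + hand + distal exosuit), l_c = 0.15 m, g = 9.81 m/s².  The
myoprocessor decodes torque from EMG: the RMS envelope u ∈ [0, 1] maps to
activation a = (e^{A·u} − 1)/(e^{A} − 1) with shape factor A = −1; activation
maps to force through a quasi-static Hill-type reduction F = gain·F_max·a
(defaults gain = 0.8, F_max = 500 N; an optional three-element mode adds a
linearised force–velocity factor and a quadratic parallel-elastic term,
both of which vanish at the quasi-static operating point); force maps to
torque through angle-dependent moment arms arm_e(θ_e) = a1e + 2·a2e·θ_e
with the cadaveric coefficients (MEF: a1e = −0.014, a2e = −3.96e−3;
MEE: a1e = 0.025, a2e = −2.16e−3; metres, the convention of the
moment-arm literature these coefficients come from).

*Sign convention.*  With those coefficients the monoarticular flexor arm is
negative over [0, π], so the literal myoprocessor composition
τ = l_bi(θ)·F(a_bi) + l_tri(θ)·F(a_tri) is extension-positive while the
gravity profile is flexion-positive.  `myoprocessor_required_torque`
returns the literal composition; the closed loop applies
`flexion_sign = −1` to obtain a flexion-positive required torque comparable
with the gravity scheme.  This is the package's convention; both pieces are
exposed so either convention can be recovered.

**Actuator.**  Assistance torque is linear in gauge pressure:
τ_exo = (π·l·P/2)(r² − a²) with effective radius
a = (r + n·w/(2π − θ))·sin((2π − θ)/(2n)).  No numeric geometry is published
for this actuator, so the defaults (l = 0.30 m, r = 0.01 m, n = 10,
w = 0.01 m, θ_act = 0) were chosen to give a stall torque of ≈5 N·m at the
3 bar supply — comfortably above the ≈3 N·m gravitational demand — and are
all configurable.

**Low-level control.**  The interaction torque τ_i = τ_r − τ_exo drives a
dual-PID controller inside a state-machine envelope: |τ_i| ≤ τ_c closes both
valves; τ_c < τ_i < τ_state runs the inlet PID clamped to 50–80% opening;
−τ_state < τ_i < −τ_c runs the outlet PID clamped to 60–90%;
|τ_i| ≥ τ_state fully opens the inlet (under-assistance) or outlet
(over-assistance).  Defaults τ_c = 0.1 N·m, τ_state = 1.0 N·m,
PID (Kp, Ki, Kd) = (100, 60, 0) on both branches, anti-windup by freezing
the integral while the output saturates.  τ_i > 0 drives the inlet,
consistent with flexion-only assistance.  Control runs at 100 Hz (the rate
at which the device's kinematic state is available).

**Plants.**  Pressure follows first-order fill/vent dynamics
dP/dt = k_in(φ_in/100)(P_supply − P) − k_out(φ_out/100)P, integrated
exactly per tick and clamped to [0, 3 bar]; k_in = k_out = 8 s⁻¹ gives the
loop a ≈0.1–0.2 s pneumatic lag, which reproduces the ≈200 ms movement lag
seen in the device, and lets the no-error loop settle to |τ_i| < τ_c within
0.5 s.  The arm is a single damped rigid joint
(I = 0.06 kg·m², b = 0.8 N·m·s/rad) integrated with a semi-implicit Euler
step (bounded energy when undamped); θ_e is clamped to [0, π] with the
joint limits acting as inelastic stops.  The simulated wearer tracks a
minimum-jerk elbow reference with a PD effort torque (Kp = 25 N·m/rad,
Kd = 2.5); in the myoprocessor scheme the wearer's effort is mapped to
synthetic EMG envelopes that the decoder then reads.  Injected control
errors override the valve command (inflate → inlet forced open, release →
outlet forced open) for 400 ms — long enough to produce the error-locked
kinematic transient; configurable.

## Experiment protocol

A session is 15 blocks × 8 episodes; each episode is a random self-avoiding
4-neighbour path of 10–15 cells on an 11×6 grid.  Blocks 1–3 are
unassisted; block 4 gravity at 0% errors; blocks 5–9 gravity with rates a
seeded permutation of {0, 0, 30, 30, 30}%; block 10 myoprocessor 0%; blocks
11–15 myoprocessor with an independent permutation.  In an error block,
round(0.3·N) events are marked as errors at uniformly random positions
(round-to-nearest is unbiased at these block sizes), with type drawn
uniformly from {inflate, release}; error onset coincides with the cursor
fully entering the next grid cell, operationalised as cell-centre crossing.
Error positions may fall anywhere in an episode (no first/last-step
exclusion; configurable upstream by filtering).  Event onsets are
movement-locked: spacing is drawn from a movement-duration model (uniform
1.2–1.8 s by default; a callable hook accepts durations from the closed-loop
simulator), with 2 s between episodes and 3 s between blocks.  Non-error
steps are scored correct with probability 0.985, emulating the ≈98.5%
tracking accuracy of practised wearers.

## Synthetic cohort generator

**What it emulates.**  30 channels (27 scalp + 3 EOG, extended 10–20
montage, TP9/TP10 mastoid acquisition reference) at 1000 Hz; biceps/triceps
EMG at 2222 Hz with a 100 ms sliding-window RMS envelope at 222 Hz; elbow
angle/velocity at 100 Hz.  Event-locked EEG components are Gaussian bumps
at a peak channel (Cz) with Gaussian spatial falloff (σ = 0.6 unit-sphere
chord) over the scalp: a movement-locked response shared by both conditions
(+1.0 µV, 150 ms), and error-only components — positivity +1.2 µV at
270 ms, error-related negativity, sustained positivity +1.2 µV at
400–600 ms, late negativity −1.0 µV at 685 ms.  Component amplitudes are
defined in *post-analysis* terms, because the grand-average morphology they
must reproduce is itself measured after 1–20 Hz filtering and common
average referencing: the topography is rescaled so CAR leaves the
peak-channel weight at 1, and the ERN component (−2.74 µV at 334 ms) was
calibrated through the chain's linear steps so the filtered composite
error-minus-correct difference bottoms out at exactly −2.0 µV at 340 ms
(the flanking positivities contribute ≈ +0.7 µV there and the 1 Hz
highpass reshapes the broad composite).
Background activity is 1/f Gaussian noise (α = 1) with a 1 Hz spectral
knee; blinks are a stereotyped 300 ms biphasic waveform at 10/min with
fixed frontal projection weights, exercising the EOG-regression stage.

**Motor streams.**  EMG is a 20–450 Hz band-limited Gaussian carrier
amplitude-modulated by a normalised activation envelope: scheme-dependent
baseline (gravity 0.06 < unassisted 0.10 < myoprocessor 0.14 — gravity
compensation lowers overall muscle activation), a movement bump per event,
and an error-evoked burst beginning 0.5 s after the error trigger.
Kinematics are minimum-jerk tracking steps of alternating random direction
(≈13° per grid step) plus an error-locked flexion velocity transient
peaking 350 ms post onset at 18 °/s (gravity) or 31 °/s (myoprocessor);
those peak values are grand-average calibration targets, so the
single-trial transient amplitude is scaled up by the analytic expectation
of the trial-jitter smear (truncated-normal amplitude mean × Gaussian peak
reduction under latency jitter) to make the expected grand-average peak
equal the stated value.

**Variability.**  Between subjects: neural and EMG response amplitudes
scale by N(1, 0.25²) (truncated at 0.3), latencies shift by N(0, 15 ms),
noise level by a 10% lognormal — reproducing the reported inter-subject
ERP heterogeneity.  The velocity transient scales with a tighter
N(1, 0.10²) subject factor: it is device-driven (valve override → pressure
drop → arm acceleration), so its amplitude varies far less between wearers
than neural responses do.  Within subjects, single-trial motor responses
scale by N(1, 0.5²) (truncated at 0.05) with trial-level latency jitter
(EMG 80 ms, velocity 30 ms): wearers react strongly to some errors and
barely to others; without this the motor decoders would be trivially
perfect, which no real session shows.  Trial amplitude jitter has mean ≈1,
so grand-average morphology is preserved.

**Noise calibration.**  No single-trial SNR is published for this
paradigm, so the EEG noise RMS is the generator's calibration dial: the
default (3.5 µV broadband per channel) was set so that an average-amplitude
subject's EEG decoder lands in the 70–85% range typical of single-trial
ErrP classification; cohort grand means then land in the high-60s to
high-70s depending on the drawn subject amplitudes.
`effect_scale` scales every error-specific component (EEG, EMG burst,
velocity transient); 0 makes the two trial classes statistically identical
— the null generator used for calibration tests.

**What it does not emulate.**  No biophysical head model (topographies are
parametric), no saccades, no realistic EMG spectra beyond a band-limited
carrier, no non-stationarity/fatigue, no visual-evoked confound between
cursor and proprioceptive feedback.  Passing tests therefore show the
*pipeline* recovers what the generator puts in at realistic SNR — not that
real recordings would decode at these exact accuracies.

## Preprocessing

EEG and EOG: zero-phase Hamming windowed sinc FIR bandpass 1–20 Hz (MNE's
FIR designer); bad channels flagged when their excess-kurtosis z-score
across channels exceeds the two-sided 5% normal bound (1.96), one pass, and
replaced by spherical-spline interpolation (inverse-distance weighting
available); blink correction by least-squares regression of each scalp
channel on the three EOG channels, with coefficients fitted on the
continuous filtered record (stable with short epochs); common average
reference over the scalp channels only (EOG excluded by default; an all-zero
EOG record is treated as "nothing to regress" rather than an error).  No
baseline correction is applied to epochs (available as an option, default
off).  Epoch windows are half-open in samples — [0, 1.0) s for EEG (exactly
1000 samples at 1 kHz), [−0.2, 1.5) s for EMG envelopes and kinematics —
and trials whose window leaves the recording are dropped with a log entry.

## Decoding

EEG features: epochs decimated to 125 Hz (zero-phase anti-alias FIR) on the
11-channel fronto-central subset {Fz, F3, FC1, C3, Cz, C4, T8, FC6, FC2,
F4, F8} and flattened — 11 × 125 = 1375 features per trial.  A config
option (`bin_ms = 55`) averages the window into 18 temporal bins for
11 × 18 = 198 features, the "approximately 200 features" layout; the
full-resolution layout is the default.  EMG features are the two RMS
envelopes over the epoch; kinematic features the raw angular-velocity
trace.  PCA (95% retained variance, fitted on training folds only) precedes
a shrinkage-regularised LDA on the pooled within-class covariance
Σ_λ = (1−λ)Σ + λ(tr Σ/d)I, λ by the analytic Ledoit–Wolf estimate.  Fisher
scores (μ₁−μ₀)²/(σ₁²+σ₀²) are a diagnostic ranking, not a selection step
(optional pre-selection behind a flag).  Validation is stratified 10-fold
CV, re-randomised over 10 repeats (stratification protects against
empty-error folds at the 30% rate); PCA and the classifier never see test
folds.

**Classifier threshold de-biasing.**  With 30/70 class imbalance, plug-in
LDA is majority-biased: the minority mean is estimated with more noise,
inflating ‖μ̂₁−μ̂₀‖ along the discriminant and shifting the score at the
true common mean by −tr(Σ_λ⁻¹Σ)(1/n₁−1/n₀)/2.  `rlda_fit` estimates and
cancels this term, so label-free data scores at chance irrespective of the
class ratio.  Class priors are equal (standard in ErrP decoding); ties
resolve to non-error.

**Statistical behaviour of CV accuracy.**  Even after de-biasing,
cross-validated accuracy on null data at the default EEG shape (n ≈ 590
trials, 1375 features) has a standard deviation of ≈3% — wider than the
binomial 2% — because fold predictions are dependent and the classifier is
strongly overparameterised.  Chance-level detection therefore uses a 2.5×
inflated binomial half-width in the pipeline report, and the null-
calibration test compares the observed accuracy against a label-permutation
distribution rather than a plain binomial interval.  The low-dimensional
EMG and kinematic decoders do satisfy the plain binomial interval.

## Statistics

Channel × time significance maps compare error vs non-error trial
distributions per cell with the two-group Tukey HSD, evaluated through the
exact two-group identity Q = √2·|T| (k = 2, df = n₁+n₀−2), which vectorises
over all cells ~10⁴× faster than the generic studentized-range integral and
agrees with it to numerical precision; no correction is
applied across cells beyond Tukey's per-cell family handling, mirroring how
such maps are usually presented (a Bonferroni option exists; the per-cell
Tukey over thousands of cells is reported as-is without endorsing its
family-wise error control).  Condition comparisons: Tukey HSD across the
three tracking-accuracy conditions; paired t-tests between the two assisted
schemes' decoding accuracies, preceded by a Lilliefors normality screen of
the paired differences (degenerate zero-spread differences skip the screen).
ERP similarity is the Pearson correlation of two waveforms over the
300–400 ms negative deflection.  The power extrapolation replicates each
subject's paired difference k times and recomputes the paired t-test at
each total n — the t statistic grows as √n at fixed mean/SD, answering how
many identically behaving subjects would make the scheme contrast
significant.

## Problem sizes

The default cohort is 5 subjects at full protocol size (≈1500 events,
≈42 min of multichannel signal per subject); one subject generates in
≈10 s and preprocesses in ≈30 s on one core, so cohort-level analyses
(generation + preprocessing + repeated CV for three modalities) complete in
minutes.  Unit tests run on a structurally identical session with 2
episodes per block.  Streams are float32 end to end; all randomness derives
from one master seed through `numpy.random.SeedSequence` spawning, making
every session byte-reproducible.

## Known limitations

- The actuator geometry, PID gains, plant constants and wearer impedance
  are plausible engineering defaults, not identified from hardware.
- The Tukey map inherits the per-cell error-control caveat above.
- The generator's ERP topography is spatially smooth and unit-sphere
  parametric; interpolation accuracy on it is better than on real data.
- Reported decoding accuracies characterise the synthetic conditions; they
  are plausibility-matched to, not estimates of, real-device performance.
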