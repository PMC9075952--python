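# Methods

`vermispop` re-implements, as a tested pipeline, the analysis of how cerebellar
Purkinje cells in the anterior vermis integrate vestibular (semicircular-canal)
and neck-proprioceptive signals, and how a population of such cells can explain
the more stereotyped responses of their targets in the rostral fastigial
nucleus (rFN). This note documents the models, the synthetic world they are
exercised on, the numerical choices, and the known limitations.

## 1. Stimulus paradigms

Three dynamic rotation conditions about the earth-vertical axis, all sampled at
1 kHz:

- **whole-body** — head and body rotate together (canals driven, neck not);
- **body-under-head** — body rotates under an earth-fixed head (neck driven,
  canals not);
- **head-on-body** — head rotates on an earth-fixed body (both driven).

The dynamic waveform is "active-like": alternating raised-cosine velocity
pulses, v(t) = V/2·(1 − cos 2πt/T), with half-cycle T = 500 ms and displacement
±30°, hence V = 2·30/0.5 = 120 °/s. The raised cosine is a smooth,
unidirectional profile resembling the head trajectory of ±30° orienting gaze
shifts; its 500-ms half-cycle makes the dominant frequency 1 Hz, which is why
phasors are evaluated at f = 1 Hz. A fourth, **gain-field**, condition applies
1-Hz ±40 °/s whole-body sinusoids with the head statically oriented at one of
five positions on the body (−30, −15, 0, 15, 30°).

Movement **direction** (ipsi/contra) is labeled per half-cycle by the sign of
the driving channel's velocity; ipsi is positive velocity by convention (the
synthetic world fixes laterality).

## 2. Firing-rate model and constrained fit

Per movement direction, a cell's firing rate on one channel (head or body
kinematics X, Ẋ, Ẍ) is

    fr(t) = b + c_p·X(t) + c_v·Ẋ(t) + c_a·Ẍ(t)

with the three kinematic coefficients constrained to share one sign. The fit is
solved once under a non-negative and once under a non-positive criterion and
the branch with lower residual sum of squares is kept; the branch choice is
made independently per direction, while the bias b is shared across the two
directions of a condition. For head-on-body rotations the vestibular and neck
contributions are not separable and a single coefficient set on the
head-on-body channel is estimated.

Numerically, fits are assembled from per-segment Gram matrices and solved by an
eigenvalue square-root plus NNLS, with the free bias split into a ± pair of
non-negative variables. Columns are rescaled to unit diagonal and a relative
ridge of 1e−11 is added before the eigendecomposition: pure sinusoids make
position and acceleration exactly collinear (Ẍ = −ω²X), and the ridge pins the
RSS-flat ridge of solutions to its minimum-norm point without measurably
biasing well-posed fits (verified against a box-constrained least-squares
oracle on the raw design to ~1e−15 relative RSS). The (sensitivity, phase)
summary is invariant along that ridge, so gain-field sinusoid fits remain fully
interpretable. A rank error is raised only when a fitted channel carries no
kinematic signal at all.

**Sensitivity and phase.** At frequency f (default 1 Hz), with ω = 2πf,

    S = sqrt((ω²c_a − c_p)² + (ω c_v)²) / ω        [(sp/s)/(°/s)]
    φ = atan2(ω²c_a − c_p, ω c_v)                   [degrees]

S is the gain relative to angular velocity, which keeps units consistent with
every sensitivity quoted in the field. The quadrant-aware atan2 makes
anti-phase (non-positive-branch) responses land beyond ±90°, so Type II
responses near ±172° are representable; the constraint branch (±1) is also
carried explicitly as the sign term. The inverse map (used by the generator)
places the quadrature component in position *or* acceleration, whichever keeps
the triple sign-consistent; any triple realizing (S, φ) at 1 Hz is equivalent
for every downstream quantity.

**Bootstrap pruning.** Significance is assessed by resampling whole movement
segments with replacement (jointly across directions; the segment is the
resampling unit to respect temporal autocorrelation), n = 2000 draws by
default, α = 0.05. Two deliberate choices differ from the obvious recipe:

1. *Per-draw refits are sign-unconstrained.* The constrained estimator folds
   at the zero boundary, so the bootstrap distribution of a true-zero
   coefficient lies almost entirely strictly inside the feasible half-line and
   a percentile interval essentially never covers zero — pruning would never
   fire. The unconstrained refit has the symmetric sampling distribution an
   interval test assumes. The final reported model is still the
   sign-constrained fit on the retained terms.
2. *Intervals are symmetrized*, θ̂ ± q₀.₉₇₅(|θ* − θ̂|), centered on the
   full-sample unconstrained estimate. With only ~20 resample units, raw
   percentile intervals under-cover (measured true-zero rejection ≈ 7% instead
   of 5%); the symmetrized form restores near-nominal calibration (≈ 4%).

Coefficients whose interval contains zero (including intervals touching the
boundary exactly) are set to zero and the constrained model is refit. Note the
family-wise consequence: a cell with six true-zero neck coefficients has
≈ 1 − 0.96⁶ ≈ 20% probability of at least one false survivor, which inflates
the recovered bimodal fraction above the generated one. This is a property of
the per-coefficient testing procedure itself, reproduced deliberately.

**VAF** = 1 − var(observed − fitted)/var(observed); NaN for a constant
observed trace; invariant under common affine rescaling.

## 3. Ground-truth neurons and the synthetic population

Each synthetic cell holds a baseline (sp/s) and a sign-consistent coefficient
triple per (modality, direction). Rates are rectified at 0 sp/s and the
rectified fraction is logged so analyses can exclude heavily clipped cells.
Direction switching follows the stimulus's segment labels (equivalently, the
driving velocity's sign away from zero crossings).

Population sampling realizes the recorded statistics: 54/73 bimodal, 32/73
Type I (preferred direction ipsilateral); vestibular preferred-direction
phasors drawn from 0.42 ± 0.37 (sp/s)/(°/s) at 6 ± 31° (Type I) and
0.31 ± 0.34 at 172 ± 42° (Type II); proprioceptive phasors from 0.12 ± 0.44 at
159 ± 29° and 0.13 ± 0.46 at −27 ± 20°. Sensitivity magnitudes are truncated
to [0.05, 1.5] (proprioceptive floor 0.08 so "bimodal" is detectable at the
study's noise level). Counts of bimodal/Type-I cells are exact (rounded
fractions, shuffled assignment) rather than binomial. The non-preferred
direction is constructed from a tuning-shape mix — linear 40%, rectifying 35%,
v-shaped 20%, other 5%, a plausible mix chosen once for this generator (the
source distribution is not printed) — using the 0.2 (sp/s)/(°/s) conventions
of §5. Baselines are N(80, 15) sp/s clipped at 10, keeping rectification rare
at the drawn sensitivities; rate noise is white Gaussian (default SD 5 sp/s
for noisy studies).

**Combined-condition convention.** During head-on-body rotation the neck is
stimulated in the complementary direction to the head's movement. Measuring
one and the same neck-driven response against the body channel
(body-under-head) versus the head-on-body channel flips the sign of the
reference, which would force a 180° rotation into any phasor bookkeeping. The
generator absorbs that sign into the coefficient definition: in the combined
condition the *opposite-direction* proprioceptive coefficients apply to the
head-on-body channel directly. With this convention the linear-summation
prediction — vestibular phasor plus complementary-direction proprioceptive
phasor, no rotation — is exact by construction for non-rectifying cells,
matching how the summation model is defined and used.

**Spikes.** Inhomogeneous Poisson: per-bin counts at the grid resolution,
spike times uniform within bins, strictly ordered, seed-reproducible. Firing
rates are recovered by convolving the delta train with a unit-DC-gain Kaiser
FIR low-pass (β = 6, configurable; length ≈ 3/cutoff) cut off at twice the
stimulus frequency range — 2 Hz for the 1-Hz sinusoids, 4 Hz for the 500-ms
transients (range taken as the reciprocal of the half-cycle). The kernel's
negative sidelobes are *not* clipped: clipping would break linearity and
inflate the single-spike area by ~14%.

## 4. Gain fields

A cell's tuning is stored as the measured curve S(p) = A·exp(−(p−μ)²/2σ²) over
static head-on-body position p; the rate model multiplies the vestibular drive
by S(p)/S_pref, evaluated at the instantaneous head-on-body position. Sampled
bimodal cells are made self-consistent — A = S_pref·exp(μ²/2σ²) with
μ ~ N(0, 5°), σ ~ N(7.2, 2)° clipped at 3° — so that their dynamic-condition
sensitivity equals the tuning curve at 0°. Unimodal cells carry no tuning.
Imputed tuning (for cells "not held long enough" to test) is drawn from normal
distributions fitted to the tuned cells' (A, μ, σ) and need not be
self-consistent, mirroring the imputation procedure it emulates.

Gaussian fits use multi-start bounded nonlinear least squares (starts at the
highest observed points with several initial widths; μ ∈ [−45, 45]°,
σ ∈ (0, 90]° — five-point designs are under-determined for very wide curves,
so the width bound plus the reported RMSE let downstream code filter).
"Untuned" means fitted A < 0.1 (sp/s)/(°/s), or no AIC improvement over the
constant model, or nearly flat data; this threshold is a package convention.
At the study conditions (15°-spaced positions, σ ≈ 7.2° ≪ spacing, noise SD
0.05) the median relative amplitude error is ≈ 10% and is statistics-limited:
a dense global search never improves on the multi-start optimum.

Peak-aligned averages evaluate each tuned cell's *fitted* Gaussian, shifted so
its peak sits at zero, on a common grid; linearly interpolating the five coarse
raw samples instead would undershoot every peak by ~20% and make averages of
identical cells disagree with the single cell. The confidence band is a
cell-level bootstrap.

## 5. Taxonomy

- **Preferred direction**: the direction with the (larger) excitatory response;
  excitatory in a direction means the constraint branch that raises firing for
  motion in that direction (+ for ipsi, − for contra). Bidirectionally
  excitatory (v-shaped) cells take the larger sensitivity; exact ties break to
  ipsi; cells with no excitatory direction are flagged and take the larger |S|.
- **Type I/II** = preferred direction ipsi/contra.
- **Unimodal/bimodal**: unimodal iff every proprioceptive coefficient is
  pruned to zero in both directions.
- **Shape** (threshold 0.2 (sp/s)/(°/s), first matching rule wins):
  *linear* — excitatory preferred, inhibitory non-preferred, magnitudes within
  the threshold; *rectifying* — excitatory preferred, non-preferred magnitude
  below the threshold; *v-shaped* — excitatory both ways, magnitudes within
  the threshold; *other* — anything else (including inhibitory-only cells,
  an edge this package covers explicitly).

## 6. Summation model and reference-frame metrics

The combined-condition response is predicted as the complex sum
S_v·e^{jφ_v} + S_p·e^{jφ_p} of the vestibular phasor in the tested direction
and the proprioceptive phasor in the complementary body-under-head direction
(pairing table explicit in `summation.COMBINED_PAIRING`). Population agreement
is summarized by OLS of estimated on predicted, for sensitivity and for phase
(estimated phases unwrapped about their prediction to avoid ±180° artifacts);
the slope's t-test against 1 treats numerically perfect fits as p = 1. OLS
rather than orthogonal regression is a declared choice.

Note a structural effect: a combined response that is the sum of a
positive-branch and a negative-branch triple can itself be sign-inconsistent,
which the constrained combined fit cannot represent exactly. Summation R²
below 1 on heterogeneous populations (≈ 0.96–0.98 noiseless at the default
mix) reflects this model property, not fitting error; exactness tests use
cells whose summed triples stay sign-consistent.

Per cell, head ratio = S_combined/S_vest and body ratio = S_prop/S_vest (an
ideal head encoder sits at (1, 0), an ideal body encoder at (0, 1)); the
coding index is min/max of the two ratios, signed positive when the vestibular
and proprioceptive phasors are within 90° of each other (ties antagonistic).
The head/body/intermediate designation uses cutoffs head-ratio ≥ 0.8 with
body-ratio ≤ 0.2 (and symmetrically) — configurable package conventions, as
the underlying percentages were reported without a printed rule.

## 7. Population model

An rFN-like rate is reconstructed as rFN̂(t) = Σ wᵢ·Pcellᵢ(t) with every
Purkinje weight wᵢ ≤ 0 (inhibitory synapses), optional mossy-fiber inputs with
weights ≥ 0 (excitatory), and a free intercept — without one, non-positive
weights cannot match a positive-baseline target; the intercept is a declared
addition. Fits use bounded-variable least squares on the condition-concatenated
traces (equal weight per sample), decimated to 50–100 Hz since all responses
are band-limited below ~4 Hz.

The size sweep draws `n_boot` random subsets of n cells (without replacement
within a draw, independent across draws; a single deterministic subset when
n equals the pool), refits each, and records R² with percentile intervals and
the pointwise 95% band of the predictions. The **matching size** is the
smallest n whose prediction band intersects the target's variability band at
every time point. The target band is the pointwise 2.5–97.5 percentile of the
single-trial target responses — the variability of the signal being explained.
(A standard error of the trial mean shrinks as 1/√n_trials below the model's
representational error floor, which would leave the matching size undefined
for any reasonable trial count.)

Mossy fibers respond as the sum of independent vestibular and neck (gain,
phase) phasors, drawn from 0.6 ± 0.1 (sp/s)/(°/s) and 20 ± 5° (the reference
distribution), with doubled/halved gain (1.2 ± 0.2, 0.3 ± 0.05) and phase
(40 ± 10°, 10 ± 2.5°) variants. The robustness harness reruns the sweep per
variant over repeated mossy draws and reports the matching size per simulation
with its dispersion.

**Low-rank caveat.** Noiseless generator rates are exact linear combinations
of the per-condition masked kinematic basis plus a constant (rank ≈ 19 over
the three dynamic conditions), so (i) a full-pool fit identifies weights only
up to that span — weight-recovery checks therefore fit the constructor cells,
while full-pool checks assert exact target reproduction — and (ii) small
subsets already span much of the response space, so matching sizes on
synthetic targets are smaller than for real heterogeneous neurons, whose
trial noise and nonlinearities break this degeneracy. The sweep's saturating
shape is reproduced; its absolute scale is generator-dependent.

## 8. Problem sizes and defaults

Library defaults follow the study conditions (1-kHz grid, n = 2000 bootstrap,
five gain-field positions, 73-cell pools). The test-suite and acceptance
script use desk-scale sizes chosen once: 5–10 movement repeats per condition
(10–20 segments), bootstrap pruning studies at n = 300 draws, 200-replicate
recovery studies, population sweeps at 60–100 subsets per size on 50–100-Hz
traces, and 20 mossy simulations per variant (100 in total across the five
distributions). All randomness flows from explicit seeds; every generator is
deterministic under a fixed seed.

## 9. What passing tests do and do not show

The synthetic world reproduces the statistical structure the analysis assumes:
phasor-consistent kinematic responses, direction-dependent sign-consistent
coefficients, the bimodal/unimodal and Type I/II mixes, Gaussian gain fields,
Poisson spiking, and non-positive pooling. It does not emulate: eye-movement
signals or their screening, complex spikes, spike-sorting artifacts,
neuron-to-neuron correlations or synchrony, non-Gaussian rate noise,
history-dependent (adaptation) dynamics, or the high intrinsic dimensionality
of real population activity (see the low-rank caveat). Passing tests certify
the pipeline's correctness and calibration on data obeying its own model
class; agreement with any particular recorded dataset is a separate, empirical
question.
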