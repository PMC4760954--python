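# Methods

This note documents the models, estimators and numerical choices behind
`seqsel`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem left the design open.

## Task model

Seven gamble options pay a minimum of 1 reward unit (30 µl) and a
maximum of 3, 5 or 9 units with probability 0.2, 0.4 or 0.8; the two
corner cells of the 3×3 design (expected values 1.4 and 7.4) are not in
the set, so expected value is matched along the three diagonals
(1.8 / 2.6 / 4.2 units).  Blocks hold 28 trials: each of the 21
unordered gamble pairs once as a choice trial (two targets at distinct
random directions among 45°/135°/225°/315°, 10° eccentricity implied)
and each gamble once as a forced single-target trial, in random order.

Default subjective values ψ are a mildly risk-seeking transform of
expected value, EV + 0.1·max_reward, min-max normalized.  The transform
is monotone in EV, and it exists because the equal-EV diagonals would
otherwise collapse the 7 value levels to 3, making every 7-level
analysis (value binning, binarized value decoding, value templates)
degenerate.  Any monotone ψ can be supplied instead.

## Behavior

Choices follow a Thurstonian rule: each offered option's ψ is corrupted
by independent Gaussian noise of SD σ_d (default 0.15) and the noisy
maximum is chosen.  The implied psychometric function is
Φ(Δψ/(σ_d·√2)); the difference-scaling fit estimates noise on the
difference scale, so it recovers σ_d·√2 from generator data.  Reaction
times are rt_base − rt_slope·drive + Gaussian noise (defaults 280 ms,
40 ms per unit value, SD 25 ms, floor 120 ms), with drive the target's ψ
on forced trials and the chosen option's signed ψ advantage on choice
trials.

The MLDS likelihood is maximized in the unanchored difference
parametrization (u₁ = 0, unit noise), where it is a log-concave probit
likelihood; ψ and σ_d are recovered by affine re-anchoring, which also
makes the fit equivariant under relabeling of options.  Eight jittered
multi-starts guard the quasi-Newton optimizer.  Degenerate data (no
preference information) is flagged as `sigma_unbounded` rather than
returning an arbitrary scale.  Choice trials with Δψ below −0.5
(anomalously fast choices of dominated options) are excluded from the RT
regression only.

## Spike-rate estimation

Spike density functions use a **causal** half-Gaussian kernel, σ = 10 ms
truncated at 4σ, unit integral, at 1 ms resolution.  Causality is a
deliberate choice: the package's headline quantities are onset
latencies, and a symmetric kernel moves signal backward in time, biasing
onsets early by up to its half-width — in pilots a symmetric kernel
shifted strong direction-signal onsets ~25 ms before their true latency
while weak value signals were detected late, distorting the latency
*gap* in both directions.  With a causal kernel every onset estimate
lags its true latency by a small positive amount (ramp time plus kernel
rise, ~15–30 ms here), which cancels in first order when comparing two
onsets.  `gaussian_kernel(causal=False)` restores the symmetric form.
All windows are half-open `[lo, hi)` in ms; negative times precede the
alignment event.

## Ground-truth generator

Each simulated unit has baseline b₀, value weight b₁ with sigmoid
(s, t), direction weight b₂ with circular Gaussian (w, p), optional
interaction b₃, an undifferentiated visual amplitude, and
relative-action-value weights β_PD > 0 ≥ β_NPD.  The rate on a trial is
composed per 1 ms bin:

1. baseline throughout;
2. from 50 ms after target onset, a visual response to *both* targets,
   each weighted by the unit's direction tuning (ramp 20 ms);
3. from L_value = 110 ms before saccade onset, the chosen-option value
   term b₁·f(ψ_chosen).  It is gated off only when the sole target sits
   in the unit's anti-preferred direction — a unit not engaged by the
   display expresses no value modulation (this reproduces the flat
   value dependence of forced NPD trials), while in choice trials the
   gate is always open, so within a fixed target configuration the term
   carries no direction information before L_dir;
4. from L_dir = 60 ms before saccade onset, the direction term
   b₂·g(D_chosen), plus β_PD·ψ of the target at the unit's PD and, on
   choice trials, β_NPD·ψ of the target opposite it.

Spikes are drawn per 1 ms bin as Poisson counts at the bin's constant
rate (exact for a piecewise-constant intensity) and jittered uniformly
within the bin; negative composed rates are clipped at zero.

Default population: 60 units, PDs balanced over the four directions with
±15° jitter, b₀ ~ U(5,15), b₁ ~ U(60,90), b₂ ~ U(26,34),
s ~ U(0.6,1.0), t ~ U(0.35,0.65), w ~ U(1.5,3.0), visual amplitude
U(4,10) sp/s, β_PD = 20 and β_NPD = −10 sp/s per unit ψ (the planted
2 : −1 opposition).  The amplitudes were calibrated once, during
generator design, so that the planted geometry survives the estimators'
own attenuation at this scale: the value modulation must be strong
enough to be seen through the template-noise attenuation of the
decomposition (30 forced trials per value level in 20 ms windows), and
the measured PD/NPD slope ratio must center on the planted 2 : −1
*after* the choice-mediated contributions the regression design itself
introduces (higher PD value → PD more often chosen → direction term
engaged).  They were not revisited afterwards.

What the generator does **not** emulate: biophysical competition (the
latencies and the NPD suppression are planted phenomenologically, not
produced by an inhibitory circuit), rate adaptation and history effects,
across-trial nonstationarity, correlated noise between units, and error
dynamics such as change-of-mind trajectories.  Passing tests therefore
show that the estimators recover planted effects of realistic size from
realistic Poisson variability — not that real cortical data would be
this well-behaved.

## Decoding

Per unit and 1 ms bin, a one-dimensional Fisher discriminant (equal
priors, pooled variance — nearest class mean) evaluated leave-one-out;
per-bin significance from ≥ 1000 label permutations; a unit's onset is
the first bin of ≥ 10 consecutive significant bins.  Chosen-direction
decoding is stratified by target configuration: the classifier is
trained and tested within trials sharing the same unordered pair of
target locations, and label shuffles stay within configuration.
Without this the direction-tuned visual response to the configuration
itself decodes "chosen direction" from trial start (observed: 0.54
accuracy 150 ms before the planted direction latency).  Within-group
leave-one-out accuracy is pessimistically biased under class imbalance;
the within-group permutation null shares the bias, so p-values remain
calibrated.  Chosen-option labels are a median split of chosen ψ with
ties assigned to balance classes.

## Mutual information

4 activity bins × 4 variable bins per 1 ms time bin.  Activity
boundaries are forced-trial quartiles at the same time bin (midpoints
between the flanking order statistics), applied to all conditions; the
7 value levels pack into 4 ordered groups of sizes (2,2,2,1); the 4
directions map one-to-one.  The plug-in estimate is corrected by the
first-order bias (U_FX − U_F − U_X + 1)/(2·M·ln 2), then residually
debiased by the mean of 100 within-time-bin permutations; significance
compares the corrected estimate with the sixth-highest permutation value
(empirical p ≤ 0.05); non-significant or negative results are zero and
estimates are capped at the 2-bit ceiling (the cap matters only for
degenerate near-diagonal tables where the first-order term is negative).
Population onsets: per-bin paired t-test of chosen vs non-chosen MI
across units, first run of ≥ 10 consecutive bins with p < 0.05 and a
positive mean difference.  The chosen-vs-non-chosen *difference* is what
makes the onset immune to configuration leakage, which enters both
sides symmetrically.

## Template decomposition

Forced-trial templates per direction (4) and per value level (7) on a
sliding 20 ms window, 10 ms step, −200 to +20 ms; cells with fewer than
3 trials are masked.  Choice-trial rates are regressed on the chosen and
non-chosen attribute's templates with **no intercept**, exactly as the
model is written; steps with masked or near-collinear templates
(condition number > 1e8) are masked.  The population onset is the first
run of ≥ 3 steps (10 ms each) with a paired t-test of b₁ vs b₂ across
units at p < 0.05 and positive mean difference.  Template estimation
noise attenuates b₁ − b₂ substantially (errors-in-regressors with ~30
trials per value cell); this attenuation, not the estimator, limits how
early the value-sort onset can be detected at desk scale.

## Value-effect regression

Activity is the pre-saccadic window mean (−50 to +20 ms), normalized per
unit by the min/max of its chosen-direction × trial-type condition
means.  Value bands on the 7-level rank scale: low 1–2, medium 3–5,
high 6–7.  For each mode the varied slot's per-level activity is
averaged within units, then across units, and the level means are
regressed on ψ (t-test on the slope, df = levels − 2).  The choice modes
hold the other slot at medium value.  The recovered PD slope is larger
than β_PD alone and the NPD slope than β_NPD alone because choices
mediate additional value dependence; the *ratio* near 2 : −1 is the
meaningful recovery target and is insensitive to the normalization.

## Action value map

Per unit, the 16 condition means (12 choice: chosen direction × relative
placement of the other target; 4 forced directions) define the map
normalization: the −50 to 0 ms pre-target mean across conditions maps to
0 and the condition-set maximum to 1.  Rows are the unit's fitted PD
minus the chosen target's direction (mod 360°), circularly interpolated
to a 7.2° grid.  Onset statistics use units whose PD is within ±30° of
the relevant target; the reference is the non-chosen target's band
(choice) or the 240–300° relative band (forced trials); background is
the −20 to 0 ms pre-target rate.  Significance is a sign-flip
permutation across units of the per-unit difference, with a
**studentized max-statistic** correction over time bins: with raw means
the large sustained late effects dominate the familywise threshold and
early onsets are missed by construction; the max-t statistic is
scale-free per bin.  The value-difference split partitions choice trials
at |Δψ| = 0.4 (boundary to "large") and greedily drops extreme trials
until the two sides' mean chosen ψ agree within 0.02.

## State space

Responses in 10 ms bins from −200 to +10 ms re saccade, z-scored per
unit over all choice trials and bins (pooled).  Per unit and bin, a
regression on chosen direction (left/right and up/down, ±1), chosen ψ,
their non-chosen counterparts and a single intercept (the
typographically duplicated intercept slot in the source model is read as
one intercept).  For each named axis the across-unit coefficient vector
at its maximal-norm time is taken; the three axes (direction-LR,
direction-UD, chosen value — the fixed QR order) are orthogonalized by
QR with signs aligned to their sources.  No PCA denoising is applied.
Condition averages for the variance-explained analysis use **diagonal
(180°-apart) configurations only**: with mixed configurations the tuned
visual response makes chosen-direction condition means differ from trial
start (a direction-axis onset ~185 ms before saccade in pilots, pure
configuration leakage), whereas in diagonal configurations the
configuration component is balanced across direction conditions for a
PD-balanced population.  Axes themselves are estimated from all choice
trials, where the design is full rank.  The permutation null shuffles
trial-condition assignments; an axis onset is the first run of ≥ 3 bins
above the per-bin 95th percentile.

Endpoint-distance regressions pool within-group condition pairs
(distance vs |Δψ|).  At 60 units the chosen-value separation is strongly
significant; the non-chosen-value separation is a second-order effect
(it reaches the projected axes only through the 2 : −1 suppression
weight) whose slope is reliably positive but whose t-test is
underpowered at this scale.

## Tuning fits and screening

Nonlinear least squares per model with up to 12 deduplicated starts
(p at each tested direction × a coarse (s,t,w) grid), bounds
s ∈ (0,1], t ∈ (0,1), w ∈ (0,4π], trf algorithm, tolerance 1e-8.  BIC
counts k as the number of included terms — the deliberately loose
convention that retains marginal units.  Two consequences are worth
knowing: the interaction term h nests g at equal counted complexity, so
"directional" is the recoverable classification (a circular-Gaussian
*term* in the winner), not the exact term identity; and on pure-noise
data h's uncounted shape parameters let it beat the constant model in a
sizeable minority of units, so the constant model wins a clear majority
but not near-always.  The preferred direction is defined as the
direction where the fitted profile is maximal (a negative direction
amplitude is a sign-flipped tuning curve whose raw p marks the trough).
PD identifiability with only four tested directions degrades sharply for
narrow tuning (the flanking directions carry e^{−w} of the peak): at
b₂ = 4 × noise SD, the exact-interpolation estimator keeps 90% of errors
below 15° only for w ≲ 1.6, which is why the recovery tests use broad
tuning.  The task-related screen compares each 50 ms task interval
(50–200 ms post-target, 150–0 ms pre-saccade) against the 200–150 ms
pre-target baseline by label permutation, any interval at p ≤ 0.05
sufficing — a deliberately liberal, uncorrected screen.

## Problem sizes

The reference study condition is 60 units × 30 blocks (840 trials);
the test suite runs this once (shared fixture) for the latency-recovery
and value-signature checks and uses smaller populations (8–24 units,
2–20 blocks) for structural and null-calibration tests, with permutation
counts of 300–1000 chosen to keep empirical p-value resolution below the
thresholds tested.  `scripts/acceptance.py` regenerates the full default
session and reruns every stage at the given seed.

## Known limitations

* Onset estimates are biased late by ramp + causal-kernel lag
  (~15–30 ms); comparisons of onsets are much more accurate than single
  onsets.
* The MI estimator's bin boundaries collapse for near-silent units;
  those unit × time cells are excluded rather than imputed.
* The decomposition's b₁/b₂ split is attenuated by template noise; it
  recovers planted weights exactly only when templates are noise-free.
* The value-difference split can fail (raising, with the achieved gap)
  when one side is empty or chosen-value distributions barely overlap.
* No support for units recorded in different sessions with partially
  overlapping trial sets; the population analyses assume a common trial
  basis (as the simulator provides).
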