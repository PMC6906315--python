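# Methods

This note documents the models implemented in `enscode`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests
do and do not establish.

## Orientation geometry

Orientations live on a 180°-periodic circle and are wrapped to [−90°, 90°).
All circular statistics (mean, SD, median) operate on doubled angles.  The
channel basis is R(Δ) = cos⁷ Δ evaluated on *wrapped* center offsets, which
on the orientation circle equals |cos Δ|⁷.  This wrap matters numerically:
a literal 360°-periodic cos⁷ contains only four odd harmonics and makes the
8 × 8 channel design rank-4 (C₁C₁ᵀ singular), whereas |cos Δ|⁷ has a full
even-harmonic spectrum and the design is well conditioned.  Channel centers
sit at the eight stimulus orientations (−78.75° … 78.75°, 22.5° apart), so
the peak of each trial's channel profile coincides exactly with its
stimulus; the −90° … 67.5° grid is the *aligned offset axis* of the
reconstructed profile.

## Inverted encoding model

Training solves Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹ on per-fold, per-orientation averaged
observations; testing inverts Ĉ₂ = (ŴᵀŴ)⁻¹ŴᵀB₂.  Cross-validation uses 3
folds × 100 iterations by default; each iteration repartitions trials at
random with per-orientation counts equalized (surplus trials discarded
uniformly at random under the iteration's RNG substream, derived as
SeedSequence(seed, iteration) so runs are reproducible and
parallelizable).  Reconstructed profiles are baseline-corrected (channel
mean removed), circularly shifted so each observation's own channel sits at
offset 0, averaged, and regressed on the sign-folded axis
(−90, −67.5, −67.5, −45, −45, −22.5, −22.5, 0)°.  The slope ("orientation
sensitivity") is computed as a fixed linear functional of the profile,
which makes the per-trial and averaged-test paths exactly interchangeable:
decoding a pooled trial set equals the trial-count-weighted mixture of
decoding its subsets.

Numerical choices: the cross-validated drivers invert Ŵ through an SVD
pseudoinverse so that identically zero training data (noiseless pre-onset
samples) reconstructs zeros instead of failing; the standalone
`estimate_weights` / `invert_to_ctf` operations keep strict rank checks
(relative tolerance 1e−10) and raise on deficient designs, naming the
unexcited channels.

Cross-condition (SO→VO) decoding trains on SO folds only and tests every VO
trial each fold, labelled by the *mean* orientation of the display.  Test
trials are averaged per mean-orientation bin by default, mirroring the
within-condition averaging; a per-trial path exists because the
median-split analysis necessarily operates on trial subsets with unequal
orientation counts.  Whether the original analysis averaged VO test trials
before inversion is not determinable from the procedure description; both
paths are provided and the default is the averaged one.

## Temporal generalization and the stable/dynamic index

A TG matrix holds the sensitivity for weights trained at t₁ and tested at
t₂; partitions are shared across the matrix so its diagonal reproduces the
per-timepoint result under the same seed.  Off-diagonal cells are
classified at the group level by three one-sided hypotheses — below the
train-time diagonal (H1), below the test-time diagonal (H2), above zero
(H3) — with dynamic = H1 ∧ H2 and stable = ¬H1 ∧ ¬H2 ∧ H3; the classes are
disjoint by construction.  Cell tests default to one-sided paired /
one-sample t-tests at α = 0.05, uncorrected; a sign-flip randomization
alternative (statistic: the group t, which under sign flips is a monotone
function of the flipped mean because the sum of squares is invariant) is
exposed with the add-one p-value rule.  The published procedure says the
cell tests used permutation tests without specifying the scheme; sign
flipping across subjects is this package's concrete choice, and the two
methods move the index by well under 0.01 on emulated group data.

The stable (dynamic) index at time t is the proportion of stable (dynamic)
cells within a 310 ms square window centered on (t, t), excluding cells
within ±50 ms of the diagonal (inclusive) — the guard absorbs the temporal
smearing of the 100 ms moving-average filter.  Windows truncate at epoch
boundaries and the denominator adapts; at 100 Hz an interior window holds
31² − 311 = 650 eligible cells.  If truncation leaves no eligible cells
the index is undefined (NaN).

## Preprocessing

Smoothing is a centered 51-sample boxcar with *truncated* windows at the
epoch edges (no padding — fabricating data at the edges seemed worse than
a mild variance increase there; published edge behavior is unstated).
Decimation to 100 Hz keeps sample 0 and every fifth sample; no additional
anti-alias filter is applied beyond the boxcar.  ROI subsets ship as a
packaged JSON.  The source electrode lists contain two apparent typos which
the JSON resolves: a duplicated "F7" in one 14-electrode frontocentral list
(read as F7 + F8, matching that montage) and "Poz" (read as POz).

## Synthetic data generator

Each electrode is a weighted sum of the eight channel responses plus
i.i.d. Gaussian noise (an AR(1) knob exists, default off).  True weights
are i.i.d. standard normal; at least 8 electrodes are required.  Tuned
signal begins at stimulus onset; earlier samples are noise only.  Regimes:
*stable* holds W fixed; *dynamic* redraws W independently every 100 ms
(default) after onset, which produces the diagonal-dominant TG structure
characteristic of dynamic coding; *mixed* averages a stable and a dynamic
component with equal variance.  A subject's SO and VO epochs share the same
weights so the SO-trained decoder can generalize.

VO displays drive the channels with λ·basis(mean) + (1−λ)·mean of the four
item-offset basis vectors.  λ ∈ [0, 1] (default 0.5) is this package's
construct for testing cross-condition generalization — no generative model
for ensemble-display signals is implied by the source analysis — and the
cross-condition slope is linear in λ, which the λ-sweep property test
exploits.  Trial counts, epoch windows (−200…1600 ms and −200…1000 ms at
500 Hz), item offsets (±10°, ±30° and ±7.5°, ±22.5°) and probe designs
follow the two task protocols; `SimConfig.for_experiment` loads them.

Behavioral generators: old/new responses come from a blended-memory
observer — memory = (1−w)·item + w·mean + von Mises noise (concentration κ
on the doubled circle, default 8 ≈ 12° SD in orientation units, a typical
estimation-noise level for oriented bars), "old" iff the probe falls
within a 20° criterion (half the spacing between neighboring "new" probe
offsets).  Estimation responses are target + w·(mean − target) + noise, so
the expected signed error is −w · target-offset and the recoverable
tendency is w × 15° in the estimation task.  Default w = 0.3 gives biases
of a few degrees, the order observed in mean-ward bias experiments.

What the generator does *not* emulate: volume conduction and realistic EEG
spectra, temporal autocorrelation (by default), eye movements and
artifacts, display geometry.  Passing tests therefore establish the
correctness and statistical calibration of the *analysis* under its own
assumptions, not decodability of real recordings.

## Behavioral models

The old/new psychometric model is the cumulative Weibull
W(sim) = γ − (γ − δ)·e^−(sim/α)^β of the probe-to-mean similarity
sim(θ) = 1 − |θ|/(π/2); α is the similarity at which the curve reaches
1 − e⁻¹ ≈ 63.2% of its asymptote span.  Fitting minimizes the binomial
negative log-likelihood with L-BFGS-B over 30 random restarts (α, γ, δ
started uniform in (0,1); β in (0,10)).  The constant log-binomial terms
are dropped — reported NLLs differ from the full pmf by a data-dependent
constant that cannot move the argmin.  β's upper bound is 100 (a bounded
solver needs a finite bound; the curve is already saturated there).
γ ≥ δ is *not* enforced; inverted fits are flagged.  Degenerate tables
(all responses identical) drive γ and δ to a bound and set a boundary flag.

"Precision" in the estimation task is the reciprocal circular SD of the
response errors (deg⁻¹) — the source figure does not define its precision
measure, so this standard choice stands in and is documented as such.
The median split recodes errors so positive = toward the mean, splits at
the circular median (computed by rotating to the circular mean, taking the
ordinary median of residuals, and rotating back — deterministic and
order-invariant), labels ties "mean", and refuses degenerate (< 4 trials
or all-identical) inputs.

## Group inference

The permutation null shuffles orientation labels within subject (jointly
across conditions when both are given), refits the IEM — with a reduced
iteration count (default 10) as a fidelity/runtime knob — and recomputes
the one-sample group t; one-tailed p-values use the add-one rule, which
keeps them in (0, 1] and makes the test exact.  Null distributions are
kept per time point.  Bootstrap SEs are the SD of 10,000 participant-
resampled means.  Brain–behavior association is the OLS R² (with
regression p) of window-averaged TG sensitivity (200–1000 ms × 200–1000 ms
by default) against the behavioral ensemble tendency, plus a Spearman ρ
for robustness.

## Problem sizes

Tests and the acceptance script run the full pipeline at desk scale —
typically 8–20 synthetic subjects, 48–96 trials per condition, 12–16
electrodes, 100 Hz grids over 0.3–1.2 s epochs, 3–10 CV iterations, and
150–2000 permutations/sign-flips — sizes chosen so the complete suite
finishes in minutes while keeping every statistical property measurable.
The type-I-error study uses 200 datasets × 200 permutations (8 subjects ×
96 pure-noise trials each) in the acceptance script and a 100 × 150
version in the test suite, both compared against the nominal level with
binomial Monte-Carlo tolerance.

## Known limitations

- The IEM reconstructs modeled channel responses; tuning *width* is not
  interpretable, which is why the slope (amplitude-and-width compound) is
  the only summary statistic.
- The cos⁷ design has small trailing eigenvalues, so individual weight
  estimates are high-variance even though predictions and slopes are
  stable; tests of Ŵ unbiasedness scale tolerances by the design
  covariance.
- No multiple-comparison correction anywhere (deliberate, matching the
  uncorrected one-tailed analysis stance); index time courses are
  descriptive.
- The all-cells permutation TG null is expensive; the permutation test is
  typically run at selected time points.
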