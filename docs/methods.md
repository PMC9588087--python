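# Methods

This note documents the models, defaults, and design choices behind
`attnsal`. It covers what the synthetic data emulate (and what they do
not), the exact conventions of each analysis stage, and the numerical
decisions that affect results.

## Task model

A trial runs on a fixed event clock (seconds from trial start): fixation at
0, saccade target at 0.5, frame cue at 1.0, stimulus pair at 1.2, cue offset
at 1.4. The luminance change follows stimulus onset at latency
`offset + X`, `X ~ Exponential(tau)` truncated to `[0, cutoff]`, which
flattens temporal expectation. Defaults: tau 2.5 s / cutoff 1.4 s for the
single-change paradigm (D); tau 2.5 s / cutoff 1.9 s (target) and
tau 1.25 s / cutoff 1.9 s (distractor) for the go/no-go paradigm (G);
offset 0.4 s throughout. Sampling is by inverse CDF, so the support is
exactly `[offset, offset + cutoff]`.

Trial composition: frame side exactly counterbalanced (n/2 left for even n),
stimulus values drawn independently and uniformly from the five reward
levels {~0, 1, 2, 4, 8 standard drops} (the "~0" small drop codes as 0 in
all regressors), trial types drawn i.i.d. at 90/10 (D) or 80/10/10 (G), and
a configurable single-stimulus fraction (defaults 7.1% / 10.1%). The
delivered reward is drawn uniformly between the two stimuli, so neither
the cue nor salience predicts the outcome. In distractor+target trials the
target latency is redrawn until it exceeds the distractor latency; no joint
distribution is imposed beyond that ordering.

Derived variables are pure functions of the stored trial: CV/UCV (value at
the cued side — opposite the frame — and the other side), SV/NSV
(max/min of the two values), their differences, total value, and the cue
location code (−1 left / +1 right). When the two values are equal,
SV = NSV = CV = UCV and the trial has no salient side; such ties are
excluded from salience-conditioned behavioral cells and from SV-based trial
groupings, but enter every regression.

## Behavioral simulation and scoring

Outcomes are Bernoulli draws per (trial type × change-at-salient) cell;
reaction times are normal, truncated to the legal response window
(0.1–0.4 s after the change). Default cell probabilities and RT means mimic
a well-trained subject (valid ≈ 94%, invalid ≈ 90% hits; target ≈ 92–94%,
correct rejections ≈ 81%), with the salience split chosen to average to the
published-style marginals with a small salience advantage. These are
generator settings, not analysis inputs: every rate the package reports is
re-measured from the scored trials.

Scoring is recomputed from response timing, independently of the
generator's draw, and the two must agree (tested): a saccade within the
window after a target change is a hit; within the window after a distractor
change a false alarm — with precedence, so a response that falls inside the
distractor's window counts as a false alarm even if the target change had
already occurred; holding fixation through a distractor-only trial is a
correct rejection; responses before any change are "breaks" and excluded
from all denominators. A false alarm ends the trial, and a target change
that would have occurred later is marked as never shown.

The across-session test is a two-tailed Wilcoxon signed-rank: zero
differences dropped, mid-ranks for ties, exact p by dynamic-programming
enumeration of all 2^n sign assignments for n ≤ 15, tie-corrected normal
approximation (variance Σr²/4, no continuity correction) above. The exact
p-values are valid but discrete, hence slightly conservative at small n.

## Neuron model

Each unit's instantaneous rate is

    lambda(t) = max(0, baseline + sum_c coeff_c * k_c(t) * x_c(trial)),

with difference-of-exponentials kernels `k_c` (unit peak) anchored to trial
events, and `x_c` the signed cue location or a z-scored reward level
(standardized against the uniform distribution over the five levels).
Components and default kernels:

- `cue_side_pre` — cue onset + 40 ms, rise 20 ms, decay 150 ms: bottom-up
  capture by the frame, fading after stimulus onset;
- `cue_side_post` — stimulus onset + 150 ms, rise 50 ms, decay 8 s
  (effectively sustained): the top-down attention side after the shift.
  Opposite signs of the pre/post coefficients reproduce the attention-flip
  geometry;
- `frame_transient` — cue onset + 40 ms, decay 60 ms: a brief frame-side
  visual transient;
- `sv`, `nsv` — stimulus onset + 100 ms, sustained value signals.

Spikes are Poisson per 2-ms bin with uniform placement within the bin. The
linear-Gaussian rate models fitted downstream treat their noise term as
Gaussian; the generator uses Poisson counts because it must emit spike
trains, and rate-level Gaussianity is a good approximation at the default
rates (~8 Hz baseline, lognormal across units). For calibration tests that
need the fitted model to hold exactly, `gaussian_rate_table` bypasses the
spiking front end and returns noise-free or Gaussian-noise epoch rates.

Two shipped profiles set the coefficient distributions. *OFC-like*: 70% of
units carry an SV coefficient (gamma-distributed magnitude, 58% positive),
weak NSV and sustained-cue coefficients, frequent frame transients.
*DLPFC-like*: 90% carry cue-side coefficients with a pre/post sign flip
(post = −gain × pre, gain ~ U(0.6, 1.4)) and moderate SV coding. The paper
trail for these populations is qualitative (which signals dominate where),
not quantitative; all magnitudes are free configuration and the sampled
ground truth is stored with every synthetic session.

What the generator does **not** emulate: trial-to-trial rate correlations
between neurons (units are conditionally independent given the trial),
slow drifts and adaptation, error-trial dynamics of attention, eye-position
artifacts, and learning. Passing tests therefore demonstrate that the
analyses recover the encoding structure they target under Poisson noise at
realistic rates — not that real cortical data satisfy the generative
assumptions.

## Decoding pipeline

Spike counts are binned at 10 ms (half-open bins, label = center) in two
alignment windows: −400–600 ms around stimulus onset and −400–400 ms around
the luminance change. Each neuron is z-scored over all trials and all time
points of both windows jointly (zero-variance units are excluded with a
warning), then smoothed with a Gaussian kernel (sigma 50 ms) truncated to a
100 ms window and renormalized at the edges.

Pseudo-ensembles pair, per class, the m-th of 100 trials sampled without
replacement independently per neuron (M = 200 pseudo-trials); units need
100 trials in each cue condition. Features for each sliding 25-ms decode
window (10-ms steps; windows extending outside the binned range are
dropped) are window-averaged rates reduced by PCA to the smallest leading
subspace capturing ≥ 70% of variance — an independent subspace per window
for the time-resolved decoder, or one subspace fit on the (M·T)×N unfolding
(shared by all windows) for cross-temporal generalization.

The classifier is a two-class Gaussian discriminant with pooled covariance
and priors fixed at 0.5; performance is the posterior probability assigned
to the true cue side, so chance is 0.5 by construction and posteriors
reliably below the shuffle level indicate a sign-reversed code. Performance
is estimated by leave-one-out cross-validation, computed exactly via a
rank-one downdate of the pooled scatter (Sherman–Morrison), verified
against per-fold refits; the pooled scatter gets a trace-scaled ridge
(1e−6·tr(S)/P) only when its condition number exceeds 1e8 — PCA normally
prevents this. The whole procedure repeats over independently resampled
pseudo-ensembles (default 200; 20 in the heavier cross-temporal runs) and
reports the across-resample mean with SEM across pseudo-trials.

One deliberate choice: z-scoring and PCA are fit on the full pseudo-ensemble
while the discriminant is fit on training folds only. Both preprocessing
steps are unsupervised — they never see the labels — so they cannot leak
class information into the held-out fold, and fitting them once keeps the
resampling loop tractable; the discriminant, which does see labels, is
strictly fold-fit. The shuffle control runs the identical pipeline with
labels permuted within the ensemble, and significance is a per-bin
two-tailed paired t-test of true vs shuffled posteriors (pairs are
resample × pseudo-trial), Benjamini–Hochberg corrected across bins at
p < 0.01, with above- and below-null bins flagged separately. The RT-split
analysis halves each unit's trials at its median RT (median trial to the
slow half; a split with an empty half is rejected as degenerate) and
compares the two decoders bin-wise the same way.

## Encoding analyses

Epoch rates are spike counts over half-open windows divided by window
length: cue-stimulus 0–0.2 s and early-stimulus 0.2–0.6 s after stimulus
onset, late-stimulus the 0.4 s before the change (requires latency ≥ 0.4 s),
plus the variable-length stimulus period (onset→change), post-cue period
(cue offset→change), and the 200 ms pre-cue baseline window. All neural
analyses use double-stimulus hit trials: they are the correct trials with a
defined luminance change, which the variable-length windows require.

The selectivity screen regresses each epoch rate on each task variable
separately (two-sided t on the slope, selective at p < 0.005). A unit is
value-selective if any value variable is selective in any epoch; the signs
of its significant value slopes across variables and epochs classify it as
positively tuned, negatively tuned, or contradictory (mixed signs), and
contradictory units are excluded from tuned-group response averages.

The CPD models regress the trial rate on the cue-location code plus either
(SV, NSV) or (CV, UCV), all predictors z-scored on the analyzed trial
subset. CPD_i = (SSE_−i − SSE_all)/SSE_−i from nested OLS fits, which
guarantees 0 ≤ CPD < 1 and equals the squared partial correlation
(verified to 1e−10 against residual-on-residual fits). Time courses use
25-ms rates on both alignments; the per-neuron baseline is the
regressor-averaged CPD of the rate in the full 200-ms pre-cue window
(one window, not its individual bins — the simpler of the two readings of
the baseline definition; the bin-wise alternative is a parameter away).
Population significance per bin is a neuron-wise paired t against baseline
with BH-FDR at p < 0.005 across the bins of both alignments, and the same
machinery tests SV-vs-NSV (or CV-vs-UCV) contrasts. Epoch-level summaries
report per-neuron CPDs with per-coefficient regression t-tests (p < 0.05
uncorrected, matching scatter/histogram conventions; the threshold is a
parameter), the population paired t between value regressors, and the
per-neuron difference CPD(cue) − CPD(SV) against zero — negative means
salience dominates the unit's variance budget.

Grouped population responses average each unit's stimulus-period rate per
(group × value) cell — identical-value pairs, SV, CV, UCV groupings, and
the maximal-salience contrast (SV = 8, attention toward vs away) — then
average across units. The group-vs-value comparison is an additive two-way
ANOVA (no interaction term, matching the reported degrees-of-freedom
pattern) with type-II sums of squares, which coincide with the classical
balanced-design sums on balanced tables (tested against hand-computed
values) and remain well-defined on unbalanced ones.

## Numerical conventions

- Half-open windows everywhere; bin label = bin center; times in seconds
  relative to trial start.
- CSV bundles: UTF-8, comma, "NA" nulls, floats at %.17g (bit-exact
  round-trip; readers use round-trip float parsing).
- Degenerate inputs: zero-variance neurons excluded with a warning;
  constant predictors raise; all-zero rate bins yield CPD 0; identical
  paired vectors give a degenerate Wilcoxon (p = 1) and identical CPD
  columns a flagged paired t.
- Determinism: every stochastic operation takes a seed or Generator;
  identical seeds give identical schedules, spike trains, ensembles, and
  CSV bytes.

## Problem sizes

Default analysis runs in the test-suite and the acceptance script use
600-trial sessions with 100–150 units, 20 pseudo-ensemble resamples for
decoding, 500 random designs for the CPD oracle, and 10^6 draws for the
latency sampler — sizes at which the qualitative contrasts of interest
(salience dominance, the attention flip, null calibration) are decisively
resolved on a single core.

## Known limitations

- The pseudo-population treats serially recorded units as simultaneous;
  noise correlations, if present in real data, would change decoding
  performance in ways the generator cannot probe.
- The per-bin PCA dimension varies across bins and resamples; posterior
  time courses are comparable across bins only through the shared variance
  threshold, which is why cross-temporal analyses use the joint subspace.
- Leave-one-out posteriors under the null have a small pessimistic bias
  (the held-out trial pulls its class mean away from itself); at M = 200
  and the default variance threshold it is well inside ±0.02 of chance,
  and the shuffle comparison cancels it, but very high-dimensional
  subspaces at small M would inflate it.
- Exact Wilcoxon p-values are discrete; uniformity under the null holds
  only up to that discreteness.
- The behavioral generator draws outcomes independently across trials; it
  has no sequential effects, lapses, or motivation drifts.
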