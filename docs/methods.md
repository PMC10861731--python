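# Methods

This note documents the models, estimators, numerical choices and known
limitations of `megspect`, in the order the pipeline runs.

## Signal conditioning

Inputs are region × time matrices assumed artifact-free (dual-signal
subspace projection, ICA rejection and source reconstruction are upstream,
out of scope). Filtering uses Hamming-window FIR designs with a default
transition width of 1 Hz, giving an order of ≈ 3.3·fs (1,651 taps at
fs = 500 Hz). Filters are applied zero-phase as two same-direction passes
of the symmetric kernel via overlap-add convolution with reflect padding —
numerically equivalent to forward–backward filtering for a linear-phase
FIR and much faster at this order. The effective magnitude response is the
square of the single-pass design; spectral analysis downstream is
phase-insensitive, and `edge_samples` on the result marks the boundary
samples still influenced by the padding (one kernel length per side).
Epoching takes non-overlapping 5-s segments in temporal order and discards
the trailing remainder.

## Spectral estimation and parameters

The Blackman–Tukey estimator computes the biased sample autocorrelation
(via FFT), truncates it at a maximum lag of 1 s, tapers it with a Bartlett
lag window, and Fourier transforms the symmetric sequence. The Bartlett
window makes the estimate nonnegative by construction (its transform is
the Fejér kernel), which matters because PSDn is subsequently treated as a
probability distribution; a Hamming lag window is available, with negative
excursions clipped to zero before normalization. Default frequency spacing
is fs/(2·max-lag samples) = 0.5 Hz at fs = 500; `nfft` can refine it. The
estimator's frequency resolution (main-lobe width ≈ 2 Hz at a 1-s lag)
smooths sharp peaks; the synthetic fidelity check bounds the consequence
(mean |relative error| of PSDn ≈ 3% at 300 s, comfortably under the 10%
tolerance the generator targets).

**Bands.** The conventional printed edges (delta 1–3, theta 4–7, alpha1
7–9, alpha2 9–11, alpha3 11–13, beta 13–25, low gamma 26–40, high gamma
41–70 Hz) leave gaps at 3–4, 25–26 and 40–41 Hz and repeat shared
endpoints. The package's default is the contiguous half-open partition
[1,4), [4,7), [7,9), [9,11), [11,13), [13,26), [26,41), [41,70], which
preserves ΣRP = 1 exactly and avoids double counting; the literal printed
edges are available as `PRINTED_BANDS` for comparison.

**MF / IAF.** Both are median frequencies of PSDn (IAF after restriction
to 4–15 Hz and renormalization — renormalizing does not move the split
point). Sub-bin resolution treats each bin's mass as uniform over its own
width: this returns the exact bin centre for a point-mass spectrum and the
exact centre of any symmetric spectrum, whereas interpolating between
cumulative nodes does neither. Results are clipped to the grid range.

**SSE.** Natural logarithm with 0·log 0 := 0; the 1/log N normalization
makes the base immaterial. A flat spectrum gives 1, a single line 0.

**Order of operations.** Parameters are computed per epoch and then
averaged arithmetically across epochs per region (not computed on an
epoch-averaged PSD); global values are unweighted means across regions.

## eZIS metrics

Z = (control mean − individual)/control SD per voxel, requiring strictly
positive control SDs inside the brain mask. *Severity* averages **all**
VOI voxels (positive and negative Z alike; whether only positive voxels
should enter is unspecified in the field's descriptions — the all-voxel
mean is the simpler, linear choice). *Extent* uses the strict inequality
Z > 2. A whole-brain extent of zero makes *ratio* undefined; it is
reported as missing (NaN), never as zero. The VOI is a single boolean
mask even when spatially discontinuous.

## Global bootstrap

Spearman's ρ is the Pearson correlation of average ranks (ties get average
ranks; missing pairs are dropped listwise, adjusting N). The bootstrap
resamples subject pairs with replacement (default 5,000 draws), reports
the percentile 2.5/97.5 interval, the plug-in ρ and the across-iteration
mean ρ (figures in this literature print the latter; both are emitted).
Degenerate resamples (a constant vector, possible with heavily tied
scores) are redrawn. Percentile rather than BCa intervals: the method this
mirrors specifies only a "95% bootstrap confidence interval". Calibration
under independence is checked by simulation (≈5% false-positive rate at
n = 50).

## Cluster-based permutation test

Per region, T = ρ√(N−2)/√(1−ρ²). The covariate is shuffled across
subjects (default 5,000 times); the **cluster-forming threshold is
empirical** — each region's own permutation-distribution 0.025/0.975
quantiles — rather than a parametric t quantile, and the same permutation
draws serve both thresholding and the null. Supra-threshold regions are
grouped into connected components of the adjacency graph separately for
the positive and negative tails; each observed cluster's summed T is
referred to the permutation distribution of the per-iteration maximal
(positive) or minimal (negative) cluster sum, with iterations yielding no
cluster contributing 0 (this keeps the null sample size at n_perm).
p-values use the ≥ / ≤ convention including ties, without adding the
observed statistic to the null (no +1 correction); positive and negative
clusters are each tested at 0.025. No correction is applied across the
(parameter × covariate) family of tests — the battery is exploratory by
design. Type-I behaviour is verified by simulation: across 200 null
cohorts the any-significant-cluster rate sits inside the 99% binomial band
around the nominal 0.05.

Rank-based ingredients make every result invariant to strictly monotone
transforms of the covariate, and region relabelling permutes cluster
membership without changing sums or p-values (both properties are tested).

## PLS/VIP confound screen

For covariates that correlate with age (ratio, MMSE, FAB), each cluster
member's parameter is regressed on the standardized pair [covariate, age]
with a one-component PLS model. With one component and two predictors the
weight vector is w ∝ X'y (oriented so the component covaries positively
with the response; VIP is sign-invariant) and VIP_j = √2·|w_j|/‖w‖, so
VIP₁² + VIP₂² = 2 identically — a useful internal check. Members with
VIP(age) > VIP(covariate) are pruned; cluster mean ρ / mean T / sum T are
recomputed over survivors, empty clusters are dropped, and p-values are
**not** recomputed (the screen is post hoc).

## Synthetic cohort

The generator is the package's verification instrument: it produces data
with the statistical structure the analysis assumes, plus the ground truth
needed to score recovery.

- **Spectra.** Target PSD per subject and region = aperiodic floor
  `offset/f^exponent` (offset 1.0 ± 0.15, exponent 1.0 ± 0.1 across
  subjects) + Gaussian alpha peak (amplitude 0.4 ± 0.08, centre
  9.5 Hz, SD 1.5 Hz) + Gaussian theta bump at 5.5 Hz. A standard-normal
  latent impairment raises the theta amplitude (gain 0.08 per SD over a
  0.1 base) and slows the alpha centre (−0.5 Hz per SD). Per-region
  log-normal jitter (σ = 0.15) on peak amplitudes and ±0.2 Hz on the alpha
  centre provides within-subject regional variability. These values were
  fixed once, by design, to give global effect sizes in the range typical
  of memory-clinic cohorts (|ρ| ≈ 0.6–0.8 between cognitive scores and
  theta power / median frequency).
- **Covariates.** Linear-Gaussian in the latent, then clipped (and rounded
  for the integer instruments) to their ranges: MMSE 24 − 4·latent ± 2.5
  on 0–30, FAB 12 − 2.5·latent ± 1.8 on 0–18, severity/extent/ratio with
  positive loadings, age 77 + 2·latent ± 6.5. Intercepts and spreads sit
  near published memory-clinic descriptives.
- **Time series.** Inverse-FFT spectral shaping with i.i.d. uniform
  phases — a circularly stationary Gaussian surrogate whose empirical PSD
  converges to the target. Phase streams are keyed by (seed, subject,
  region), so any subject can be realized independently and bit-identically.
  Default fs = 500 Hz (every downstream operation is fs-agnostic) and
  300 s per subject.
- **Adjacency.** A 2-D lattice embedding of region indices (4-neighbour,
  connected) stands in for atlas neighbourhoods, which published VOI
  definitions leave unspecified; random-geometric graphs and file input
  are alternatives.
- **Z maps.** Gaussian voxel noise around a VOI mean that rises with the
  latent (base 1.3 + 0.5·latent, SD 1) over a milder whole-brain
  background.
- **Planted regional effects.** For power studies, a contiguous patch
  (breadth-first growth on the adjacency) receives a theta amplitude that
  is a strictly increasing transform of a Gaussian latent correlated with
  the covariate; the Gaussian rank-correlation identity r = 2·sin(πρ_s/6)
  sets the mixing weight so the *population* Spearman correlation is
  exactly the requested value (0.45 by default). Monotonicity guarantees
  the correlation survives the spectrum → RPt mapping unchanged.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: measurement and sensor noise,
artifacts, non-stationarity within a session, realistic spatial
correlation structure beyond the single latent factor (real atlases have
distance-dependent leakage correlations), non-Gaussian covariate
distributions, and diagnosis-specific spectral signatures. The
single-latent design also means planted global effects recruit essentially
all regions, so significant clusters in demo runs span the whole graph —
real cohorts yield partial clusters.

## Problem sizes and budgets

Simulation studies use sizes chosen to make their Monte-Carlo error small
relative to the bands they check: 200 null cohorts (n = 64, 103 regions,
500 permutations) for the type-I rate, 50 seeds for patch-detection power
and global sign recovery, 400 replicates for bootstrap calibration in the
test suite (200 in the acceptance script), 1,000 random spectra for the
algebraic identities. The statistical simulations evaluate parameters
analytically on the target spectra (the population PSD); the time-series →
estimator route is validated separately by the spectral-fidelity check.

## Degenerate inputs and tie-breaks

Constant vectors raise `ConstantInputError` (a rank correlation is
undefined); in the global battery such pairs are flagged and skipped
rather than fatal. All-zero spectra in 1–70 Hz raise
`DegenerateSpectrumError`; zero alpha-band mass raises
`DegenerateBandError`. |ρ| = 1 maps to a signed-infinite T with a warning.
Exclusion rules fire in a fixed order and each record is tallied once,
under the first rule that matches. All stochastic stages are deterministic
given (seed, n_boot/n_perm); the regional battery derives one sub-seed per
(parameter, covariate) pair from the run seed.
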