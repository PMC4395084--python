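# Methods

This note records the models, estimators, conventions and deliberate design
choices behind `mfwarn`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## Scaling model and estimator

A scale-free signal is characterized by power-law decay of multiresolution
quantities: `(1/n_j) Σ_k T(j,k)^q ~ 2^{j ζ(q)}` across dyadic scales
`2^j`. We use wavelet leaders as the multiresolution quantity: at octave j
and position k, `L(j,k)` is the supremum of |d(j′,k′)| over all dyadic
intervals at octaves j′ ≤ j contained in the three-interval neighborhood
`λ_{j,k-1} ∪ λ_{j,k} ∪ λ_{j,k+1}`. The supremum includes the scale's own
coefficients (j′ = j), the standard leader definition. Leaders, unlike raw
coefficients, yield valid structure functions for negative moments and are
the basis of the log-cumulant formalism: `ζ(q) = Σ_p c_p q^p / p!`, with

- `Ĉ1(j)` = sample mean of `ln L(j,·)`, `Ĉ2(j)` = unbiased sample variance,
- `c_p` = OLS slope of `Ĉp(j)` against `j ln 2` over octaves `[j1, j2]`.

Per scale, R bootstrap resamples of the leaders (i.i.d. within scale,
independent across scales) each produce a cumulant estimate; the reported
value is the mean of the R replicates and the replicate vectors are kept.
An identity-resample hook exists for testing (R = 1 without resampling
reproduces the plug-in estimate exactly).

### Conventions and numerical choices

- **Wavelet**: Daubechies with 3 vanishing moments (filters from
  PyWavelets); the dyadic cascade, boundary bookkeeping and leaders are
  implemented here, vectorized over a batch axis so thousands of short
  windows are analyzed in a few array operations.
- **L1 normalization**: raw cascade outputs are divided by `2^{j/2}`, so a
  self-similar signal with exponent H has `|d(j,·)| ~ 2^{jH}` and `c1` is
  directly comparable to H.
- **Boundaries**: coefficients whose filter support extends past the signal
  end are flagged invalid; no signal extension is applied. Validity
  propagates through the cascade, the leader recursion (a leader is valid
  only if its whole neighborhood at all finer octaves is valid), and every
  statistic. This protects the short 2-s analysis windows from edge
  contamination at the cost of a few leaders per octave.
- **Degenerate leaders**: a valid leader below `1e-14 ×` the window median
  invalidates negative-q structure functions for that window and is
  excluded from log statistics; any octave retaining fewer than 8 valid
  leaders invalidates the window's cumulant estimate (NaN, flagged).
- **Regression**: unweighted OLS across octaves by default; weighting by
  the per-scale leader count is available but off, as nothing in the
  method's definition prescribes weights. `ζ(0) = 0` holds exactly.
- **Defaults**: octaves 3–7 at 2 kHz sampling (≈ 11.7–187.5 Hz; the octave
  representative frequency is the dyadic band midpoint `3·fs/2^{j+2}`,
  which reproduces the printed 187.5 Hz upper edge exactly — the often
  quoted 11.8 Hz lower edge rounds our 11.72 Hz), q ∈ {−5,…,5} in integer
  steps, R = 100.

## Feature series

`(c1, c2)` are estimated on consecutive non-overlapping 2-s windows per
channel and averaged inside 1-min windows advanced by 15 s — the grid on
which classification, warnings and epochs all live (`floor((D−60)/15)+1`
windows for a D-second segment). Band powers (delta 0.5–3.9, theta 4–7.9,
alpha 8–14, beta 15–30, gamma 30–58, ripples 80–250, fast ripples 250–450
Hz) are Welch estimates (2-s Hann segments, 50% overlap) integrated over
each band on the same grid; they serve as a vigilance-state confounder
control, not as prediction features.

**Validity.** A 2-s window intersecting a recording gap is invalid. A 1-min
window is invalid if it intersects a gap at all — gaps are hard evidence of
missing data — or if more than half of its 2-s sub-windows are invalid for
estimation reasons; otherwise it averages the valid sub-windows. Bootstrap
seeds derive deterministically from (seed, channel), so a run is
reproducible given (data, config, seed).

## Discriminability analysis

Features are averaged inside 5-min epochs; each preictal epoch ends at a
seizure onset and each 5-min interictal epoch mean counts as one
observation (how many interictal epochs were pooled per observation is
genuinely ambiguous in the method's description; one-epoch-one-observation
is the simplest reading and is what the synthetic experiments assume).
Preictal and interictal epoch averages are compared per channel with a
two-tailed Wilcoxon rank-sum test — midranks for ties, normal approximation
with tie-corrected variance and 0.5 continuity correction, a good match to
exact enumeration down to group sizes of ~4 (checked in tests) —
Bonferroni-corrected over channels, with tiers at corrected p < 0.01 (+)
and < 0.001 (++) and the direction of the mean difference. The confounder
table reports, on each cumulant's most discriminating (largest |z|)
channel, the band-power tiers next to the cumulant tier.

## Classifier and warning protocol

Per channel, a linear discriminant (pooled covariance, equal priors, lsqr
solver with a tiny shrinkage for degenerate single-feature cases) is fit on
labeled 1-min windows. Channel score = mean over stratified 10-fold CV of
(sensitivity + specificity)/2; the phrase "10-fold leave-one-out" is read
as stratified 10-fold with every fold held out once (a literal
leave-one-out scheme is available), and the score formula — never stated in
the method's description — is balanced accuracy, the natural combination.
Fold assignment is deterministic (contiguous stratified blocks, no
shuffling): this keeps channel scoring exactly permutation-equivariant
across channel relabelings and reproducible; shuffled folds are available
by argument. The top three channels by score (ties broken by label) vote on
each test window; a window is preictal when strictly more than half of the
valid channel decisions say so, ties resolving to interictal to bias
against false warnings.

Five consecutive preictal 1-min windows on the 15-s grid — exactly 2 min of
continuously preictal signal — emit a detection at the closing window's end
time, and again at every step while the run persists. Invalid windows break
runs. Each detection extends an active warning to `detection + τ`;
overlapping periods merge and count as one warning. A warning whose active
period intersects a recording interruption longer than 3 min (beginning
before the period ends) is discarded; its span, and all >3-min gaps, are
excluded from assessed time (whether discarded spans should also shrink the
false-prediction-rate denominator is unstated in the protocol's
description; we exclude them from all time denominators for consistency).
τ bundles the seizure-occurrence period and the prediction horizon as one
lump.

## Evaluation statistics

With N test seizures, n of which have their onset inside an active warning
(half-open intervals; an onset exactly at a warning's end is unpredicted):

- sensitivity n/N; ρ = warning time / assessed time; warning rate =
  counted warnings / assessed hours;
- false-prediction rate (Mormann convention) = warnings containing no
  onset, divided by assessed hours − N·τ;
- chance predictor: a random warning set occupying fraction ρ of the span
  covers each onset with probability ρ, so its sensitivity is ρ; the
  improvement-over-chance p-value is `p = P(Binomial(N, ρ) ≥ n)` (evaluated
  through the regularized-incomplete-beta survival function, exact to
  1e-12; defined for n/N ≥ ρ, the one-sided domain), with ρ computed per τ
  from the evaluated timeline itself;
- Benjamini–Hochberg q-values `q_(i) = min_{j≥i} m p_(j)/j` across the
  comparison grid (per patient across the τ grid in the synthetic cohorts;
  the grid shape is configurable);
- all metrics are linearly interpolated at the critical rate 0.15/h
  (3.6 seizures/day ÷ 24), using the first bracketing τ pair in increasing
  order, with endpoint-plus-flag behavior when the curve never crosses it.

## Synthetic data: what it emulates, what it does not

`simulate_fbm` uses exact circulant embedding (Davies–Harte) of fractional
Gaussian noise — the sampler has the exact target covariance, so
parameter-recovery tests measure estimator error only. `simulate_mrw`
modulates fGn by `exp(ω)` with log-covariance `λ² ln(L/(lag+1))` up to an
integral scale L (default the series length), the canonical construction
with `c2 = −λ²`. Log-correlated embeddings can be slightly indefinite;
negative eigenvalues are clipped at zero.

`simulate_recording` builds multichannel patients from MRW-type segments:
interictal background with parameters (H, λ²) and, on affected channels,
preictal segments `[onset − preictal_duration, onset)` whose ground-truth
c1 is shifted — either through H (tilts the 1/f spectrum with it) or
through λ² (`c1 = H + λ²`; leaves the Gaussian factor's spectrum unchanged,
which is the mode used to demonstrate a cumulant difference invisible to
band powers). Segments are stitched with a 2-s linear crossfade of the
increments and normalized to unit increment variance per segment so regime
changes do not double as amplitude changes; gaps zero the signal and are
recorded. Defaults: 2 kHz, H = 0.6, λ² = 0.02, preictal 300 s, increment
scale 20 µV.

The generator emulates the *statistical* structure the method feeds on —
1/f spectra, stationary interictal scaling, preictal cumulant shifts,
annotations, interruptions — and nothing of EEG morphology: no spikes,
oscillatory bursts, sleep architecture, artifacts, or volume conduction.
Passing synthetic cohort tests therefore demonstrates that the chain
recovers injected scale-invariance differences above chance with correct
null behavior; it is not evidence about the magnitude or existence of such
differences in clinical recordings, and the injected shift size (+0.15) is
a test convenience, not a physiological claim.

## Problem sizes of the shipped experiments

Parameter-recovery checks run fBm/MRW at n = 2¹⁶ over 10 seeds (estimator
tolerances: |mean ĉ1 − H| < 0.05, |mean ĉ2| < 0.02 monofractal, ĉ2 within
0.03 of −λ²). The end-to-end cohorts run at a reduced size chosen to keep a
full cohort in minutes on one core: 500 Hz sampling with octaves 2–6 — the
processes are scale-free, so this is statistically equivalent to the 2-kHz
/ octaves-3–7 default at a quarter of the data volume — R = 10, a 30-min
training recording (two preictal + two interictal 5-min epochs), a
monofractal background, and test spans of 125 min (four seizures, power
cohorts) or 30 min (three seizures, null cohorts); τ grid {3, 5, 8, 10}
min, shorter than the default 5–60-min grid because warnings on a
two-hour span must stay well below full occupancy for the chance test to
resolve. Full-size defaults remain in `RunConfig`.

## Known limitations

- Cumulants stop at p = 2; the singularity spectrum D(h) and higher
  cumulants are out of scope, as are confidence-interval tests on c2 (the
  bootstrap is used for averaging only).
- The bootstrap is i.i.d. within scale; a time-block bootstrap (which the
  original toolbox may use) is not implemented.
- The state-similarity features of the companion method are not computed;
  feature sets FS4–FS6 accept externally supplied feature columns in their
  place.
- EDF output is 16-bit; round-trips are exact only to one quantization
  step of the per-channel physical range.
- The warning protocol is offline; streaming operation is out of scope.
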