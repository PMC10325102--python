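# Methods

## The analysis

Each couple contributes, per interaction context, two valence series
`y_a(t), y_b(t)` in [-1, +1] sampled at 1 Hz for 10 minutes, and one
binary outcome (separated within two years). The pipeline asks whether
the series predict the outcome, and which of three nested kinds of
information carries the signal: each person's mean level, each person's
variability, or the temporal coupling between the partners.

**Cross-power spectral density.** Coupling is operationalized in the
frequency domain: the one-sided cross-periodogram of the two series,
computed on a single full-length segment (boxcar window, constant
detrend, no zero padding, density scaling, interior bins doubled). For
T samples this yields `floor(T/2)+1` bins — 301 for T = 600 — spanning
0 to the Nyquist frequency, with no cross-segment averaging and hence no
loss of spectral resolution. Working with the full spectrum considers
all response lags between partners simultaneously instead of fixing one.
`scipy.signal.csd` supplies the estimator; the test suite pins its exact
convention (`P_ab = conj(X_a)·X_b`, Hermitian under argument swap,
Cauchy–Schwarz bounded, Parseval-consistent) against a direct-summation
DFT oracle.

**Features and classifier.** The classifier input per couple is
`[|P_ab| over all bins, mean_a, mean_b, var_a, var_b]` (variances use the
population denominator n). The magnitude of the complex CPSD is used:
magnitude is what the sub-band analysis interprets, and it makes the
feature invariant to which partner is called A. A phase-preserving
variant (real and imaginary parts concatenated) is available via
`include_phase`. The model is a random forest with pinned defaults —
100 trees, unlimited depth, square-root feature rule, bootstrap
resampling — because "library defaults" drift across versions. A
logistic baseline uses the five-number summary
`[mean_a, mean_b, var_a, var_b, lag-0 r]`.

**Single-segment magnitude factorizes.** One consequence worth stating
explicitly: with a single segment, `|P_ab(f)| = |X_a(f)|·|X_b(f)|`
exactly — the magnitude carries only the two *marginal* amplitude
spectra, not the cross-phase alignment. Coupling reaches the magnitude
features through the shape of each partner's own spectrum (two coupled
partners both carry the shared component's spectral signature), and
time permutation is detected because permutation whitens each partner's
spectrum, not because it breaks phase alignment. Cross-segment-averaged
estimators (Welch) would behave differently; they are deliberately out
of scope because they change the feature dimensionality.

**Surrogate attribution.** Six variants of the raw series feed the same
feature/evaluation machinery: `original`; `a` mean-centred per person;
`b` standardized per person (centering plus division by the standard
deviation — "standardized" is read conventionally; a literal
divide-by-variance is available behind `divide_by_variance`); `c` each
partner's series independently permuted in time; `a+c`; `b+c`.
Standardizing a zero-variance series yields zeros with a warning rather
than an error, so one flat rater cannot abort a cohort run. Performance
loss relative to `original` attributes predictive value to the removed
information. Permutations are redrawn inside every evaluation
repetition, so the repetition spread includes permutation variability.

**Evaluation.** Per repetition (default 50): draw a fresh stratified
k-fold partition (default k = 5 — with ~17 positives, k = 10 would
leave test folds without positives; stratification keeps positives in
every fold, since MCC is degenerate on single-class test sets), train
on k−1 folds, predict the held-out fold, pool all held-out predictions,
and compute one MCC (zero by convention when a confusion-matrix margin
vanishes; per-fold averaging available behind `per_fold_mcc`). The
repetition mean and its standard error `sd/sqrt(R)` summarize each
variant; two variants differ significantly when their mean ± SE
intervals are disjoint. Note the SE captures repetition variability
(splits, forest randomness, permutations) around *this cohort's*
performance, not sampling variability across cohorts; a fixed finite
cohort can carry small spurious feature–label associations that the SE
does not reflect.

**Coupling and variance reports.** Per couple, mean log10(|P_ab| + 1e-12)
within six 5-cpm sub-bands partitioning 0–30 cpm (cpm = 60·Hz; the last
band closes at the Nyquist rate so the partition covers all bins; the
DC bin sits in band 1, which is harmless because constant detrending
zeroes it and the raw means are separate features). Outcome groups are
compared with couple-level bootstrap resampling (default 1000
resamples): histograms pool the resampled per-couple values on shared
Freedman–Diaconis bin edges, and the group-mean difference gets a 95%
percentile interval from the bootstrap distribution of group means.
Individual emotion variance is related to the outcome by point-biserial
correlation (Pearson r against 0/1 labels; two-sided p from
`t = r·sqrt((n−2)/(1−r²))` on n−2 df), reported per partner role and
context.

## The synthetic cohort generator

The generator emulates the target design — 98 couples, 2 partners, 2
contexts, 600 samples at 1 Hz, separation prevalence 17/98 ≈ 17.3% —
with the statistical structure the analysis is designed to detect.
Per couple and context:

    y_i(t) = mu_i + sigma_i · ( sqrt(c)·s(t) + sqrt(1−c)·e_i(t) ),

hard-clipped to [-1, +1] (matching the bounded joystick scale; clipping
distortion is accepted and kept negligible by the default mean/amplitude
ranges). Both partners share `s(t)`; `e_i(t)` are independent AR(1)
streams (coefficient 0.85 — per-second affect ratings are strongly
persistent); every component is standardized to unit sample variance, so
the coupling `c` is the shared fraction of variance and the expected
lag-0 inter-partner correlation.

**Shared-component spectrum.** `s(t)` is a random-phase sum of
sinusoids at the series' Fourier frequencies whose amplitudes follow
the AR(1) noise spectrum *capped* above a knee (default 4 cpm), with
extra weight (default ×2) below 5 cpm, restricted to `shared_band`
(default 0.1–30 cpm). This shape is chosen deliberately. Because the
single-segment |CPSD| factorizes into marginal spectra, coupling is
visible to the analysis only through the spectral-shape contrast
between the shared and individual components; and because both
components have unit variance, no shape can dominate everywhere — a
narrowband shared signal (e.g. a small set of random tones) makes
weakly coupled couples show *higher* log-magnitude at the frequencies
the shared signal misses, reversing the group comparison in some
sub-bands. Capping the AR(1) shape reallocates shared power away from
the noise-dominated lowest frequencies, which puts the shared-to-noise
density ratio above one across essentially the whole 0–30 cpm range.
That yields the two regularities the pipeline should recover from a
coupled cohort: strongly coupled couples have higher expected
log|CPSD| in every sub-band, and a marginal-spectrum signature that
survives per-person standardization.

**Couplings and labels.** Couples are first assigned a latent
separation-prone group (probability = target prevalence); coupling is
drawn near the group target (`coupling_sep` = 0.1 vs `coupling_stay`
= 0.8 by default, jitter SD 0.03). The separation label is then a
Bernoulli draw from a logistic function of the coupling's normalized
position between the two targets (steepness 6 logits across the gap),
with the intercept calibrated by root finding so the cohort's expected
prevalence equals the target. Labels are therefore noisy — deterministic
labels would saturate MCC at 1 and make surrogate comparisons
uninformative; the defaults put the Bayes-optimal MCC near 0.87. When
the two coupling targets coincide the logistic score degenerates, and
the latent group indicator takes its place as the propensity; this
keeps mean-only or variance-only cohorts constructible (via
`mean_shift_sep`, a baseline shift, and `sd_scale_sep`, an amplitude
scale, applied to separation-prone couples) while leaving coupling and
label exactly unassociated.

Per-person baselines are drawn uniformly from `mean_range` (default
−0.2 to 0.6: interactions skew mildly positive) and amplitudes from
`sd_range` (default 0.1–0.35 valence units, keeping clipping rare).
One caveat the test suite exploits deliberately: time permutation
preserves each series' total power, so in a finite cohort with
heterogeneous amplitudes the permuted variants inherit whatever chance
correlation the amplitude draws have with the labels — a fixed offset
that the repetition SE cannot see. Cohorts built to demonstrate that
permutation leaves *nothing* behind therefore use a degenerate
`sd_range` (all couples share one amplitude).

**What the generator does not emulate.** Real valence series are
nonstationary (topic changes, regime switches), have rater-specific
response styles and quantization, and their coupling need not be
variance-preserving or stationary in frequency. Passing tests
demonstrate that the pipeline recovers planted structure of the kind
described above and stays at chance when there is none; they do not
certify effect sizes on real data. On real recordings the logistic
baseline would not be expected to rival the spectral model as it does
on synthetic cohorts, where the lag-0 correlation feature reads the
planted coupling directly.

## Numerical and design choices

- One master seed drives everything; per-stage seeds are the first four
  bytes of SHA-256 over `"<seed>:<stage label>"` (mod 2^31), so stages
  and variants can be re-run in isolation and reproduce exactly.
- Degenerate label draws (zero or all positives) are redrawn from the
  next substream, at most 10 times, then raise.
- CSV series round-trip uses `%.17g` and round-trip float parsing, so
  write→read preserves float64 values bit-exactly. Gaps of at most 2 s
  in an input series are forward-filled; longer gaps drop the
  couple-context with a logged reason (the spectral features require
  gapless series). Time is 0-based seconds; the pipeline assumes the
  input is already 1 Hz.
- The unpenalized logistic baseline falls back to a light ridge penalty
  if the fit fails outright (perfect separation); failures are logged.
- Frequency sub-bands assign bins half-open (`low ≤ 60f < high`) except
  that the final band includes its upper edge; for odd T the one-sided
  grid tops out half a step below Nyquist.
- Problem sizes in the test suite: the full-size attribution checks run
  98-couple cohorts at 50 repetitions for the coupling cohort and 20
  repetitions for the mean-only, variance-only and no-signal cohorts;
  unit and property tests use 20–40 couples and 64–300-sample series.
  `scripts/acceptance.py` runs the default 98-couple cohort, positive
  context, all six variants at 50 repetitions.

## Known limitations

- Magnitude-only features discard cross-phase information by design;
  enabling `include_phase` changes the feature dimensionality (2F + 4).
- With ~17 positives, per-fold positive counts are small even under
  stratification; MCC estimates for a single repetition are coarse, which
  is why only repetition means are interpreted.
- The SE-overlap significance rule is descriptive (a convention for
  comparing repetition distributions), not a calibrated hypothesis test
  across cohorts.
- The bootstrap group comparison resamples couples within group and so
  conditions on the observed group sizes (17 vs 81 by default); with
  very small groups the percentile interval is itself noisy.
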