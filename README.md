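# dyadsync

Analysis pipeline for **dyadic emotion dynamics and relationship
stability**: do the second-by-second emotions two partners experience
during a 10-minute conversation carry enough information to predict
whether the couple will separate within two years — and if so, is it the
*level* of emotion, its *variability*, or the *coupling* between the two
partners that carries the signal?

The package is aimed at affective scientists and methodologists working
with continuous dyadic self-report data (video-mediated recall, joystick
valence ratings in [-1, +1] at 1 Hz). It provides:

- **Spectral features.** For each couple and interaction context, the
  cross-power spectral density (CPSD) of the two valence series, computed
  as a single full-length cross-periodogram. Two partners whose emotions
  fluctuate at a shared rate *f* — at any lag — produce cross-spectral
  energy at *f*, so the CPSD operationalizes coupling without fixing a
  response time. A 600-sample series at 1 Hz yields 301 frequency bins
  (0 to 0.5 Hz); the classifier input is `[|P_ab(f_0)| … |P_ab(f_300)|,
  m_a, m_b, s²_a, s²_b]`.
- **Surrogate attribution.** Five information-removal variants of the raw
  series — mean-centred (a), standardized (b), time-randomized (c), and
  the combinations a+c and b+c. A performance drop relative to the
  original attributes predictive value to the removed information;
  time randomization destroys auto- and cross-correlation (the coupling)
  while preserving each person's value distribution.
- **Evaluation.** Repeated (default 50×) stratified k-fold
  cross-validation of a random forest (plus a logistic baseline on
  `[m_a, m_b, s²_a, s²_b, r_ab]`), scored with the Matthews correlation
  coefficient, MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
  which behaves like a Pearson correlation and is robust to the strong
  class imbalance (~17% separations). Variants are compared by
  non-overlap of mean ± SE intervals.
- **Coupling reports.** Per-couple mean log₁₀|CPSD| in six 5-cycles-per-
  minute sub-bands with bootstrapped group histograms
  (stayed vs separated), and point-biserial correlations between each
  person's emotion variance and the outcome.
- **A synthetic cohort generator** that emulates the study design (98
  couples × 2 partners × 2 contexts × 600 s = 235,200 samples, ~17.3%
  separation rate) with a tunable coupling difference between outcome
  groups, so the whole pipeline is testable without any data download.

## Worked example

```python
import numpy as np
import dyadsync as ds
from dyadsync.pipeline import variant_feature_source, stage_seed

config = ds.GeneratorConfig(n_couples=40, series_length=300,
                            contexts=("positive",), seed=11)
cohort = ds.generate_cohort(config)
labels = cohort.label_map()

dyads = cohort.dyads["positive"]
eval_config = ds.EvalConfig(repetitions=10)
for variant in ("original", "b", "c"):
    spec = ds.SurrogateSpec.from_variant_id(variant)
    source = variant_feature_source(dyads, labels, spec)
    rng = np.random.default_rng(stage_seed(7, f"eval:{variant}"))
    dist = ds.repeated_kfold_eval(source, eval_config, rng, variant, "positive")
    print(f"{variant:9s} MCC = {dist.mean_mcc:+.3f} (SE {dist.se_mcc:.3f})")
```

prints

```
original  MCC = +0.442 (SE 0.032)
b         MCC = +0.277 (SE 0.054)
c         MCC = -0.007 (SE 0.007)
```

The original features predict separation well above chance; removing
each person's mean and variance (`b`) weakens but does not destroy the
signal, because the spectral coupling signature survives
standardization; independently permuting each partner's series in time
(`c`) removes the coupling and performance collapses to chance — the
prediction rested on the temporal structure, not on who was generally
happier or more volatile. The same cohort shows the coupling direction
descriptively: couples who stay together have higher mean log₁₀|CPSD|
than separated couples in every sub-band (differences of 0.21–0.32
log units in this run).

The same analysis runs from the shell:

```bash
dyadsync simulate --seed 4 --out cohort/
dyadsync evaluate --series cohort/series.csv --labels cohort/labels.csv \
    --context positive --repetitions 50 --out performance.csv
dyadsync report --series cohort/series.csv --labels cohort/labels.csv \
    --out report_out/
dyadsync all --seed 4 --out full_run/          # everything + manifest
```

Real data are supplied as a long-format CSV (`couple_id, partner,
context, t, valence`) plus a label CSV (`couple_id, separated, excluded,
exclusion_reason`); see `dyadsync.read_dyads` / `read_labels`.

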