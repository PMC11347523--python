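# Methods

## Problem and data model

The pipeline quantifies how much information each regional morphometric
feature carries about MRI-estimated brain age. Its input is a
subject-level feature table: chronological age (years), sex, and one
column per (region, hemisphere, measure) triple. The default atlas
contract is 33 bilateral cortical regions × {GMV, WMV, CSF, CT} = 264
features (volumes in mm³, mean cortical thickness in mm). Region labels
are opaque strings; the shipped registry of 33 labels is a placeholder
set that includes the five regions the analysis treats as anchors
(pre-central gyrus, superior frontal gyrus, cingulate, insula, superior
temporal gyrus) and can be overridden from a YAML schema file. All
computations key on labels, never on column positions.

## Brain-age model

ε-insensitive support vector regression with an RBF kernel
(scikit-learn `SVR`). Features are z-scored per column and the age
target is standardized, both fitted on the training split only; raw
mm³ scales differ by five orders of magnitude between volumes and
thickness and are numerically pathological for an RBF kernel.
Constant features are dropped with a warning.

Hyperparameters: C is selected from {0.1, 1, 10, 100} by exhaustive
grid search under shuffled 10-fold cross-validation scored by negative
mean absolute error, then the model is refit on all training data with
the selected C. ε defaults to 0.1 on the standardized target (≈ 2
years for a typical adult-lifespan cohort) and the kernel width is
scikit-learn's `scale` default, 1/(n_features · var). Fold shuffling is
reproducible from the run seed; no age stratification is applied.

### Age-bias correction

Kernel regressors shrink extreme predictions toward the training mean,
so the young are over-predicted and the old under-predicted. The
correction fits ŷ ≈ α·age + β on training predictions by ordinary
least squares and adjusts every prediction by the residual of that
line:

    corrected_i = ŷ_i + [age_i − (α·age_i + β)]

Two properties follow algebraically and are enforced by tests: if
predictions sit exactly on the fitted line, correction returns
chronological age at machine precision; and on the fitting set the
OLS slope of (corrected − age) on age vanishes.

By default α and β are fitted on **out-of-fold** training predictions
(10-fold `cross_val_predict` with the selected C). In-sample refit
predictions overfit toward ŷ = age, dragging α toward 1 and weakening
the correction on held-out data; an `in_sample` mode is retained for
literal replication of pipelines that fit the line in-sample.

Note the correction consumes each subject's chronological age at
application time: "corrected brain age" is not a pure function of the
scan. This is the standard formulation; its partial circularity is a
property of the method, not of this implementation.

## KSG mutual information

Per-feature information about corrected brain age is estimated with
the first Kraskov–Stögbauer–Grassberger estimator:

    I(X, Y) = ψ(k) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩ + ψ(N)

For each point, the distance to its k-th neighbor in the joint space is
taken under the Chebyshev (max-coordinate) metric (`scipy.spatial.cKDTree`
with p=∞); n_x and n_y count marginal points **strictly** within that
distance, computed in O(N log N) with a sorted copy and `searchsorted`.
Numerical choices:

- **k = 3** by default (the estimator authors' bias/variance
  recommendation), exposed everywhere as `--k`.
- **Units: nats.** The digamma identity is natural-log native;
  `MIEstimate.in_bits()` divides by ln 2.
- **Tie-breaking jitter**: uniform noise of amplitude 1e−10 × sd is
  added before neighbor search, seeded from (seed, array content) so
  the same variable always receives the same jitter — this makes
  `ksg_mi(x, y)` and `ksg_mi(y, x)` exactly equal.
- **Boundary robustness**: the k-th joint neighbor lies at exactly the
  ball radius in one coordinate, so its strict exclusion would
  otherwise be decided by float rounding; the marginal radius is
  shrunk by a relative 1e−12 before counting, making counts invariant
  to subject order and to the jitter realization.
- **Clipping**: the estimator is unbiased around zero and can go
  negative for weakly dependent data; reported values are clipped at 0
  and the raw value is retained alongside.

A plug-in discrete MI (`H(x) + H(y) − H(x, y)` by direct entropy
summation over a joint probability table) serves as an exact
small-instance oracle; the test suite checks the KSG estimator against
it and against the bivariate-Gaussian closed form −½·ln(1−ρ²), and
cross-checks one estimate against scikit-learn's independent
nearest-neighbor MI implementation.

### Aggregation

Hemisphere merging, regional measure combinations (parenchyma =
GMV+WMV, intracranial = GMV+WMV+CSF) and per-measure totals are all
**sums of per-feature MI values**, so conservation identities hold
exactly and are asserted in tests. An alternative reading — MI of the
summed volumes rather than the summed MI — is available as
`combine_volumes=True`; summation of MI is the primary mode because it
is the arithmetic consistent with per-measure totals over 33 regions
whose individual values peak well below one nat. Rankings sort
descending with ties broken by region label; tertile grouping
(highest/middle/lowest thirds, 11 regions each) is defined for the
33-region atlas and omitted for sub-schemas.

Sums of clipped estimates are upward-biased for near-independent
features (each term is ≥ 0); totals should be read as decoding scores,
not as calibrated joint information.

## Sex-subgroup comparison

The test cohort is partitioned by sex; per-subgroup metrics
(before/after correction) and MI profiles are recomputed with the
**training-set** bias coefficients deliberately reused — subgroup
analyses probe the single trained model, they do not refit it. Region
rankings are compared male-vs-female, male-vs-all and female-vs-all by
Spearman correlation (average ranks on ties, two-sided t-approximation
p, 0.05 level), per measure, per combination, and on the all-measure
merged region profile. A constant profile (every estimate clipped to
zero, possible in tiny cohorts) has no ranking; the comparison reports
NaN rather than a coefficient.

## Synthetic cohort generator

Each feature follows

    value = baseline + slope·age + quad·age² + sex_offset·[male] + N(0, sd)

truncated below at 1% of baseline to preserve positivity, with ages
uniform on [18, 88] and a 50/50 sex ratio. The default aging preset
emulates the qualitative structure of cross-sectional aging cohorts:

- **GMV** (baseline 12000 mm³, sd 900): linear decline; the most
  sensitive region loses 4.5 sd over the age span (≈ a −0.65
  feature–age correlation, consistent with the stronger regional
  associations reported in aging morphometry).
- **CSF** (2500 mm³, sd 350): linear increase, up to 3.4 sd.
- **CT** (2.6 mm, sd 0.13): linear thinning, up to 2.8 sd.
- **WMV** (9000 mm³, sd 500): weakly non-monotone inverted-U peaking
  at 75 years, range up to 2.8 sd — white matter rises through midlife
  before declining, and carries the least age information of the four
  measures.
- **Sex**: +8% on volume baselines for males, nothing on thickness.
- **Noise**: independent Gaussian per feature. An optional shared
  log-normal head-size factor on volumes exists but is off by default;
  independence keeps the planted truth interpretable.

The planted **truth** is each feature's standardized effect size — the
range of its deterministic trajectory over the age span divided by its
noise sd (computed numerically on an age grid, so it is well defined
for the non-monotone WMV) — and the per-measure region rankings it
implies.

Region sensitivity is structured, not i.i.d.: the five anchor regions
are pinned at the top of the measures they exemplify (GMV:
pre-central gyrus; CSF: cingulate; CT: superior temporal gyrus; WMV:
insula; the superior frontal gyrus is planted second in both GMV and
WMV so that it tops the parenchyma combination, and the cingulate's
high CSF plus high GMV make it top intracranial volume). All other
regions share one seed-shuffled sensitivity order across measures —
mirroring the empirical pattern that a region aging quickly in one
measure tends to age quickly in the others — with effect sizes
linearly spaced from 0.75 × the measure maximum down to the measure
minimum. The anchor margins (rank-2 at 0.85–0.93 of the maximum,
rest from 0.75) were chosen so that each planted top exceeds its
runner-up by several times the KSG sampling noise at the design cohort
scale (≈ 600 subjects), i.e. the planted structure is recoverable by
construction, not by luck.

**What the generator does not emulate**: inter-feature noise
covariance, non-uniform age distributions, site/scanner effects,
measurement-error heteroscedasticity, and any true nonlinearity of the
feature–age relationship beyond a quadratic. Passing recovery tests
therefore demonstrate that the pipeline correctly decodes planted
monotone-plus-noise structure at realistic scale — not that it would
rank real cortical regions identically.

## Problem sizes and determinism

The design scale is 600 training / 550 testing subjects (the scale the
cohorts this pipeline targets typically have); unit tests use smaller
cohorts (60–300 subjects) and sub-schemas where the property under
test allows it. One master seed expands through `SeedSequence` into
independent stage seeds (simulation, fold shuffling, jitter); the full
train/predict/correct/decode path is bit-reproducible from (data,
config, seed), and re-running a pipeline config reproduces every JSON
artifact byte for byte.

## Known limitations

- MI values depend on k and on n; cross-study numeric comparison of MI
  magnitudes is not meaningful without matching both.
- MI against *predicted* age is inflated for features the model itself
  leans on (their measurement noise enters the prediction); decoding
  scores mix "informative about age" with "used by the model". This is
  inherent to decoding a model output.
- The bias-corrected target requires chronological age at test time
  (see above).
- Tertile grouping presumes the 33-region atlas; other parcellations
  get rankings and top-k lists but no tertiles.
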