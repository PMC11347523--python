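# brainage-mi

Decode which regional morphometric features carry information about
MRI-estimated brain age.

Brain-age models compress a structural MRI scan into a single number — the
age a regression model assigns to the brain — but the number alone says
nothing about *which* anatomy drives it. `brainage-mi` implements a
transparent decoding pipeline for regional morphometry tables (gray matter
volume, white matter volume, CSF volume and cortical thickness for 33
bilateral cortical regions, 264 features per subject):

1. **Brain-age model** — ε-insensitive support vector regression with an
   RBF kernel on z-scored features; the regularization constant C is chosen
   by exhaustive grid search under 10-fold cross-validation scored by
   negative mean absolute error, and the final model is refit on the full
   training set.
2. **Age-bias correction** — regression models over-predict the young and
   under-predict the old. With (α, β) from the training-set fit
   ŷ ≈ α·age + β, each prediction is corrected as

   corrected_i = ŷ_i + [age_i − (α·age_i + β)]

3. **MI decoding** — every input feature x is scored by its Kraskov (KSG)
   k-nearest-neighbor mutual information with the corrected brain age ŷ_c:

   I(X, Y) = ψ(k) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩ + ψ(N)

   with ψ the digamma function, joint neighborhoods under the Chebyshev
   norm and strict marginal counts (values in nats). MI is symmetric,
   non-negative and invariant under monotone transforms, so it ranks
   features without assuming any functional form.
4. **Aggregation** — left/right MI values are summed per region; regional
   combinations (parenchyma = GMV+WMV, intracranial = GMV+WMV+CSF) and
   per-measure totals are sums of those; each 33-region ranking is split
   into tertiles of 11 and a top-10 list.
5. **Sex subgroups** — the test cohort is split by sex, metrics and MI
   profiles are recomputed per subgroup, and region rankings are compared
   with Spearman correlation at the 0.05 level.

Real brain-age cohorts of this kind sit behind managed access, so the
package ships a synthetic-cohort generator with *planted*, exactly known
regional age-sensitivity (declining GMV/CT, rising CSF, weakly non-monotone
WMV, a male offset on volumes, Gaussian measurement noise). Every
downstream claim is therefore testable as a recovery problem: the MI
ranking must reproduce the planted effect-size ranking.

## Worked example

```bash
brainage-mi run --config demo.yaml
```

simulates a 600-subject training and 550-subject testing cohort, trains the
model, and writes all artifacts plus `run/summary.md`. With the shipped
config (master seed 20) the summary reads, in part:

```
- selected C: 1.0
- bias coefficients: alpha=0.915, beta=4.439 years

| set   | phase             | MAE (y) | RMSE (y) | R2    |
| train | before correction | 2.78    | 3.51     | 0.971 |
| train | after correction  | 2.44    | 3.05     | 0.978 |
| test  | before correction | 2.71    | 3.44     | 0.971 |
| test  | after correction  | 2.46    | 3.12     | 0.976 |

- GMV: 6.89   - CSF: 6.41   - WMV: 4.11   - CT: 3.82   (MI totals, nats)
```

Reading: the fitted bias slope α = 0.915 < 1 is the regression-dilution
signature, and applying the correction improves every accuracy metric on
both cohorts. The per-measure MI totals rank gray matter volume and CSF
volume as the most informative feature families; the top-10 tables in the
same summary show the planted anchor regions (e.g. pre-central gyrus for
GMV, cingulate for CSF) leading their measures.

Each stage is also runnable standalone — `simulate`, `train`, `predict`,
`decode-mi`, `subgroup`, `report` — on the files a prior stage wrote; see
`brainage-mi --help`.

## Library use

```python
from brainage_mi import (RegionSchema, default_aging_preset, simulate_cohort,
                         fit_brain_age_model, predict_age,
                         apply_bias_correction, mi_profile)

schema = RegionSchema()
preset = default_aging_preset(schema, seed=11)
train, truth = simulate_cohort(preset, schema, n=600, seed=101)
test, _ = simulate_cohort(preset, schema, n=550, seed=202)

model = fit_brain_age_model(train, schema, seed=5)
pred = predict_age(model, test)
corrected = apply_bias_correction(pred, test.ages, model.bias)
profile = mi_profile(test, corrected, schema, k=3, seed=9)
print(profile.measure_totals)         # nats, per measure
print(profile.ranked("GMV")[:3])      # top regions by gray-matter MI
```

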