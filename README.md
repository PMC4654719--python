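# thyrotex

Texture analysis of thyroid nodules on diffusion-weighted MRI: apparent
diffusion coefficient (ADC) mapping, a MaZda-style catalogue of 278
texture features, statistical feature selection, and a linear
discriminant classifier that separates benign from malignant nodules —
plus a synthetic cohort generator so the entire study can be run,
end to end, without patient data.

## The problem

Thyroid nodules are common and mostly benign; imaging-based
malignancy triage aims to reduce unnecessary biopsies.  On
diffusion-weighted MRI, malignant nodules tend to restrict water
diffusion (lower ADC) and to be texturally more heterogeneous than
benign ones.  This package implements a slice-based texture pipeline:

1. **ADC mapping.**  From a pair of diffusion-weighted images acquired
   at b-values 0 and b (s/mm²), the mono-exponential model
   `S(b) = S(0)·exp(−b·ADC)` gives `ADC = ln(S(0)/S(b)) / b`
   per pixel.  An optional quadrature noise-floor correction
   `S' = sqrt(max(S² − NF², 0))` counters Rician bias at low SNR;
   negative ADC estimates are clipped to zero and counted.  Per-nodule
   ADC is the area-weighted mean of per-slice region-of-interest (ROI)
   means, `Σᵢ wᵢ·x̄ᵢ / Σᵢ wᵢ` with `wᵢ` the ROI pixel areas.
2. **Texture features.**  Each slice ROI of the ADC map (or raw DWI) is
   quantized to `2^bits` gray levels and summarized by 278 features:
   gray-level co-occurrence statistics at 20 offsets, run-length
   statistics in 4 directions, histogram moments and percentiles,
   gradient-magnitude statistics, a causal autoregressive model, Haar
   wavelet subband energies at 3 scales, and moment-based ROI geometry.
   `docs/feature_registry.txt` (regenerable via `thyrotex registry`)
   lists every feature name with its formula.
3. **Feature selection.**  Features are ranked three ways — Fisher
   coefficient, mutual information, and a greedy probability-of-error +
   average-correlation (POE+ACC) criterion — the top 10 of each are
   pooled, and backward elimination over the pooled ranking picks the
   subset minimizing resubstitution LDA error.
4. **Classification.**  Linear discriminant analysis projects the
   selected, z-scored features onto the most discriminating factor
   (MDF1); a cutoff trained on the MDF1 scores calls each slice, and a
   nodule is called benign only if its *lowest-scoring* slice is benign
   — a deliberately conservative rule, since a single malignant-looking
   slice should not be outvoted by its neighbours.
5. **Evaluation.**  Misclassification rates, sensitivity/specificity
   with Clopper–Pearson exact confidence intervals, ROC curves with
   trapezoidal AUC and Hanley–McNeil confidence intervals, and Welch's
   t-test for group ADC comparisons.

The synthetic generator plants class-conditional ADC levels and texture
correlation structure in multi-slice elliptical nodules with Rician
noise, so selection and classification can be exercised — and their
calibration checked against known ground truth — at any sample size.

## Quick start (Python)

```python
from thyrotex import CohortConfig, generate_cohort, run_training, run_test

cohort = generate_cohort(CohortConfig(seed=1))   # 16+8 train, 9+9 test
training = run_training(cohort.training)
print(training.model.features)                   # selected feature names
print(training.metrics["slice_auc"])             # resubstitution AUC

held_out = run_test(cohort.test, training.model)
print(held_out.metrics["nodule_accuracy_pct"])
```

On real data, build a `pandas` feature table with columns
`nodule_id, slice_id, label, <feature...>` (e.g. via `extract_all` on
your own ADC maps and ROI masks) and call `train_from_table` /
`test_from_table` directly.

## Quick start (command line)

```bash
thyrotex simulate --seed 1 --out cohort/            # images + manifest.csv
thyrotex adc      --manifest cohort/manifest.csv --out adc/
thyrotex extract  --manifest cohort/manifest.csv --site training \
                  --out features_train.csv
thyrotex train    --features features_train.csv --out model/
thyrotex extract  --manifest cohort/manifest.csv --site test \
                  --out features_test.csv
thyrotex evaluate --features features_test.csv \
                  --model model/model.json --out test_metrics.json
```

or, all in memory:

```bash
thyrotex run-all --seed 1 --out study/
```

## Worked example

At the default configuration (24 training nodules / 18 held-out test
nodules from an independent noisier site, seed 1) the pipeline selects
2 features, separates the training slices perfectly, and transfers to
the held-out site with 1 of 77 slices and 1 of 18 nodules
misclassified:

| quantity | value |
|---|---|
| weighted-mean ADC, benign (10⁻³ mm²/s, n=200 nodules) | 2.29 |
| weighted-mean ADC, malignant (10⁻³ mm²/s, n=200 nodules) | 1.91 |
| ADC-only ROC AUC (training cohort) | 0.76 |
| training slice AUC (MDF1) | 1.00 |
| test slice misclassification | 1.3 % |
| test nodule accuracy (lowest-slice rule) | 94.4 % |
| held-out slice AUC on a null cohort (no planted effect) | 0.59 |

For context, at a 94-slice training sample 5 errors correspond to a
misclassification rate of 5.3 %, and 2 errors among 34 test slices to
5.9 % (`misclassification_rate(89, 94)` → 5.3).

## Layout

- `src/thyrotex/adc.py` — ADC mapping, ROI summaries, weighted pooling
- `src/thyrotex/texture.py` — quantization and the 278-feature catalogue
- `src/thyrotex/selection.py` — Fisher / mutual information / POE+ACC,
  ranking fusion, backward elimination
- `src/thyrotex/lda.py` — LDA fit, MDF1 scores, cutoff, nodule rule
- `src/thyrotex/evaluation.py` — error rates, exact CIs, ROC, Welch test
- `src/thyrotex/simulate.py` — synthetic cohort generator
- `src/thyrotex/pipeline.py` — orchestration (tables, training, testing)
- `src/thyrotex/cli.py` — `thyrotex` command-line interface
- `docs/methods.md` — modelling choices, parameters, limitations
- `docs/feature_registry.txt` — every feature name → formula
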