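# cytoprs

Myeloblast texture biomarkers for post-transplant relapse risk, end to end:

1. **simulate** — render synthetic Wright-Giemsa-like bone-marrow aspirate
   tiles with exact per-cell ground-truth masks. Each patient carries a
   latent chromatin-heterogeneity value that drives both the rendered
   nuclear texture (between-cell spread of GLCM contrast, skew of GLCM
   correlation) and an exponential proportional-hazards survival time with
   uniform censoring.
2. **segment** — classical myeloblast nucleus segmentation (blue-excess
   channel, Otsu, opening/hole-filling, distance-transform watershed,
   area/solidity filters, area+circularity blast classification) with
   per-pixel TPR/TNR/F1 evaluation. External label masks can be ingested
   instead (e.g. ground truth, or a learned segmenter's output).
3. **extract** — 53 per-cell descriptors (13 Haralick GLCM features,
   8 first-order intensity statistics, 10 morphometrics, 7 Hu moments,
   10 elliptic Fourier harmonic magnitudes, 5 boundary-irregularity
   measures), aggregated to per-tile statistics (mean, median, std,
   skewness across myeloblasts) and averaged over tiles, plus total blast
   count and blast percentage: a frozen, ordered 214-feature patient vector.
4. **train / evaluate** — LASSO-penalized Cox feature selection with
   cross-validated penalty, a pathological risk score (PRS), mean-PRS
   dichotomization, Kaplan-Meier curves, log-rank test, hazard ratios and
   Harrell's C-index; a two-class LDA relapse classifier with ROC/AUC and
   an accuracy-maximizing operating point; and a machine blast-percentage
   baseline evaluated with identical machinery.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria, including
multi-seed simulation studies (about 20 minutes on one CPU); the rest of
the suite runs in a few minutes.

## CLI

```bash
cytoprs simulate --n-patients 92 --tiles-per-patient 6 --tile-px 512 --seed 1 --out cohort/
cytoprs segment  --manifest cohort/manifest.csv --out seg/ --use-truth-masks
cytoprs extract  --manifest cohort/manifest.csv --out features.csv
cytoprs train-prs --features features.csv --manifest cohort/manifest.csv --folds 10 --seed 1 --out model.json
cytoprs classify --features features.csv --model model.json --manifest cohort/manifest.csv --out cls/
cytoprs evaluate --features features.csv --model model.json --manifest cohort/manifest.csv --out eval/
cytoprs all --n-patients 60 --seed 1 --out run/     # full pipeline + comparison report
```

All artifacts are plain text or PNG: tile images (8-bit RGB), label masks
(16-bit PNG), CSV manifests/features, JSON models and reports, a Markdown
comparison report, and a resolved-config snapshot for reproducibility.

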