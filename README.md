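# sarcoemg

Surface electromyography (sEMG) is an attractive, non-invasive window on the
muscle weakness that defines sarcopenia.  `sarcoemg` implements a complete
screening pipeline for clinicians and biosignal researchers: it takes
4-channel lower-limb sEMG (left/right Gastrocnemius Lateralis and Tibialis
Anterior) recorded during a sit-to-stand test, together with routine
screening data (SARC-F questionnaire, hand-grip strength, gait speed), and
grades subjects into three ordinal sarcopenia *confidence levels*:

* **level 1** — SARC-F ≥ 4;
* **level 2** — additionally weak grip (EWGSOP2 cut-offs: < 27 kg men,
  < 16 kg women);
* **level 3** — additionally slow gait (< 0.8 m/s).

Because no public patient dataset exists for this task, the package ships a
synthetic cohort generator (amplitude-modulated band-limited Gaussian noise
with level-dependent amplitude and spectral content) that reproduces the
statistical structure the analysis relies on, including the 3/22/7 class
imbalance of the original clinical cohort.

## Pipeline

1. **Preprocessing** — 4th-order Butterworth band-pass 20–450 Hz; linear
   envelope (full-wave rectification + 10 Hz low-pass); per-channel Maximum
   Voluntary Contraction (MVC) normalisation from 5 s calibration segments.
2. **Feature extraction** — 200 ms windows advanced by 50 ms over the
   sit-to-stand segment; 12 features per channel (48 total):

   | amplitude / energy | counts (guard thr = 0.1 mV) | spectral |
   |---|---|---|
   | IEMG = Σ\|xᵢ\|, MAV, MAV1, MAV2, RMS = √(Σxᵢ²/N), VAR, AAC, SSI | ZC, SSC, WAMP | AIF (mean instantaneous frequency from the analytic-signal phase, Hz) |

3. **Balancing** — SMOTE interpolation to ~50 instances per class, then
   Edited Nearest Neighbours cleaning (drop any instance whose label
   disagrees with ≥ 2 of its 3 nearest neighbours).
4. **Feature selection** — either the fixed published subset
   {IEMG, RMS, AIF} × 4 channels (12 columns, the default) or a binary
   tree-growth metaheuristic wrapper search.
5. **Evaluation** — eight classifiers (SVM, DT, RF, LR, KNN, NB, MLP,
   gradient boosting) at their published hyper-parameters under stratified
   10-fold CV; accuracy, macro precision/recall/F1, Cohen's Kappa
   κ = (p₀ − pₑ)/(1 − pₑ) with qualitative agreement bands, and summed 3×3
   confusion matrices.

## Worked example

```python
from sarcoemg import (BalancingParams, CohortSpec, PipelineConfig,
                      extract_cohort_features, fixed_paper_subset,
                      generate_cohort, run_cv, smote_enn)

cohort = generate_cohort(CohortSpec(seed=1))          # 32 subjects, 3/22/7
fm = smote_enn(extract_cohort_features(cohort, PipelineConfig(seed=1)),
               BalancingParams(target=50, seed=1))    # 150 x 48
report = run_cv(fm, folds=10, seed=1,
                mask=fixed_paper_subset(fm.columns))  # 12 columns
print(report.table().to_string(float_format="%.3f"))
```

prints

```
     Accuracy  Precision  Recall    F1  Kappa Agreement
SVM     1.000      1.000   1.000 1.000  1.000   perfect
DT      1.000      1.000   1.000 1.000  1.000   perfect
RF      1.000      1.000   1.000 1.000  1.000   perfect
LR      1.000      1.000   1.000 1.000  1.000   perfect
KNN     1.000      1.000   1.000 1.000  1.000   perfect
NB      1.000      1.000   1.000 1.000  1.000   perfect
MLP     0.900      0.850   0.900 0.867  0.850   perfect
XGB     1.000      1.000   1.000 1.000  1.000   perfect
```

Each row is one classifier's fold-averaged performance on the balanced
synthetic cohort with the 12-column subset.  The synthetic effect sizes make
the three levels nearly linearly separable, so most classifiers saturate;
on real patients the separation (and hence the ranking spread between
classifiers) is substantially smaller.  See `docs/methods.md` for what these
numbers do and do not establish.

The same pipeline is available from the shell:

```sh
sarcoemg synth --out cohort/ --seed 1
sarcoemg features --in cohort/ --out features.csv
sarcoemg balance --in features.csv --out balanced.csv --target 50 --seed 1
sarcoemg select --in balanced.csv --mode fixed --out mask.json
sarcoemg evaluate --in balanced.csv --mask mask.json --folds 10 --seed 1 --out report.json
# or everything at once, with a run manifest:
sarcoemg all --out results/ --seed 1
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole computation from scratch —
generates the default cohort, extracts and balances features, applies the
fixed subset and benchmarks all eight classifiers — printing the summary
table and writing the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
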