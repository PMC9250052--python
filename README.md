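# pmtl — personalized clinical risk models with transfer learning

Global risk models fit one set of coefficients to an entire hospital
population and can be systematically wrong for the subpopulations that
need them most. `pmtl` implements the alternative: for each index
patient, retrieve the most similar patients under a learned
weighted-Euclidean distance, then fit an on-demand logistic model on that
neighborhood, warm-started from — and softly anchored to — the global
model so that a small neighborhood does not mean an overfit model.

The package was built around acute kidney injury (AKI) risk estimation in
hospitalized adults and ships the full surrounding workflow:

- **Cohort labeling** — KDIGO stage-1 creatinine criteria on rolling 48-h
  windows (rise ≥ 0.3 mg/dL over the window minimum, or ≥ 1.5× the
  admission baseline), baseline-creatinine selection, MDRD-eGFR
  eligibility filtering, and estimation-point placement 24 h before onset
  (cases) or before the last creatinine (non-cases).
- **Model core** — the six benchmark families: global, subgroup and
  personalized logistic models, each cold-started or transfer-initialized.
  The transfer fit minimizes
  `Σᵢ logloss + λₐ‖β − β₀‖² + λᵣ‖β‖²` started at the global coefficients
  β₀, so transferred knowledge dominates when the neighborhood is small
  and the local likelihood dominates when it is large.
- **Similarity** — exact weighted k-NN retrieval (k = 10% of the training
  pool by default) and a probe-AUROC-driven multiplicative search over
  per-feature distance weights.
- **Evaluation** — AUROC (Mann–Whitney), AUPRC (average precision),
  binned calibration error, DeLong and z tests, paired bootstrap
  win counts, a stratified 5-fold cross-validation harness, a
  training-fraction sweep, and alert-matched case-retrieval comparison.
- **Interpretation & metaregression** — permutation AUROC gain,
  interclass score difference, top-predictor correlation heterogeneity,
  relative-effect matrices, coefficient-of-variation across personalized
  fits, and DerSimonian–Laird random-effects metaregression treating each
  personalized model as a study (verified against R `metafor`).
- **Synthetic cohorts** — latent-subgroup generators with
  subgroup-specific coefficients over a shared global signal, calibrated
  prevalence (default 9.4%), mixed binary/continuous features, MCAR
  missingness, and creatinine trajectories that the labeler provably
  round-trips — so every component is testable without protected data.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a heterogeneous cohort, label it from raw creatinine, and run
the cross-validated benchmark:

```bash
pmtl simulate --seed 7 --out work/ --n 4000 --d 12
pmtl label --encounters work/encounters.csv --scr work/scr.csv \
     --out-labels work/labels.csv --out-exclusions work/excl.csv
# -> labeled 4000 encounters (9.7% AKI), excluded 0
pmtl crossvalidate --features work/features.csv --labels work/labels.csv \
     --out work/cv --seed 1 --models global,personalized_tl
```

Or in Python, the core comparison on a strongly heterogeneous cohort
(5 latent subgroups, coefficient-deviation SD τ = 2):

```python
from pmtl import crossvalidate
from pmtl.simulate import SyntheticConfig, generate_cohort, feature_columns

cfg = SyntheticConfig(n=8000, d=12, n_subgroups=5, tau=2.0, sparsity=0.5,
                      n_informative=4, separation=1.2,
                      beta_density=0.5, beta_scale=0.5, seed=0)
cohort, truth = generate_cohort(cfg)
res = crossvalidate(cohort[feature_columns(cohort)], cohort["y"],
                    subgroups=cohort["subgroup_id"],
                    models=("global", "personalized_tl"), seed=0)
rep = res.reports
print(rep["global"].auroc, rep["personalized_tl"].auroc)
print(res.delong[("global", "personalized_tl")])
```

On this cohort the personalized model with transfer learning reaches a
pooled out-of-fold AUROC of **0.844** against **0.754** for the global
model (DeLong p ≈ 1e-62): when subgroups genuinely differ, neighborhoods
of similar patients carry information the global fit averages away. On a
homogeneous cohort (τ = 0) the two models agree to within 0.01 AUROC —
personalization costs nothing when there is no heterogeneity to exploit.
In the training-fraction sweep, shrinking the training set from 100% to
5% costs the cold-started global model about 0.08 AUROC but the
transfer-initialized refit only about 0.005: the anchor to the full-data
coefficients absorbs most of the small-sample damage.

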