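# Methods

This note documents the models and procedures implemented in `trm-spatial`,
the assumptions behind them, the synthetic-data generator that stands in for
patient cohorts, and the numerical and design choices that were genuinely
open.

## Input model and assumptions

The pipeline starts *after* image analysis: cells arrive as a flat table
with planar coordinates in µm, a region label (tumor center `TC` or invasive
margin `IM`, supplied upstream — the package does not segment regions), a
tissue compartment (`epithelium`/`stroma`, from the upstream tissue
segmenter) and binary marker calls. Intensity thresholding and probabilistic
phenotype calling are out of scope by construction: marker calls are
consumed as booleans.

All cells of a patient-region are treated as one pooled point pattern, even
if they originate from several tissue cores. Distances are 2-D Euclidean;
no edge correction is applied at core boundaries. Axis orientation is
irrelevant since only distances enter the features.

Cells co-staining CK and CD8 are classified as cancer cells and excluded
from every immune phenotype. This keeps the cancer-cell set disjoint from
the immune sets, which the distance-based features require.

## Spatial features

Four per-patient features per phenotype × region:

| feature | definition | unit / range | missing when |
|---|---|---|---|
| Dens | n(A)/n(total) × 1000 | cells per 1000, [0, 1000] | region absent |
| InS | n(A)ᵉᵖⁱ / n(A)ˢᵗʳᵒ | ratio ≥ 0 | phenotype absent, or stromal count 0 with epithelial cells present (flagged `undefined-infinite`) |
| mNND | mean over A cells of distance to nearest cancer cell | µm ≥ 0 | no A cells or no cancer cells |
| CCPS | mean over cancer cells of A-cell count within radius r | cells ≥ 0 | no cancer cells |

The density denominator is all segmented cells of the patient-region, both
compartments, because the definition normalises to "total cells" with no
compartment qualifier. mNND and CCPS ignore the compartment label for the
same reason.

The CCPS radius r is a free parameter; the default is **20 µm**, a
cell-contact scale (one to two cell diameters) consistent with reading CCPS
as the number of phenotype cells actually engaging each cancer cell. It is
configurable everywhere and recorded in the fitted-model JSON.

Nearest-neighbour and radius queries run on `scipy.spatial.cKDTree` and are
exact; the test suite holds them to 1e-9 relative agreement with the O(n²)
double loop on random configurations.

An undefined InS is propagated as missing (NaN plus a flag), not as zero or
infinity; imputation happens only inside the modelling step, with training
medians, so the feature table itself stays honest.

## Signature construction

1. **Split.** Patients are randomly assigned 7:3 to train/test with a fixed
   seed. The events-per-variable ratio of the training set is reported and a
   warning raised below 10 EPV.
2. **Preprocessing.** Candidate features are median-imputed and
   standardised; both statistics come from the training set only.
3. **Importance ranking**, three survival learners on (DFS time, event) —
   the endpoint is never binarised:
   - *penalised Cox* (`CoxnetSurvivalAnalysis`, lasso path of 50 penalties):
     the penalty is chosen by ten-fold cross-validation scored by held-out
     Breslow partial log-likelihood; importance = |coefficient| at the
     chosen penalty;
   - *gradient-boosted Cox trees* (`xgboost`, objective `survival:cox`,
     depth 2, η = 0.1): total-gain importance averaged over bootstrap refits
     (default 1000 repetitions; the repetition count is configurable and
     smaller profiles are used at desk scale). Averaging over bootstrap
     resamples stabilises gain importance, which is otherwise noisy for a
     single fit;
   - *random survival forest* (`RandomSurvivalForest`): permutation
     importance, i.e. mean drop in training concordance when one feature
     column is shuffled.
   Ties are broken by lexicographic feature name; constant features get
   importance 0.
4. **Selection.** The intersection of the three top-10 lists, ordered by
   mean rank. An empty intersection is an error (more data or a larger
   top-k is needed) — on pure-noise cohorts this is the expected outcome
   and is exactly what keeps the null safe.
5. **Cut-points.** Each selected feature is dichotomised at the threshold
   maximising the two-group log-rank statistic over all observed values,
   with at least 10% of patients on each side (the core operation of
   cut-point software such as X-tile, re-implemented here with a vectorised
   log-rank scan; `lifelines` serves as an independent oracle in the
   tests). Ties resolve to the smallest threshold. No multiplicity
   correction is applied inside the search — the selected threshold's
   p-value is optimistic, which is why evaluation leans on the held-out
   set.
6. **Weights.** Each indicator's weight is ln(HR) from a univariate Cox fit
   of DFS on the training set; `SIS = Σ ln(HRᵢ)·Xᵢ`. Features whose
   univariate fit fails (e.g. zero events in one level) are dropped with a
   warning.
7. **Risk groups.** The SIS threshold comes from the same maximally
   selected log-rank search applied to the SIS itself; if no admissible
   threshold exists the training median is used (flagged in the results).

No test-set information reaches any fitted quantity; the suite verifies
this by mutating test rows and asserting an unchanged model.

## Survival evaluation

- Kaplan–Meier curves and the log-rank test between high and low SIS, per
  train/test/entire subset; a median that is never reached is reported as
  missing, not as a number.
- Univariate Cox per covariate, then a multivariate model built from the
  covariates with univariate p < 0.05 and reduced by backward elimination
  (drop the covariate whose best level-p is largest, until all retained
  covariates have a level below 0.05). Reference levels are explicit;
  multi-level covariates enter as dummy blocks.
- Time-dependent ROC: the cumulative-case / dynamic-control variant with
  inverse-probability-of-censoring weighting (`sksurv.metrics.
  cumulative_dynamic_auc`), at 12/36/60 months. The censoring distribution
  is estimated on the training subset. This flavour is the standard choice
  for fixed-horizon prognostic scores; with no censoring it reduces to the
  empirical AUC (asserted in tests). The continuous SIS is scored by
  default; the high/low group can be scored instead.
- The combined model fits a proportional-hazards model on {SIS group,
  stage} and compares its AUCs with the stage-only and SIS-only models.

Two-sided α = 0.05 throughout; no multiplicity correction.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at desk scale:

- **Geometry.** Each patient-region is a 600 µm square window with 1–k
  random disk "nests" (Poisson mean 4, radii 50–110 µm) defining the
  epithelium; everything else is stroma. Cancer cells are placed uniformly
  inside nests, so InS has a well-defined ground truth.
- **Cell mix.** Cell counts per region are Poisson around a per-patient
  lognormal size factor (default mean 1500). Default phenotype rates give a
  T_RM share of CD8⁺ cells of ~60% in TC and ~37% in IM, and a subset mix
  of roughly 40/10/25/25% (TC) and 51/9/25/15% (IM) across
  T_RM1/2/3/4 — the composition regime the analysis targets.
- **Latent coupling.** A per-patient standard-normal factor tilts the
  CD103 fraction together with the PD-1/Tim-3 subset odds and GZMB rates
  (logit-scale slopes 0.5), inducing the positive patient-level correlation
  of CD103 with checkpoint and granzyme expression across patients.
- **Placement.** Immune cells mix a uniform kernel with a Gaussian kernel
  (σ = 20 µm) around randomly chosen cancer cells; the attraction weight is
  graded 0.15/0.30/0.50/0.65 across T_RM1→T_RM4 (0.10 for T_nonRM), so the
  more exhausted subsets sit nearer cancer cells: mNND decreases and CCPS
  increases from T_RM1 to T_RM4, and GZMB⁺ fraction peaks in T_RM2 and
  bottoms in T_RM4 by the configured rates.
- **Survival.** DFS is exponential proportional-hazards on the *realized*
  planted features (standardised across the cohort; centred linear
  predictor so the 60-month baseline median describes the average patient),
  plus a configurable stage effect (default hazard ratios 1.63 for stage II
  and 3.21 for stage III against stage I). Censoring is independent uniform on
  [0, c_max] with c_max calibrated by bisection so the expected event
  fraction is 39.4%. Generating survival from realized rather than latent
  feature values makes recovery targets exactly what the pipeline measures.
  Default planted effects: ln 0.41 on `InS.TnonRM.TC` and ln 0.36 on
  `InS.TRM1.IM` (hazard ratios from the motivating signature whose planted
  magnitudes exceed 0.7 on the log scale). Aggregate features such as
  `mNND.TRM.TC` are deliberately not planted: they are exact cell-weighted
  averages of subset features also present in the candidate set, and no
  importance method can attribute a collinear cluster to one member.
- **Panel 2.** The per-region CD31⁺ rate follows a Gaussian copula against
  the realized T_RM density across patients at the configured coupling
  (default −0.4), with a lognormal dispersion of 1.0 so that between-patient
  variation dominates counting noise and the measured Spearman correlation
  tracks the knob; Hif-1α is drawn independently of T_RM (its correlation
  with T_RM density is a built-in null).
- The generator is fully seed-deterministic (byte-identical cell tables for
  a fixed config), coordinates are emitted at the declared 0.01 µm
  precision, and its output passes the IO validators round-trip.

**What the generator does not emulate:** nucleus/membrane geometry,
segmentation errors and marker spill-over, multiple cores per region,
spatial autocorrelation of marker intensity, competing risks, or informative
censoring. Passing tests therefore demonstrate the pipeline's correctness
and statistical behaviour under a clean data-generating process, not
robustness to the artefacts of real mIF data.

## Problem sizes and numerical choices

- Tests and the acceptance script run cohorts of 120–300 patients at
  200–1500 cells per region, with reduced learner profiles (e.g. 100–200
  boosting repetitions, 60–100 forest trees); these sizes keep full
  replicate loops to minutes on one CPU while leaving every statistical
  condition (cohort size, event fraction, planted effect sizes, coupling)
  at its study value.
- Cut-point scan tolerance: a candidate must beat the incumbent by more
  than 1e-12 to replace it, making the smallest-threshold tie-break robust
  to floating-point noise.
- The log-rank variance uses the standard hypergeometric tie correction;
  risk sets with one subject contribute zero variance.
- Coxnet cross-validation scores a fold by the Breslow partial
  log-likelihood of the held-out fold alone (not the difference trick);
  folds without events are skipped.
- Degenerate inputs: empty regions yield missing features (flagged);
  constant features rank last with importance 0; a signature whose every
  selected feature fails cut-point or Cox fitting is an error, not a silent
  empty model.

## Known limitations

- The maximally selected cut-point search is optimism-prone by design
  (matching common practice with X-tile); its in-sample p-values should not
  be quoted.
- Permutation importance splits credit among strongly correlated features;
  aggregate features and their components compete in the ranking, which is
  a property of the feature algebra, not of the implementation.
- With two planted features and a generous candidate set, the triple
  intersection often selects only the planted pair; real cohorts with
  diffuse signal will select more.
- The IPCW AUC requires the horizon to lie inside the follow-up range;
  horizons beyond the last observed time are reported missing.
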