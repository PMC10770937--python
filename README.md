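# trm-spatial

Spatial phenotyping of CD103⁺CD8⁺ tissue-resident memory T cells (T_RM) in
the tumor microenvironment, and construction of a prognostic **spatial immune
signature (T_RM-SIS)** from multiplex-immunofluorescence (mIF) cell tables.

The package is for analysts working with single-cell mIF exports from tumor
tissue (e.g. NSCLC tissue microarrays): one row per segmented cell with
planar coordinates in µm, a tumor-region label (tumor center `TC` / invasive
margin `IM`), a tissue compartment (`epithelium` / `stroma`) and binary
marker calls. From these it derives per-patient spatial features, builds a
survival signature, and evaluates it — and it ships a synthetic-cohort
generator so every stage can be exercised and validated without patient
data.

## The model

**Phenotypes.** CD8⁺ T cells split into T_RM (CD103⁺CD8⁺) and T_nonRM
(CD103⁻CD8⁺); T_RM further partitions by immune-checkpoint co-expression
into T_RM1 (PD-1⁻Tim-3⁻), T_RM2 (PD-1⁺Tim-3⁻), T_RM3 (PD-1⁻Tim-3⁺) and
T_RM4 (PD-1⁺Tim-3⁺). Granzyme B positivity is a cytotoxicity readout, never
part of a subset definition. CK⁺ cells are cancer cells (disjoint from all
immune sets). A second panel reads CD31 (microvessel endothelium) and
Hif-1α (hypoxia).

**Spatial features** per patient, phenotype A and region:

- `Dens(A) = n(A) / n(total cells) × 1000` — density per 1000 cells;
- `InS(A) = n(A)ᵉᵖⁱ / n(A)ˢᵗʳᵒ` — epithelial/stromal infiltration score;
- `mNND(A~C) = Σᵢ d_min(Aᵢ~C) / n(A)` — mean distance to the nearest
  cancer cell (µm);
- `CCPS(A) = Σᵢ n(Cᵢ →ʳ A) / N(C)` — mean number of A cells within radius
  r (default 20 µm) of each cancer cell.

**Signature.** On a 7:3 train/test split, candidate features are ranked by
three survival learners (L1-penalised Cox with ten-fold CV, gradient-boosted
Cox trees with bootstrap-averaged gain, random survival forest with
permutation importance); the intersection of their top-10 lists is selected.
Each selected feature is dichotomised at its maximally selected log-rank
cut-point and weighted by the univariate Cox log hazard ratio:

    SIS = Σᵢ ln(HR_Xᵢ) · Xᵢ ,   Xᵢ = 1[featureᵢ > cutoffᵢ]

Patients split into high/low risk at the SIS's own cut-point. Evaluation:
Kaplan–Meier/log-rank, univariate + backward-eliminated multivariate Cox,
and IPCW time-dependent AUC at 12/36/60 months, plus a SIS+stage combined
model. Everything a scored patient touches derives from training data only.

## Worked example

```python
import trm_spatial as ts

cfg = ts.SyntheticConfig(n_patients=150, cells_per_region=400, seed=3)
cohort, truth = ts.generate_cohort(cfg)

model = ts.SpatialSignatureModel.from_cohort(cohort)
results = model.fit(seed=5, xgb_repetitions=100, rsf_trees=100)
print(results.summary())
evaluation = results.evaluate()
print(evaluation.summary())
```

prints

```
T_RM spatial immune signature
==============================================
split: 105 train / 45 test (seed 5)
selected features (2):
feature               cutoff    ln(HR)      HR
InS.TRM1.IM           0.5714    -1.486    0.23
InS.TnonRM.TC         0.1333    -1.397    0.25
SIS cut-point: -1.4862 (max-logrank)

Signature survival evaluation
======================================================
train: log-rank p=0.000133; median DFS high: 30.8, low: not reached
test: log-rank p=0.0811; median DFS high: 20.9, low: not reached
entire: log-rank p=2.97e-05; median DFS high: 26.1, low: not reached
time-dependent AUC (continuous SIS):
horizon     12     36     60
set
entire   0.784  0.745  0.823
test     0.784  0.785  0.785
train    0.799  0.728  0.897
...
multivariate (retained: stage, sis_group):
  stage       II        HR 1.09 (0.56, 2.12)  p=0.796
  stage       III       HR 2.45 (1.27, 4.73)  p=0.00766
  sis_group   high      HR 4.34 (2.02, 9.29)  p=0.000162
```

The generator planted protective effects on two infiltration-score features
(`InS.TnonRM.TC`, `InS.TRM1.IM`); the pipeline re-discovers exactly those
two from 58 candidates, dichotomises them, and the resulting SIS separates
survival on the held-out set and remains prognostic next to tumor stage in
the multivariate Cox model.

The same pipeline is available from the shell:

```bash
trm-spatial simulate  --config sim.yaml --out-dir sim/
trm-spatial features  --cells sim/cells.csv --clinical sim/clinical.csv \
                      --radius 20 --out features.csv
trm-spatial signature --features features.csv --clinical sim/clinical.csv \
                      --seed 17 --out-model model.json --out-scores scores.csv
trm-spatial evaluate  --features features.csv --clinical sim/clinical.csv \
                      --model model.json --scores scores.csv --out aucs.csv
```

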