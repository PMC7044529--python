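# protraj — prognostic trajectory modelling for MCI-to-dementia progression

`protraj` is a Python library and command-line tool for modelling
individualised trajectories of cognitive decline in mild cognitive
impairment (MCI). Rather than stopping at the usual binary question — will
this patient progress to Alzheimer's dementia within three years (pMCI) or
remain stable (sMCI)? — it derives a *continuous* prognostic score from a
binary classifier, and validates that score against each patient's
subsequently observed rate of memory decline.

It is aimed at researchers working with ADNI-style cohort data: baseline
cognitive composites (a memory composite, an executive-function composite,
a depression sum score), amyloid-PET SUVR, APOE ε4 status, longitudinal
memory scores, and voxelwise grey-matter density maps from structural MRI.
Because such data are access-restricted, the package ships a seeded
synthetic-cohort generator with the same statistical structure, so the full
pipeline is runnable and testable out of the box.

## The models

**GMLVQ with a scalar projection.** Generalised Matrix Learning Vector
Quantization learns one prototype per class, w_s (stable) and w_p
(progressive), together with a full metric tensor Λ = ΩᵀΩ defining the
distance d(x, w) = (x − w)ᵀ Λ (x − w). Training is stochastic steepest
descent on the Sato–Yamada cost Σᵢ (d_J − d_K)/(d_J + d_K), with Ω
renormalised after every update so that trace(Λ) = 1: the diagonal of Λ
is then a relevance profile over features and the off-diagonals are signed
pairwise interactions. The continuous score is the Λ-weighted projection
onto the prototype axis,

    s(x) = (x − w_s)ᵀ Λ (w_p − w_s) / (w_p − w_s)ᵀ Λ (w_p − w_s),

so that s(w_s) = 0, s = 0.5 exactly on the decision boundary, and
s(w_p) = 1, with values beyond [0, 1] meaningful.

**PLS-RFE grey-matter biomarker.** Partial least squares regression from
voxelwise grey-matter density to the memory composite, combined with
recursive feature elimination under 5-fold nested cross-validation and
early stopping, yields a sparse voxel weight map. The *PLS-derived grey
matter score* of a subject is the centered weighted sum of their density
over the retained voxels — a scalar atrophy biomarker that can replace the
raw image in the GMLVQ "biological" model (grey-matter score, amyloid
SUVR, APOE4).

**Validation statistics.** Stratified k-fold CV with nested hyperparameter
tuning (accuracy, macro-averaged error, class-wise rates), random
resampling with median-model selection, Pearson correlations with Fisher
confidence intervals, partial correlations, Fisher r-to-Z and Steiger Z
comparisons of correlations, OLS rates of decline, a 2-SD outlier rule and
a 90th-percentile biomarker-positivity rule.

## Worked example

```python
from protraj import GMLVQ, PLSRFE, SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(seed=1))      # 300 subjects, 22^3 voxels
lab = cohort.labelled                                   # stable/progressive MCI

# grey-matter biomarker from density -> memory regression
pls = PLSRFE(cohort.voxels, cohort.table.adni_mem.to_numpy()).fit(seed=1)
print(pls.summary())

# cognitive GMLVQ classifier and its relevance profile
model = GMLVQ.from_dataframe(lab, ["gds", "adni_mem", "adni_ef"], "label")
res = model.fit(seed=1)
print(res.summary())
```

prints (abridged):

```
PLS-RFE results
=============================================
input voxels:    10648
retained voxels: 144
outer folds:     5
components/fold: [1, 1, 1, 1, 1]
held-out r2:     0.6342
...
GMLVQ results
=============================================
features:             gds, adni_mem, adni_ef
...
feature relevances (diagonal of lambda):
  gds                    0.0090
  adni_mem               0.9897
  adni_ef                0.0013
```

The 144 retained voxels recover the planted 123-voxel atrophy region (the
extra ones are its immediate neighbours), the held-out r² is the
cross-validated variance in the memory composite explained by the
grey-matter score, and the relevance profile identifies the memory
composite as the dominant discriminative feature — the structure the
simulator planted. `res.project(X)` then yields the scalar projection per
subject; on held-out subjects it correlates strongly negatively
(r ≈ −0.77 on this cohort) with the true memory-decline slope.

The same pipeline is scriptable from the shell:

```sh
protraj simulate --out data --seed 1
protraj fit-pls --voxels data/voxels.csv --voxel-index data/voxel_index.csv \
    --table data/cohort.csv --out map.csv
protraj score-gm --map map.csv --voxels data/voxels.csv \
    --voxel-index data/voxel_index.csv --table data/cohort.csv --out gm.csv
protraj fit-gmlvq --features data/cohort.csv --columns gds,adni_mem,adni_ef \
    --out model.json
protraj project --model model.json --features data/cohort.csv --out proj.csv
protraj validate --features data/cohort.csv --columns gds,adni_mem,adni_ef \
    --mode cv --k 10
```

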