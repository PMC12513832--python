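# tmesig

Signature discovery for spatial multi-omics cohorts of immunotherapy-treated
patients. `tmesig` is for computational oncologists who have per-patient,
per-compartment (tumor vs stroma) cell-type fraction matrices and
gene-expression count matrices with survival follow-up, and who want
*directional*, externally validatable risk signatures plus an account of the
spatial organization behind them.

## What it implements

**Cell-type signatures by sign-constrained stability selection.** Given the
fraction matrix `M_ij` (patient i, cell type j) and progression-free
survival, the pipeline fits M LASSO-penalized Cox models (fresh ten folds
per split; tenfold CV picks the penalty λ; the split's model is refit on the
pooled cohort at that λ) with coefficients constrained non-negative for
resistance signatures or non-positive for response signatures. Cell types
with nonzero coefficients in at least t of the M models are retained, with t
the largest threshold keeping at least three cell types. A final
unpenalized, still sign-constrained Cox fit gives `β_final`, and patients
are scored as

    S_i = Σ_j β_final_j · M_ij

The median (or upper-tertile) training score is frozen into the model;
validation cohorts are dichotomized at that stored cutpoint and tested with
a one-sided log-rank in the training-established direction (two-sided in
discovery).

**Cell-to-gene signatures.** Candidate genes are restricted to the signature
cell types' marker sets (~500 genes for a resistance model, ~200 for
response, with the bundled synthetic libraries). Fifty 80/20 splits each run
a negative-binomial exact-test DE filter (P < 0.05, training half only) and
100 seeded CV-LASSO fits; each split's gene union is refit unpenalized and
scored on its held-out fifth. Genes with nonzero coefficients in ≥5% of the
splits whose held-out HR passes the gate (HR > 1.5 resistance, HR < 0.7
response) are retained, capped at ten, and refit on the full discovery
cohort with a frozen upper-tertile cutpoint.

**Survival core.** Breslow/Efron partial likelihood, Newton fits with
separation handling, an IRLS + coordinate-descent solver for the
sign-constrained L1-penalized Cox objective (numba-compiled), stratified CV
deviance for λ, Kaplan–Meier, one-/two-sided log-rank, hazard ratios.

**Spatial analysis.** Pairwise interaction scores (neighbors within 30 µm
capped at the 10 nearest) against a within-region label-permutation null;
cellular neighborhoods from 10-nearest-neighbor composition vectors
clustered into ten groups by seeded k-means; OLS differential enrichment of
cell types across neighborhoods by outcome; per-patient neighborhood
frequencies with Welch t-tests.

**Synthetic cohorts.** Dirichlet fractions over 14 phenotypes, exponential
proportional-hazards survival driven by planted per-SD signature
coefficients, NB counts with cell-type programs, spatial fields with planted
niches — so every stage is testable end to end without any external data.
An NNLS deconvolution consistency check (`B × F_i ≈ M_i` against an
LM22-style reference matrix) is included.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Train a resistance signature on a synthetic cohort with three planted
hazardous cell types (per-SD log HR = 1 each), then validate it on an
independent cohort with the frozen cutpoint:

```python
from tmesig import (CohortSpec, CelltypePipelineConfig,
                    simulate_cell_fractions, simulate_survival,
                    planted_scores, train_celltype_signature,
                    score_patients, evaluate_signature)

spec = CohortSpec(n_patients=150, seed=7,
                  planted_resistance={"proliferating_tumor": 1.0,
                                      "granulocyte": 1.0, "vessel": 1.0})
fractions = simulate_cell_fractions(spec)["tumor"]
surv = simulate_survival(planted_scores(fractions, spec), spec)

cfg = CelltypePipelineConfig(n_models=100, direction="resistance", seed=0)
model = train_celltype_signature(fractions, surv, cfg)
scores = score_patients(model, fractions)
res = evaluate_signature(scores, surv, model, sided="two")
```

Output:

```
selected cell types: ['b_cell', 'granulocyte', 'proliferating_tumor', 'vessel']
coefficients: {'b_cell': 2.84, 'granulocyte': 17.06, 'proliferating_tumor': 18.39, 'vessel': 15.07}
threshold t: 100 of M = 100
frozen median cutpoint: 3.984
training HR = 6.09 (95% CI 3.85-9.63), two-sided log-rank p = 1.40e-17
validation HR = 4.71, one-sided log-rank p = 0.000
```

The three planted types are selected in all 100 splits (t = 100; one noise
type, `b_cell`, sneaks in with a small coefficient). Coefficients are on the
raw fraction scale — a fraction SD is ≈ 0.07, so 17 per unit fraction is
≈ 1.1 per SD, matching the planted effect. Patients above the frozen median
cutpoint progress about six times faster in training, and the signature
transfers to the independent cohort (HR 4.7) without recomputing anything.

The same flow is available from the shell:

```bash
tmesig simulate --n-patients 150 --seed 7 --out-dir sim
tmesig train-celltype --fractions sim/fractions_tumor.csv \
    --clinical sim/clinical.csv --direction resistance --out model.json
tmesig validate --model model.json --fractions sim/fractions_tumor.csv \
    --clinical sim/clinical.csv --sided one
```

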