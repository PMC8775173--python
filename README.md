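# iescore

Immune Effective Score (IES) analysis for bulk expression cohorts of
HER2-positive breast cancer (and, more generally, any cohort where a
composite immune-effector score is evaluated against therapy response and
survival).

## The problem

A sizeable fraction of HER2-positive breast cancers do not reach a
pathological complete response (pCR) under neoadjuvant trastuzumab, and
host immune activity is a leading candidate explanation: tumors with strong
effector-cell infiltration respond better and live longer. `iescore`
implements the full analysis pipeline for quantifying that signal from a
log-scale gene expression matrix:

1. **ssGSEA signature scoring.** Seven immune effector signatures — CD8 T
   cells, Tfh, Th1, NK, cytolytic activity, inflammation promoting, and
   T-cell costimulation — are scored per sample by single-sample gene set
   enrichment. With genes ranked per sample (rank 1 = highest) and
   descending-rank weight `r_i = N − rank_i + 1`, the enrichment score of a
   set `S` is the summed gap between the weighted in-set ECDF and the
   uniform out-of-set ECDF,

   `ES(S) = Σ_i [ P_in(i) − P_out(i) ]`,
   `P_in(i) = Σ_{g∈S, rank≤i} r_g^τ / Σ_{g∈S} r_g^τ`,
   `P_out(i) = |{g∉S, rank≤i}| / (N − |S|)`,

   with rank-weight exponent τ = 0.25 by default.
2. **IES.** The sample-by-signature score matrix is reduced by PCA
   (correlation-matrix PCA by default), components are sign-oriented so
   their loadings sum non-negatively, and **IES = PC1 + PC2**. Samples in
   the top third of IES are labeled "high", the rest "low".
3. **Coexpression screening (WGCNA-style).** Top-variance genes,
   unsigned adjacency `|r|^β` with β chosen by the scale-free topology fit
   (signed R² ≥ 0.9), topological overlap, average-linkage modules, module
   eigengenes, and eigengene–trait correlation (flagging modules with
   r > 0.35 and p < 0.001).
4. **Predictive evaluation.** pCR rates by IES group with Fisher's exact
   test, and ROC analysis of continuous IES with the tie-corrected
   Mann–Whitney AUC and a DeLong 95% CI.
5. **Prognostic evaluation.** Kaplan–Meier curves with Greenwood errors and
   the log-rank test by IES group, and multivariate Cox proportional
   hazards (Newton–Raphson on the partial likelihood, Efron or Breslow
   ties) with the IES entered per standard deviation.

Because the original cohorts live in external repositories, the package
ships a synthetic cohort generator (`iescore.simulate`) that reproduces the
statistical structure the analysis assumes — a latent immune factor that
raises signature-gene expression, raises pCR probability through a logistic
link, and lowers hazard through a proportional-hazards link, plus
block-correlated module genes — so every stage is testable offline.

## Worked example

```python
from iescore import (GeneratorConfig, generate, score_all, build_ies,
                     response_table, roc_auc, prognostic_report,
                     gamma_for_latent_auc)
from iescore.ies import DEFAULT_SIGNATURES

# a synthetic 88-sample cohort whose latent immune factor carries a
# discriminating signal calibrated to a latent AUC of 0.80
gamma = gamma_for_latent_auc(0.80)          # -> 1.3852
cohort = generate(GeneratorConfig(seed=7, n_samples=88,
                                  gamma=gamma, gamma_mod=0.0))

sig_sets = {k: cohort.sets[k] for k in DEFAULT_SIGNATURES}
scores = score_all(cohort.expr, sig_sets, tau=0.25, normalize=True)
model = build_ies(scores)                   # PCA, IES, tertile groups

rt = response_table(model.groups_, cohort.clinical["response"])
mask = cohort.clinical["response"].isin(["pCR", "RD"])
roc = roc_auc(model.ies_[mask],
              (cohort.clinical.loc[mask, "response"] == "pCR").astype(int))
prog = prognostic_report(model.ies_, model.groups_, cohort.clinical,
                         endpoint="OS", covariates=["age", "stage"])
```

This run prints:

```
explained variance: [0.932 0.017]
high/low: 30 58
pCR rate high = 0.60, low = 0.17, Fisher p = 0.0001
AUC = 0.800 (95% CI 0.704-0.896)
OS: log-rank p = 0.103; Cox HR per SD IES = 0.59 (95% CI 0.44-0.80), p = 0.0007
```

Reading: the first two components capture ~95% of the signature variance;
30 of 88 samples (the top third) are IES-high; the high group reaches pCR
3.5× as often as the low group; as a continuous marker the IES separates
responders with AUC 0.80; and in a multivariate Cox model each SD of IES
multiplies the death hazard by 0.59, i.e. higher immune effector activity
is protective.

The same pipeline runs from the shell:

```bash
ies simulate --out sim/ --seed 7 --n-samples 88
ies run --expr sim/expression.tsv --gmt sim/gene_sets.gmt \
        --clinical sim/clinical.csv --out results/
```

which writes score/IES/module/ROC/KM/Cox tables and a machine-readable
`report.json`.

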