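# imply-deconv

Personalized cell-type deconvolution for **repeated-measures bulk RNA-seq**.

Standard reference-based deconvolution regresses every bulk sample on one
population-level signature matrix *E* (marker genes × cell types) and so
ignores that reference profiles differ between subjects and between disease
groups.  When each subject is measured several times — longitudinal blood
draws, multi-region biopsies — those repeats share the subject's underlying
cell-type-specific expression, and that structure can be exploited to build a
**personalized reference panel** per subject and re-deconvolve against it.

## The model

For gene *g*, subject *n* (group label *z_n* ∈ {0,1}) and repeat *i*, the
pipeline runs three stages:

1. **Coarse deconvolution.**  Each sample *y·ni* is regressed on the
   population signature, *y = Eθ + b*, with a linear ν-support-vector
   regression (ν ∈ {0.25, 0.5, 0.75}, best fit by reconstruction RMSE);
   negative coefficients are truncated and the rest normalized to the
   simplex, giving initial compositions θ̂\_E.

2. **Personalized panel recovery.**  Per gene, a linear mixed-effect model

   E(y_ni) = Σ_k (m_k + β_k z_n + u_nk) · θ̂\_E,nik

   is fitted by REML — fixed cell-type means *m_k*, group contrasts *β_k*,
   and subject-level random slopes *u_nk* with diagonal covariance.  The
   subject's panel entry is r_nk = m̂_k + z_n β̂_k + û_nk (clipped at 0),
   assembling a G × K panel *R_n* per subject.

3. **Personalized deconvolution.**  Each subject's repeats are deconvolved
   against *R_n* by non-negative least squares (the joint Kronecker-form
   objective across repeats is block-separable, so it is solved per sample);
   a per-sample ν-SVR variant ("imply-s") is available with
   `--stage3-solver svr`.

The package also ships the Gamma–Dirichlet–Poisson simulator used for
benchmarking (multivariate-normal log-means/log-dispersions correlated
across cell types, Gamma cell-type-specific panels, LFC-based differential
expression, subject-to-subject variation bands, Dirichlet compositions,
Poisson counts, top-coefficient-of-variation marker selection) and the
compositional evaluation metrics ABD, rABD, CD and Lin's concordance
correlation coefficient with Euclidean and Aitchison variants.

## Worked example

```python
import imply

cfg = imply.SimulationConfig(n_genes=300, n_subjects_per_group=8,
                             n_markers=120, seed=42)
truth = imply.simulate(cfg)

model = imply.PersonalizedDeconvolution(truth.bulk, truth.signature)
result = model.fit()
print(result.summary())

rep = imply.evaluate_pair(result.proportions,        # personalized (Stage III)
                          result.stage1_proportions, # baseline (Stage I)
                          truth.theta_T)             # ground truth
print(f"ABD  = {rep.abd:.3f}")
print(f"rABD = {rep.rabd_percent:.2f}%")
print(f"CD   = {rep.cd:.4f}")
```

prints

```
Personalized Deconvolution Results
==================================================
Samples:               48
Subjects:              16
Cell types:            6
Marker genes (panel):  120
Stage III solver:      nnls
OLS fallback fraction: 0.000
--------------------------------------------------
Mean estimated proportions (Stage III | Stage I):
  CT1              0.3007 | 0.3010
  CT2              0.2468 | 0.2480
  CT3              0.2110 | 0.2106
  CT4              0.1376 | 0.1379
  CT5              0.0756 | 0.0750
  CT6              0.0282 | 0.0276

ABD  = -0.183
rABD = -18.30%
CD   = 0.0009
```

ABD sums |estimate − truth| over all (sample, cell type) entries for the
personalized estimate and subtracts the same total for the baseline: the
negative value means personalization removed about 0.18 of cumulative
absolute proportion error (−18.3% in relative terms); the positive CD means
it also increased the Pearson correlation with the truth.

## Command line

```sh
imply simulate --config sim.yaml --out simdir/        # synthetic cohort + truth
imply run --bulk bulk.tsv --meta meta.tsv \
          --signature sig.tsv --out outdir/           # three-stage pipeline
imply evaluate --est outdir/proportions.tsv \
               --baseline outdir/proportions.stage1.tsv \
               --truth simdir/theta_truth.tsv --out metrics.tsv
```

Bulk input is a genes × samples TSV/CSV (or MatrixMarket `.mtx` with
`genes.tsv`/`samples.tsv` sidecars); metadata needs `sample_id`,
`subject_id`, `repeat_index`, `group` columns.  Raw counts are scaled to
counts-per-million before modeling (`--no-normalize` to bypass).

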