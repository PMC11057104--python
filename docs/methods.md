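# Methods

## Problem setting

A cohort of *N* subjects, each with a binary group label *z_n* (e.g. case /
control) and *t_n* repeated bulk RNA-seq samples, yields a G × T expression
matrix.  The goal is the K-vector of cell-type proportions for every sample.
Reference-based deconvolution solves this with one population signature
matrix *E* (J marker genes × K cell types); the pipeline here replaces *E*,
after an initial pass, with a subject-specific panel *R_n* estimated from
the subject's own repeats.

## Stage I — coarse deconvolution

Each sample (restricted to the marker genes shared with *E*; at least K
required, a warning if more than half the markers are missing from the
bulk) is fitted with a linear ν-SVR, minimizing ½‖θ‖² + C Σ(ξ_j + ξ_j\*).
Settings: C = 1, ν grid {0.25, 0.50, 0.75}; the grid member with the lowest
root-mean-square error between the observed and reconstructed expression
wins, ties going to the smallest ν.  Both the sample vector and each
signature column are z-scored across the shared markers before fitting and
the coefficients are mapped back to the original scale afterwards; this
stabilizes the SVR across expression scales and makes the normalized output
exactly invariant to rescaling the sample (a whole-matrix standardization
of *E* was evaluated and was markedly less accurate on simulated mixtures,
so the per-column scheme is the default; `SVRConfig(standardize=False)`
disables it).  Negative coefficients are set to zero and the rest
normalized to sum to one; an all-non-positive coefficient vector falls back
to the uniform composition with a warning.

## Stage II — personalized panel recovery

Per gene (index suppressed), with θ̂ the Stage I compositions:

E(y_ni) = Σ_k (m_k + β_k z_n + u_nk) θ̂_nik,  u_n· ~ N(0, diag(σ²_1..σ²_K))

* No fixed intercept: the mean runs entirely through the compositions; an
  intercept would be confounded with the sum-to-one θ rows.
* Random effects are subject-level slopes on the θ columns with diagonal
  covariance — one variance per cell type, no cross-cell-type correlation
  and no random intercept.  This is the minimal structure in which each
  subject deviates by one number per cell type, and keeps K variance
  components estimable from t_n ≈ 3 repeats.
* Estimation is REML.  Because the design (θ, z, subject blocks) is shared
  by all genes, the profiled REML criterion is computed directly on the
  per-subject t_n × t_n marginal covariance blocks V_n = I + Z_n Γ Z_n′
  (Γ = variance ratios to the residual), subjects with equal t_n batched
  into one einsum; the criterion is minimized over Γ ≥ 0 with L-BFGS-B
  (tolerance 1e-8, 200 iterations).  This custom solver is numerically
  equivalent to a general mixed-model fit — the test suite cross-checks it
  against statsmodels `MixedLM` with variance components — but roughly an
  order of magnitude faster, which is what makes genome-wide per-gene fits
  and the replicated benchmark practical.
* Variance ratios are optimized on the bounded domain, so a component can
  land exactly at zero; its BLUP column is then exactly zero (random-effect
  shrinkage to the group mean).  Degenerate designs: a cell type whose θ
  column is identically zero is dropped from the fixed and random parts and
  gets zero coefficients; if the optimizer fails, the gene falls back to
  ordinary least squares on the fixed part (`fallback="fixed_only"`,
  fraction reported in the model summary).
* BLUPs: û_n = Γ Z_n′ V_n⁻¹ (y_n − X_n b̂).

The panel entry is r_nk = m̂_k + z_n β̂_k + û_nk, clipped at zero.  By
default Stage II fits only the J marker genes (the Stage III feature
space); `genes="all"` fits genome-wide.

## Stage III — personalized deconvolution

Per subject, the joint objective ‖(R_n ⊗ I_tn) vec(Θ′) − vec(y′)‖₂ subject
to Θ ≥ 0 couples no coefficients across repeats, so it is solved as t_n
independent non-negative least-squares problems (active-set solver); the
equivalence with the vectorized Kronecker system is asserted to 1e-10 in
the tests rather than assumed.  An all-zero panel column pins that cell
type's abundance at zero with a warning.  The objective constrains only
non-negativity; because all downstream evaluation treats Θ as proportions,
rows are normalized to sum to one by default (`normalize_output=False`
keeps the raw scale; an all-zero solution row becomes uniform with a
warning).  The `svr` solver routes each sample through the Stage I
machinery with R_n in place of E (the "imply-s" variant).

## Input scale

The mixing model is linear in expression space.  Raw counts are scaled to
counts-per-million per sample before all three stages (`--no-normalize`
bypasses this).  Stage I and Stage III are invariant to per-sample scaling
(z-scoring and simplex normalization respectively), so CPM matters mainly
for Stage II, where it puts samples with different sequencing depths on a
common response scale.

## Synthetic-data generator

The generator emulates a two-group repeated-measures cohort:

1. Per-gene log-means M (G × K) and log squared dispersions Φ from
   multivariate normals correlated across cell types; case means are
   M + Δ on the DE mask (⌈de_fraction·G⌉ genes per DE cell type, sampled
   independently per cell type, so masks may overlap), Φ shared.
2. Group panels P ~ Γ(shape 1/exp(Φ), scale exp(M)·exp(Φ)), so the mean is
   exp(M) and the squared coefficient of variation exp(Φ).  The two groups
   share one standard Gamma variate per (gene, cell type), scaled by the
   group mean: marginals are exactly as stated, and the realized
   case/control fold change is exactly exp(Δ) on DE entries and exactly 1
   elsewhere.  The coupling is deliberate — with Δ = 0 the two group panels
   must be identical, otherwise every gene would carry spurious
   between-group differences of the order of the biological CV.
3. Subject panels P_n = P_group ⊙ (1 + s·δ), δ ~ U(ssv_lo, ssv_hi),
   s = ±1 equiprobable, independent per (gene, subject, cell type).  The
   sign symmetry is a documented choice; the band is the subject-to-subject
   variation (SSV) level.
4. Compositions θ ~ Dirichlet(α_group) per sample; expected signal
   λ_ni = P_n θ_ni; observed counts y ~ Poisson(λ).
5. Signature: gene-wise average of all subject panels, ranked by the
   coefficient of variation across the K cell-type columns, top n_markers
   kept (stable order on ties).

Defaults: G = 1000, K = 6, 100 subjects per group, 3 repeats, Δ = 0.5,
10% DE genes in cell types 1–4, SSV ∈ [0, 0.05], 300 markers.

### Hyperparameter stand-ins

The MVN and Dirichlet hyperparameters are package defaults, not values
fitted to a particular dataset; all are overridable from the YAML config:

* μ̄_m = 5.0 (natural log) for every cell type, Σ̂_m with unit variances
  and cross-cell-type correlation 0.8.  Equal grand log-means express that
  cell types do not differ by a systematic whole-transcriptome scale
  factor; what distinguishes them — the marker structure deconvolution
  relies on — is per-gene variation around that common mean, induced by the
  imperfect correlation.  exp(5) ≈ 150 also puts per-gene coverage in a
  realistic bulk RNA-seq range, so the Poisson noise level is meaningful.
* μ̄_φ = log 0.15, Σ̂_φ with sd 0.5 and correlation 0.5: squared biological
  CV centered at 0.15 with moderate cross-cell-type dependence.
* α_ctrl = (12, 10, 8, 6, 3, 1) × 0.8 — a blood-like abundance gradient
  with realistic sampling variability; α_case perturbs each entry by ±10%
  (alternating) for a mild group composition shift.

### What the generator does and does not emulate

It reproduces the count nature, biological and technical noise separation,
longitudinal block structure, group DE and subject-level panel variation of
a real cohort.  It does not model batch effects, library-preparation bias,
gene–gene correlation beyond the cell-type factor structure, cell types
missing from the signature, or intra-subject panel drift over time — so
passing benchmarks here show correctness and the expected qualitative
behavior of the estimator, not performance guarantees on any particular
real dataset.

## Evaluation metrics

With Θ the truth, Θ̂_I the personalized and Θ̂_E the baseline estimate:

* ABD = Σ|Θ̂_I − Θ| − Σ|Θ̂_E − Θ| (negative = improvement);
* rABD = [Avg(|Θ̂_I − Θ|/Θ) − Avg(|Θ̂_E − Θ|/Θ)] × 100, averaging only
  over truth entries > 1e-6 (the ratio is undefined at zero truth; the
  exclusion count is logged);
* CD = corr(Θ̂_I, Θ) − corr(Θ̂_E, Θ), Pearson over the flattened matrix
  (a per-cell-type breakdown is exposed separately);
* Lin's ρ_C = 1 − E[(Θ−Θ̂)²] / E_I[(Θ−Θ̂)²], with the independence
  expectation in closed form σ_x² + σ_y² + (μ_x−μ_y)² (population moments,
  which makes ρ_C identical to the classical 2ρσ_xσ_y/(σ_x²+σ_y²+(μ_x−μ_y)²));
  the Euclidean variant sums per-sample squared distances over the K
  components with the componentwise independence denominator; the
  Aitchison variant applies the Euclidean construction to centered-log-ratio
  transformed compositions after a 1e-6 pseudocount and re-closure, and is
  labeled approximate.

Degenerate inputs (zero variance with equal means) raise an error rather
than returning a conventional value.

## Benchmark problem sizes

The replicated benchmark (`imply.benchmark`, `scripts/acceptance.py`, and
the acceptance tests) uses 25 subjects per group — a quarter of the
generator's default cohort — with 10 replicates, keeping a full run in the
minutes range on one CPU while leaving the per-replicate metrics well clear
of their decision boundaries.  The per-gene mixed-model fits dominate the
runtime.

## Known limitations

* Stage II quality is bounded by Stage I: composition noise enters the
  per-gene regressions as regressor measurement error, attenuating the
  recovered panels.  The benefit of personalization therefore grows with
  marker quality, repeats per subject and subjects per group.
* The random effect variance estimate can shrink to exactly zero for genes
  with little subject heterogeneity, in which case that gene's panel row is
  not personalized.
* Proportions are reported without uncertainty; the three stages run once
  (no alternation between panel recovery and deconvolution).
* Extra covariates are accepted in the metadata but only as fixed-effect
  interactions with the composition columns; none are used by default.
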