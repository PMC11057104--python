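# Full knob list for `imply simulate --config`, shown at the package defaults.
# Omitted keys fall back to these values; matrix/vector hyperparameters left
# null are derived from n_celltypes as documented in docs/methods.md.

n_genes: 1000
n_celltypes: 6
n_subjects_per_group: 100
repeats_per_subject: 3
lfc: 0.5                  # log-fold-change injected on DE entries
de_fraction: 0.10         # fraction of genes DE per listed cell type
de_celltypes: [1, 2, 3, 4]  # 1-based cell-type indices receiving DE genes
ssv_range: [0.0, 0.05]    # subject-to-subject variation band (multiplicative)
n_markers: 300            # top coefficient-of-variation genes kept in the signature
seed: 0

# Hyperparameter stand-ins (override with explicit K-vectors / KxK matrices):
# mvn_mean_logmean: null    # default: 5.0 for every cell type (natural log)
# mvn_cov_logmean: null     # default: unit variances, correlation 0.8
# mvn_mean_logdisp: null    # default: log(0.15)
# mvn_cov_logdisp: null     # default: sd 0.5, correlation 0.5
# alpha_ctrl: null          # default: (12, 10, 8, 6, 3, 1) * 0.8
# alpha_case: null          # default: alpha_ctrl * (1 +/- 0.1 alternating)
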