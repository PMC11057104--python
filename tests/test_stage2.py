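import numpy as np
import pandas as pd
import pytest

from imply import ProportionSet, ValidationError, fit_gene_lmm, run_stage2
from imply.stage2 import LMMDesign, _fit_one, assemble_subject_panel

from conftest import make_bulk


def _balanced_theta(n_subjects, t, K, seed=0, alpha=None):
    rng = np.random.default_rng(seed)
    alpha = alpha if alpha is not None else np.full(K, 4.0)
    samples, rows, subj = [], [], []
    for n in range(n_subjects):
        for i in range(t):
            samples.append(f"sub{n}_r{i}")
            rows.append(rng.dirichlet(alpha))
            subj.append(f"sub{n}")
    theta = ProportionSet(
        pd.DataFrame(rows, index=samples, columns=[f"CT{k}" for k in range(K)]),
        origin="truth",
    )
    subject_of = pd.Series(subj, index=samples)
    return theta, subject_of


def test_noise_free_fixed_effects_recovered_exactly():
    K, N, t = 3, 20, 3
    theta, subject_of = _balanced_theta(N, t, K, seed=1)
    group_of = pd.Series(0, index=subject_of.unique())
    m = np.array([10.0, 5.0, 1.0])
    y = theta.values.to_numpy() @ m
    fit = fit_gene_lmm(y, theta, subject_of, group_of)
    np.testing.assert_allclose(fit.m_hat.to_numpy(), m, atol=1e-6)
    np.testing.assert_allclose(fit.beta_hat.to_numpy(), 0.0, atol=1e-8)
    assert fit.varcomp.max() < 1e-6
    assert fit.fallback == "none"


def test_covariate_interactions_adjust_fixed_effects():
    # a sample-level covariate acting through the compositions is absorbed
    # by the interaction columns, leaving m_hat at the covariate-free truth
    K, N, t = 3, 20, 3
    theta, subject_of = _balanced_theta(N, t, K, seed=3)
    group_of = pd.Series(0, index=subject_of.unique())
    rng = np.random.default_rng(6)
    cov = pd.DataFrame(
        {"age": rng.normal(0.0, 1.0, size=N * t)}, index=theta.sample_ids
    )
    m = np.array([30.0, 12.0, 80.0])
    gamma = np.array([4.0, -2.0, 6.0])
    th = theta.values.to_numpy()
    y = (th * (m + np.outer(cov["age"].to_numpy(), gamma))).sum(axis=1)
    fit = fit_gene_lmm(y, theta, subject_of, group_of, covariates=cov)
    np.testing.assert_allclose(fit.m_hat.to_numpy(), m, atol=1e-5)
    biased = fit_gene_lmm(y, theta, subject_of, group_of)
    assert np.abs(biased.m_hat.to_numpy() - m).max() > 1e-3


def test_single_component_reduces_to_control_grand_mean():
    # theta identically 1 for one cell type: the model collapses to a
    # random-intercept model whose REML control-group mean is the grand mean
    rng = np.random.default_rng(4)
    N, t = 12, 3
    samples = [f"s{n}_{i}" for n in range(N) for i in range(t)]
    theta = ProportionSet(
        pd.DataFrame(np.ones((N * t, 1)), index=samples, columns=["CT0"]),
        origin="truth",
    )
    subject_of = pd.Series(
        [f"sub{n}" for n in range(N) for _ in range(t)], index=samples
    )
    group_of = pd.Series(0, index=subject_of.unique())
    y = rng.normal(50.0, 3.0, size=N * t)
    fit = fit_gene_lmm(y, theta, subject_of, group_of)
    assert abs(fit.m_hat.iloc[0] - y.mean()) < 1e-8


def test_matches_statsmodels_mixedlm_oracle():
    """Cross-check the custom REML solver against statsmodels MixedLM."""
    smf = pytest.importorskip("statsmodels.formula.api")
    rng = np.random.default_rng(11)
    K, N, t = 3, 25, 3
    theta, subject_of = _balanced_theta(N, t, K, seed=2)
    subjects = subject_of.unique()
    group_of = pd.Series([0] * 13 + [1] * 12, index=subjects)
    m = np.array([40.0, 90.0, 20.0])
    beta = np.array([10.0, -15.0, 5.0])
    u = rng.normal(0, 8.0, size=(N, K))
    th = theta.values.to_numpy()
    z = group_of.loc[subject_of].to_numpy()
    idx = pd.Categorical(subject_of, categories=subjects).codes
    y = ((m + beta * z[:, None] + u[idx]) * th).sum(axis=1) + rng.normal(
        0, 2.0, N * t
    )

    fit = fit_gene_lmm(y, theta, subject_of, group_of)

    df = pd.DataFrame(th, columns=[f"th{k}" for k in range(K)])
    for k in range(K):
        df[f"thz{k}"] = th[:, k] * z
    df["y"] = y
    df["subject"] = subject_of.to_numpy()
    fixed = " + ".join([f"th{k}" for k in range(K)] + [f"thz{k}" for k in range(K)])
    vcf = {f"u{k}": f"0 + th{k}" for k in range(K)}
    sm_res = smf.mixedlm(
        f"y ~ 0 + {fixed}", df, groups="subject", vc_formula=vcf, re_formula="0"
    ).fit(reml=True, method="lbfgs", maxiter=500)

    np.testing.assert_allclose(
        fit.m_hat.to_numpy(), sm_res.fe_params.to_numpy()[:K], rtol=2e-3, atol=0.05
    )
    np.testing.assert_allclose(
        fit.beta_hat.to_numpy(), sm_res.fe_params.to_numpy()[K:], rtol=2e-3, atol=0.05
    )
    ours = fit.u_hat.loc[subjects].to_numpy().ravel()
    theirs = np.vstack([sm_res.random_effects[s].to_numpy() for s in subjects]).ravel()
    assert np.corrcoef(ours, theirs)[0, 1] > 0.999


def test_parameter_recovery_is_unbiased():
    """Monte-Carlo over genes: mean estimates within 2 SEs of the truth."""
    rng = np.random.default_rng(21)
    K, N, t, n_genes = 3, 40, 3, 80
    theta, subject_of = _balanced_theta(N, t, K, seed=5)
    subjects = subject_of.unique()
    group_of = pd.Series([0] * 20 + [1] * 20, index=subjects)
    th = theta.values.to_numpy()
    z = group_of.loc[subject_of].to_numpy()
    idx = pd.Categorical(subject_of, categories=subjects).codes
    m = np.array([60.0, 30.0, 100.0])
    beta = np.array([8.0, -6.0, 12.0])
    sigma_u, sigma_e = 10.0, 3.0

    design = LMMDesign(theta, subject_of, group_of)
    m_hats, b_hats, u_corr = [], [], []
    for g in range(n_genes):
        u = rng.normal(0, sigma_u, size=(N, K))
        y = ((m + beta * z[:, None] + u[idx]) * th).sum(axis=1) + rng.normal(
            0, sigma_e, N * t
        )
        fit = _fit_one(design, y)
        m_hats.append(fit.m_hat.to_numpy())
        b_hats.append(fit.beta_hat.to_numpy())
        u_corr.append(np.corrcoef(fit.u_hat.to_numpy().ravel(), u.ravel())[0, 1])

    m_hats, b_hats = np.array(m_hats), np.array(b_hats)
    se_m = m_hats.std(axis=0, ddof=1) / np.sqrt(n_genes)
    se_b = b_hats.std(axis=0, ddof=1) / np.sqrt(n_genes)
    assert (np.abs(m_hats.mean(axis=0) - m) <= 2 * se_m).all()
    assert (np.abs(b_hats.mean(axis=0) - beta) <= 2 * se_b).all()
    # sigma_u dominates sigma_e, so BLUPs track the simulated deviations
    assert np.mean(u_corr) > 0.5


def test_assemble_subject_panel_arithmetic():
    fit_kwargs = dict(
        varcomp=pd.Series([1.0], index=["CT0"]),
        resid_var=1.0,
        converged=True,
    )
    from imply import GeneLMMFit

    fit = GeneLMMFit(
        m_hat=pd.Series([5.0], index=["CT0"]),
        beta_hat=pd.Series([2.0], index=["CT0"]),
        u_hat=pd.DataFrame([[-1.0]], index=["subj"], columns=["CT0"]),
        **fit_kwargs,
    )
    assert assemble_subject_panel(fit, "subj", z=1)[0] == 6.0
    assert assemble_subject_panel(fit, "subj", z=0)[0] == 4.0

    fit2 = GeneLMMFit(
        m_hat=pd.Series([1.0], index=["CT0"]),
        beta_hat=pd.Series([-3.0], index=["CT0"]),
        u_hat=pd.DataFrame([[0.0]], index=["subj"], columns=["CT0"]),
        **fit_kwargs,
    )
    assert assemble_subject_panel(fit2, "subj", z=1)[0] == 0.0  # clipped from -2

    with pytest.raises(ValidationError, match="unknown subject"):
        assemble_subject_panel(fit, "nobody", z=0)


def test_zero_variance_component_zeroes_blups():
    K, N, t = 2, 15, 3
    theta, subject_of = _balanced_theta(N, t, K, seed=7)
    group_of = pd.Series(0, index=subject_of.unique())
    rng = np.random.default_rng(8)
    # no subject heterogeneity at all
    y = theta.values.to_numpy() @ np.array([30.0, 70.0]) + rng.normal(0, 1.0, N * t)
    fit = fit_gene_lmm(y, theta, subject_of, group_of)
    assert (fit.varcomp >= 0).all()
    for k, ct in enumerate(fit.varcomp.index):
        if fit.varcomp[ct] == 0.0:
            assert (fit.u_hat[ct] == 0.0).all()


def test_run_stage2_order_invariance(small_truth):
    bulk = small_truth.bulk.to_cpm()
    theta = small_truth.theta_T
    genes = small_truth.signature.gene_ids[:20]
    fwd = run_stage2(bulk, theta, genes=genes)
    rev = run_stage2(bulk, theta, genes=genes[::-1])
    subj = fwd.subjects[0]
    np.testing.assert_allclose(
        fwd.panels[subj].to_numpy(),
        rev.panels[subj].loc[genes].to_numpy(),
        rtol=1e-12,
    )


def test_identical_subjects_have_vanishing_blups():
    K, N, t = 3, 10, 3
    rng = np.random.default_rng(12)
    samples = [f"s{n}_{i}" for n in range(N) for i in range(t)]
    # every subject sees the same composition sequence and the same response
    base = rng.dirichlet(np.full(K, 5.0), size=t)
    th = np.tile(base, (N, 1))
    theta = ProportionSet(
        pd.DataFrame(th, index=samples, columns=[f"CT{k}" for k in range(K)]),
        origin="truth",
    )
    subject_of = pd.Series([f"sub{n}" for n in range(N) for _ in range(t)], index=samples)
    group_of = pd.Series(0, index=subject_of.unique())
    y = np.tile(base @ np.array([20.0, 50.0, 5.0]), N)
    fit = fit_gene_lmm(y, theta, subject_of, group_of)
    assert np.abs(fit.u_hat.to_numpy()).max() < 1e-3 * y.mean()


def test_blups_shrink_with_cohort_size_under_zero_ssv():
    """Without subject heterogeneity the spurious random-effect magnitude
    decreases as the cohort grows (variance components shrink to zero more
    reliably)."""
    import imply

    def mean_abs_u(n_per_group, seed):
        cfg = imply.SimulationConfig(
            n_genes=200, n_markers=80, ssv_range=(0.0, 0.0),
            n_subjects_per_group=n_per_group, seed=seed,
        )
        tr = imply.simulate(cfg)
        panels = run_stage2(
            tr.bulk.to_cpm(), tr.theta_T, genes=tr.signature.gene_ids
        )
        u = np.concatenate(
            [f.u_hat.to_numpy().ravel() for f in panels.fits.values()]
        )
        return np.abs(u).mean()

    levels = [
        np.mean([mean_abs_u(n, s) for s in (1, 2)]) for n in (5, 12, 25)
    ]
    assert levels[0] > levels[1] > levels[2]


def test_control_subject_panel_is_m_plus_u(small_truth):
    bulk = small_truth.bulk.to_cpm()
    genes = small_truth.signature.gene_ids[:10]
    panels = run_stage2(bulk, small_truth.theta_T, genes=genes)
    ctrl = [s for s in panels.subjects if bulk.group_of[s] == 0][0]
    for g in genes:
        fit = panels.fits[g]
        expected = np.clip(
            fit.m_hat.to_numpy() + fit.u_hat.loc[ctrl].to_numpy(), 0, None
        )
        np.testing.assert_allclose(
            panels.panels[ctrl].loc[g].to_numpy(), expected, atol=1e-10
        )


def test_single_sample_subject_rejected(small_truth):
    bulk = small_truth.bulk
    drop = bulk.samples_of(bulk.subjects[0])[1:]
    expr = bulk.expression.drop(columns=drop)
    meta = bulk.metadata.drop(index=drop)
    from imply import BulkExperiment

    crippled = BulkExperiment(expr, meta)
    theta = ProportionSet(
        small_truth.theta_T.values.loc[expr.columns], origin="truth"
    )
    with pytest.raises(ValidationError, match="repeated measures"):
        run_stage2(crippled, theta, genes=bulk.gene_ids[:5])
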