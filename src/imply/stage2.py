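"""Stage II: personalized reference-panel recovery via per-gene mixed models.

For each gene the expected bulk expression of sample ``i`` from subject ``n``
is modeled as

    E(y_ni) = sum_k (m_k + beta_k * z_n + u_nk) * theta_nik

where ``theta_nik`` are the Stage I composition estimates, ``z_n`` the binary
group label, ``m_k``/``beta_k`` fixed cell-type effects and ``u_nk`` a
subject-level random slope with diagonal covariance (one variance per cell
type, no cross-cell-type correlation, no random intercept and no fixed
intercept: the mean runs entirely through the compositions).

Estimation is restricted maximum likelihood.  Because the design (theta, z,
subject grouping) is identical for every gene, the REML criterion is
implemented directly on the per-subject block structure: each subject
contributes a small t_n x t_n marginal covariance block
``V_n = I + Z_n diag(gamma) Z_n'`` (gamma = variance ratios to the residual),
and the profiled criterion is minimized over gamma >= 0 with L-BFGS-B.
Subjects with equal t_n are processed as one batched einsum, which makes the
per-gene fit cheap enough to run genome-wide.  The subject deviations u_nk
are recovered as BLUPs, ``u_n = diag(gamma) Z_n' V_n^{-1} (y_n - X_n b)``.

The personalized panel entry for subject ``n``, cell type ``k`` is then
``r_nk = m_k + z_n * beta_k + u_nk``, clipped at zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .types import (
    BulkExperiment,
    GeneLMMFit,
    PersonalizedPanelSet,
    ProportionSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["LMMDesign", "fit_gene_lmm", "assemble_subject_panel", "run_stage2"]

_REML_TOL = 1e-8
_MAX_ITER = 200


class LMMDesign:
    """Pre-computed design shared by all per-gene fits.

    Splits the samples into per-subject blocks (batched by the number of
    repeats t_n) and builds the fixed-effect matrix ``[theta | theta * z]``
    with exactly-zero columns dropped.
    """

    def __init__(
        self,
        theta: ProportionSet,
        subject_of: pd.Series,
        group_of: pd.Series,
        covariates: pd.DataFrame | None = None,
    ):
        self.sample_ids = theta.sample_ids
        self.cell_types = theta.cell_types
        K = len(self.cell_types)

        subj = subject_of.loc[self.sample_ids]
        self.subjects = pd.Index(subj.unique())
        self.z_subject = group_of.loc[self.subjects].to_numpy(dtype=float)

        th = theta.values.to_numpy()
        z_sample = group_of.loc[subj].to_numpy(dtype=float)

        # active cell types: theta not identically zero
        self.active = th.any(axis=0)
        if not self.active.all():
            logger.info(
                "stage2: dropping cell type(s) with all-zero proportions: %s",
                list(self.cell_types[~self.active]),
            )
        tha = th[:, self.active]
        self.K_active = tha.shape[1]

        X_main = tha
        X_int = tha * z_sample[:, None]
        self.has_interaction = bool(X_int.any())
        blocks = [X_main] + ([X_int] if self.has_interaction else [])
        # optional extra covariates enter as interactions with the
        # composition columns (their main effects would be confounded with
        # the sum-to-one rows, like an intercept)
        self.n_covariates = 0
        if covariates is not None:
            cov = covariates.loc[self.sample_ids].to_numpy(dtype=float)
            self.n_covariates = cov.shape[1]
            for j in range(self.n_covariates):
                blocks.append(tha * cov[:, j][:, None])
        X = np.hstack(blocks)
        self.p = X.shape[1]

        # order samples by subject, keep permutation for block reshaping
        codes = pd.Categorical(subj, categories=self.subjects).codes
        order = np.argsort(codes, kind="stable")
        self._order = order
        self.n_obs = len(order)
        if self.n_obs <= self.p:
            raise ValidationError(
                f"mixed model needs more samples ({self.n_obs}) than fixed-effect "
                f"coefficients ({self.p})"
            )

        t_n = np.bincount(codes, minlength=len(self.subjects))
        self.t_n = t_n
        X_ord, Z_ord = X[order], tha[order]
        codes_ord = codes[order]

        # batch subjects sharing the same number of repeats
        self.batches = []  # (subject_rows, Xb (S,t,p), Zb (S,t,K_active), obs_slices)
        starts = np.r_[0, np.cumsum(t_n)]
        for t in np.unique(t_n):
            idx = np.flatnonzero(t_n == t)
            rows = np.concatenate([np.arange(starts[i], starts[i] + t) for i in idx])
            S = len(idx)
            self.batches.append(
                (
                    idx,
                    X_ord[rows].reshape(S, t, self.p),
                    Z_ord[rows].reshape(S, t, self.K_active),
                    rows,
                )
            )
        self._codes_ord = codes_ord

        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < self.p:
            raise ValidationError(
                "singular fixed-effect design even after dropping all-zero "
                "cell-type columns"
            )

    def order_response(self, y: np.ndarray) -> list[np.ndarray]:
        """Per-batch (S, t) response blocks in subject order."""
        y_ord = np.asarray(y, dtype=float)[self._order]
        return [y_ord[rows].reshape(Xb.shape[0], Xb.shape[1]) for _, Xb, _, rows in self.batches]


def _reml_neg2(gamma, design: LMMDesign, yb_list):
    """Profiled -2 REML log-likelihood (up to an additive constant)."""
    logdetV = 0.0
    XtVX = np.zeros((design.p, design.p))
    XtVy = np.zeros(design.p)
    ytVy = 0.0
    for (idx, Xb, Zb, _), yb in zip(design.batches, yb_list):
        t = Xb.shape[1]
        V = np.eye(t)[None] + np.einsum("ntk,k,nsk->nts", Zb, gamma, Zb)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdetV += 2.0 * np.log(np.einsum("nii->ni", L)).sum()
        Xs = np.linalg.solve(V, Xb)
        ys = np.linalg.solve(V, yb[..., None])[..., 0]
        XtVX += np.einsum("ntp,ntq->pq", Xb, Xs)
        XtVy += np.einsum("ntp,nt->p", Xb, ys)
        ytVy += float(np.einsum("nt,nt->", yb, ys))
    try:
        cf = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return np.inf
    b = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - XtVy @ b
    dof = design.n_obs - design.p
    if rss <= 0:
        rss = np.finfo(float).tiny
    return dof * np.log(rss / dof) + logdetV + 2.0 * np.log(np.diag(cf)).sum()


def _solve_given_gamma(gamma, design: LMMDesign, yb_list):
    """Fixed effects, BLUPs and residual variance at a fixed gamma."""
    XtVX = np.zeros((design.p, design.p))
    XtVy = np.zeros(design.p)
    ytVy = 0.0
    for (idx, Xb, Zb, _), yb in zip(design.batches, yb_list):
        t = Xb.shape[1]
        V = np.eye(t)[None] + np.einsum("ntk,k,nsk->nts", Zb, gamma, Zb)
        Xs = np.linalg.solve(V, Xb)
        ys = np.linalg.solve(V, yb[..., None])[..., 0]
        XtVX += np.einsum("ntp,ntq->pq", Xb, Xs)
        XtVy += np.einsum("ntp,nt->p", Xb, ys)
        ytVy += float(np.einsum("nt,nt->", yb, ys))
    b = np.linalg.solve(XtVX, XtVy)

    u = np.zeros((len(design.subjects), design.K_active))
    rss = 0.0
    for (idx, Xb, Zb, _), yb in zip(design.batches, yb_list):
        t = Xb.shape[1]
        V = np.eye(t)[None] + np.einsum("ntk,k,nsk->nts", Zb, gamma, Zb)
        rb = yb - np.einsum("ntp,p->nt", Xb, b)
        rs = np.linalg.solve(V, rb[..., None])[..., 0]
        u[idx] = gamma * np.einsum("ntk,nt->nk", Zb, rs)
        rss += float(np.einsum("nt,nt->", rb, rs))
    s2 = rss / (design.n_obs - design.p)
    return b, u, max(s2, 0.0)


def _ols_fallback(design: LMMDesign, yb_list):
    X = np.vstack([Xb.reshape(-1, design.p) for _, Xb, _, _ in design.batches])
    y = np.concatenate([yb.ravel() for yb in yb_list])
    b, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    s2 = float(resid @ resid) / max(design.n_obs - design.p, 1)
    return b, np.zeros((len(design.subjects), design.K_active)), s2


def _pack_fit(design: LMMDesign, b, u, gamma, s2, converged, fallback) -> GeneLMMFit:
    K = len(design.cell_types)
    m = np.zeros(K)
    beta = np.zeros(K)
    m[design.active] = b[: design.K_active]
    if design.has_interaction:
        beta[design.active] = b[design.K_active: 2 * design.K_active]
    # any trailing coefficients are covariate-interaction nuisance terms
    u_full = np.zeros((len(design.subjects), K))
    u_full[:, design.active] = u
    vc = np.zeros(K)
    vc[design.active] = s2 * gamma
    # an exactly-zero variance component forces its BLUP column to zero
    u_full[:, vc == 0.0] = 0.0
    return GeneLMMFit(
        m_hat=pd.Series(m, index=design.cell_types),
        beta_hat=pd.Series(beta, index=design.cell_types),
        u_hat=pd.DataFrame(u_full, index=design.subjects, columns=design.cell_types),
        varcomp=pd.Series(vc, index=design.cell_types),
        resid_var=float(s2),
        converged=converged,
        fallback=fallback,
    )


def _fit_one(design: LMMDesign, y: np.ndarray) -> GeneLMMFit:
    yb_list = design.order_response(y)
    try:
        res = minimize(
            _reml_neg2,
            x0=np.ones(design.K_active),
            args=(design, yb_list),
            method="L-BFGS-B",
            bounds=[(0.0, 1e9)] * design.K_active,
            options={"maxiter": _MAX_ITER, "ftol": _REML_TOL, "gtol": 1e-6},
        )
        ok = np.isfinite(res.fun)
    except (np.linalg.LinAlgError, ValueError):
        ok = False
    if not ok:
        b, u, s2 = _ols_fallback(design, yb_list)
        return _pack_fit(
            design, b, u, np.zeros(design.K_active), s2, False, "fixed_only"
        )
    gamma = np.clip(res.x, 0.0, None)
    gamma[gamma < 1e-10] = 0.0  # boundary estimates snap to exact zero
    b, u, s2 = _solve_given_gamma(gamma, design, yb_list)
    return _pack_fit(design, b, u, gamma, s2, bool(res.success), "none")


def fit_gene_lmm(
    y_g: np.ndarray,
    theta: ProportionSet,
    subject_of: pd.Series,
    group_of: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> GeneLMMFit:
    """REML fit of one gene's expression on the Stage I compositions.

    Parameters
    ----------
    y_g
        Expression of the gene across the samples of ``theta`` (same order).
    theta
        Per-sample compositions (Stage I output, or the truth when testing).
    subject_of
        Sample id -> subject id.
    group_of
        Subject id -> group label in {0, 1}.
    covariates
        Optional numeric sample-level covariates (one row per sample); each
        enters as interactions with the composition columns.
    """
    design = LMMDesign(theta, subject_of, group_of, covariates)
    return _fit_one(design, np.asarray(y_g, dtype=float))


def assemble_subject_panel(fit: GeneLMMFit, subject, z: int) -> np.ndarray:
    """Panel row ``m_hat + z * beta_hat + u_hat[subject]``, clipped at zero."""
    if subject not in fit.u_hat.index:
        raise ValidationError(f"unknown subject {subject!r}")
    raw = (
        fit.m_hat.to_numpy()
        + float(z) * fit.beta_hat.to_numpy()
        + fit.u_hat.loc[subject].to_numpy()
    )
    return np.clip(raw, 0.0, None)


def run_stage2(
    bulk: BulkExperiment,
    theta: ProportionSet,
    genes=None,
    covariates: pd.DataFrame | None = None,
) -> PersonalizedPanelSet:
    """Fit the per-gene mixed model for every requested gene and assemble panels.

    ``genes`` defaults to every gene in ``bulk``; passing the signature's
    marker genes restricts the panels to the Stage III feature space.
    """
    bulk.require_repeated_measures()
    if genes is None:
        genes = bulk.gene_ids
    genes = pd.Index(genes)
    missing = genes.difference(bulk.gene_ids)
    if len(missing):
        raise ValidationError(f"genes absent from bulk: {missing.tolist()[:5]}")
    if not theta.sample_ids.equals(bulk.sample_ids):
        theta = ProportionSet(theta.values.loc[bulk.sample_ids], origin=theta.origin)

    design = LMMDesign(theta, bulk.subject_of, bulk.group_of, covariates)
    Y = bulk.expression.loc[genes].to_numpy()

    fits: dict = {}
    n_fallback = 0
    for j, gene in enumerate(genes):
        fit = _fit_one(design, Y[j])
        fits[gene] = fit
        n_fallback += fit.fallback != "none"
    logger.info(
        "stage2: fitted %d genes (%d OLS fallbacks)", len(genes), n_fallback
    )

    z_of = bulk.group_of
    panels = {}
    for subject in design.subjects:
        z = int(z_of.loc[subject])
        mat = np.vstack(
            [assemble_subject_panel(fits[g], subject, z) for g in genes]
        )
        panels[subject] = pd.DataFrame(mat, index=genes, columns=design.cell_types)
    return PersonalizedPanelSet(
        panels=panels, gene_ids=genes, cell_types=design.cell_types, fits=fits
    )
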