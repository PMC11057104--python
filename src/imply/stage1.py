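"""Stage I: coarse deconvolution against the population signature matrix.

Each bulk sample ``y`` (restricted to the marker genes shared with the
signature ``E``) is regressed on the cell-type columns of ``E`` with a linear
nu-support-vector regression, ``y = E theta + b``.  A small grid of nu values
is searched and the fit minimizing the root-mean-square reconstruction error
is kept.  Negative coefficients are truncated to zero and the remainder is
normalized to the unit simplex.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .types import (
    BulkExperiment,
    ProportionSet,
    SignatureMatrix,
    SVRConfig,
    ValidationError,
    warn_degenerate,
)

logger = logging.getLogger(__name__)

__all__ = ["deconvolve_sample_svr", "truncate_and_normalize", "run_stage1"]


def deconvolve_sample_svr(
    y: np.ndarray, E: np.ndarray, cfg: SVRConfig | None = None
) -> np.ndarray:
    """Raw (pre-truncation) nu-SVR coefficients of one sample on E's columns.

    Parameters
    ----------
    y
        Expression of the shared marker genes in one sample, length J.
    E
        Signature values restricted to the same J genes, shape (J, K).
    cfg
        Grid and penalty settings; defaults to :class:`SVRConfig`.

    Returns
    -------
    Coefficient vector of length K on the original expression scale.  May
    contain negative entries; see :func:`truncate_and_normalize`.
    """
    cfg = cfg or SVRConfig()
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    J, K = E.shape
    if y.shape != (J,):
        raise ValidationError(f"sample vector has length {y.shape}, expected {J}")
    if J < K:
        raise ValidationError(f"need >= {K} shared marker genes, got {J}")
    sd_y = y.std()
    if sd_y == 0:
        raise ValidationError("sample has zero variance across marker genes")

    if cfg.standardize:
        mu_y, mu_E = y.mean(), E.mean(axis=0)
        sd_E = E.std(axis=0)
        sd_E[sd_E == 0] = 1.0
        ys = (y - mu_y) / sd_y
        Es = (E - mu_E) / sd_E
    else:
        ys, Es = y, E

    best = None
    for nu in sorted(cfg.nu_grid):
        svr = NuSVR(kernel="linear", nu=nu, C=cfg.penalty_c, tol=1e-6)
        svr.fit(Es, ys)
        w = svr.coef_.ravel()
        if cfg.standardize:
            coef = sd_y * w / sd_E
            intercept = mu_y + sd_y * float(svr.intercept_[0]) - coef @ mu_E
        else:
            coef = w
            intercept = float(svr.intercept_[0])
        rmse = np.sqrt(np.mean((y - (E @ coef + intercept)) ** 2))
        if best is None or rmse < best[0]:  # strict: smallest nu wins ties
            best = (rmse, coef)
    return best[1]


def truncate_and_normalize(raw: np.ndarray) -> np.ndarray:
    """Clip negative coefficients to zero and renormalize to sum one.

    If every coefficient is non-positive the uniform composition is returned
    and a warning is emitted.
    """
    raw = np.asarray(raw, dtype=float)
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0:
        warn_degenerate(
            "all deconvolution coefficients non-positive; returning uniform composition"
        )
        return np.full(raw.shape, 1.0 / raw.size)
    return clipped / total


def _shared_genes(bulk: BulkExperiment, E: SignatureMatrix) -> pd.Index:
    shared = E.gene_ids.intersection(bulk.gene_ids)
    n_lost = E.n_genes - len(shared)
    logger.info(
        "stage1: %d/%d signature genes found in bulk", len(shared), E.n_genes
    )
    if n_lost > 0.5 * E.n_genes:
        warn_degenerate(
            f"more than half of the signature genes ({n_lost}/{E.n_genes}) "
            "are absent from the bulk matrix"
        )
    if len(shared) < E.n_cell_types:
        raise ValidationError(
            f"only {len(shared)} marker genes shared between bulk and signature; "
            f"need at least K={E.n_cell_types}"
        )
    return shared


def run_stage1(
    bulk: BulkExperiment, E: SignatureMatrix, cfg: SVRConfig | None = None
) -> ProportionSet:
    """Deconvolve every sample of ``bulk`` against the population panel ``E``."""
    cfg = cfg or SVRConfig()
    shared = _shared_genes(bulk, E)
    Emat = E.values.loc[shared].to_numpy()
    Y = bulk.expression.loc[shared].to_numpy()

    out = np.empty((bulk.n_samples, E.n_cell_types))
    for i in range(bulk.n_samples):
        raw = deconvolve_sample_svr(Y[:, i], Emat, cfg)
        out[i] = truncate_and_normalize(raw)
    values = pd.DataFrame(out, index=bulk.sample_ids, columns=E.cell_types)
    logger.info("stage1: deconvolved %d samples x %d cell types", *values.shape)
    return ProportionSet(values, origin="stage1")
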