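"""Stage III: personalized deconvolution with the recovered panels.

For each subject the repeated samples are deconvolved against that subject's
personalized panel R_n.  The joint objective

    || (R_n kron I_tn) vec(Theta') - vec(y') ||_2 ,   Theta >= 0

couples no coefficients across repeats, so it is solved as independent
per-sample non-negative least squares; the equivalence with the vectorized
Kronecker system is exercised in the test suite.  A per-sample nu-SVR route
(the "imply-s" variant) reuses the Stage I machinery with R_n in place of the
population signature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stage1 import deconvolve_sample_svr, truncate_and_normalize
from .types import (
    BulkExperiment,
    PersonalizedPanelSet,
    ProportionSet,
    Stage3Config,
    SVRConfig,
    ValidationError,
    warn_degenerate,
)

logger = logging.getLogger(__name__)

__all__ = ["deconvolve_subject_nnls", "run_stage3"]


def deconvolve_subject_nnls(y_n: np.ndarray, R_n: np.ndarray) -> np.ndarray:
    """Non-negative least-squares abundances for all repeats of one subject.

    Parameters
    ----------
    y_n
        Expression matrix (genes x repeats) of the subject's samples.
    R_n
        Personalized panel (genes x cell types), same gene order.

    Returns
    -------
    Abundance matrix of shape (cell types, repeats), entrywise >= 0 and on
    the raw (un-normalized) scale.
    """
    y_n = np.atleast_2d(np.asarray(y_n, dtype=float))
    if y_n.ndim == 2 and y_n.shape[0] == 1 and R_n.shape[0] != 1:
        y_n = y_n.T
    R_n = np.asarray(R_n, dtype=float)
    if y_n.shape[0] != R_n.shape[0]:
        raise ValidationError(
            f"gene dimension mismatch: y has {y_n.shape[0]}, panel has {R_n.shape[0]}"
        )
    K = R_n.shape[1]
    zero_cols = ~R_n.any(axis=0)
    if zero_cols.any():
        warn_degenerate(
            f"panel column(s) {np.flatnonzero(zero_cols).tolist()} are all zero; "
            "their abundances are fixed at 0"
        )
    active = ~zero_cols
    out = np.zeros((K, y_n.shape[1]))
    for i in range(y_n.shape[1]):
        out[active, i], _ = nnls(R_n[:, active], y_n[:, i])
    return out


def run_stage3(
    bulk: BulkExperiment,
    panels: PersonalizedPanelSet,
    cfg: Stage3Config | None = None,
    svr_cfg: SVRConfig | None = None,
) -> ProportionSet:
    """Deconvolve every subject's samples against their personalized panel."""
    cfg = cfg or Stage3Config()
    genes = pd.Index(panels.gene_ids)
    missing = genes.difference(bulk.gene_ids)
    if len(missing):
        raise ValidationError(f"panel genes absent from bulk: {missing.tolist()[:5]}")

    rows = {}
    for subject in bulk.subjects:
        if subject not in panels.panels:
            raise ValidationError(f"no personalized panel for subject {subject!r}")
        samples = bulk.samples_of(subject)
        R = panels.panels[subject].to_numpy()
        Y = bulk.expression.loc[genes, samples].to_numpy()
        if cfg.solver == "nnls":
            theta = deconvolve_subject_nnls(Y, R)  # (K, t_n)
            for i, sid in enumerate(samples):
                rows[sid] = theta[:, i]
        else:  # per-sample nu-SVR, the imply-s variant
            for i, sid in enumerate(samples):
                raw = deconvolve_sample_svr(Y[:, i], R, svr_cfg or SVRConfig())
                rows[sid] = np.clip(raw, 0.0, None)

    out = np.vstack([rows[sid] for sid in bulk.sample_ids])
    if cfg.normalize_output:
        sums = out.sum(axis=1)
        zero = sums <= 0
        if zero.any():
            warn_degenerate(
                f"{int(zero.sum())} sample(s) deconvolved to all-zero abundances; "
                "replaced by the uniform composition"
            )
            out[zero] = 1.0 / out.shape[1]
            sums[zero] = 1.0
        out = out / sums[:, None]
    values = pd.DataFrame(out, index=bulk.sample_ids, columns=panels.cell_types)
    logger.info(
        "stage3 (%s): deconvolved %d samples x %d cell types",
        cfg.solver,
        *values.shape,
    )
    return ProportionSet(values, origin="stage3", normalized=cfg.normalize_output)
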