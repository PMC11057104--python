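"""Compositional evaluation metrics for deconvolution benchmarking.

All metrics compare a candidate estimate ``Theta_I`` (e.g. the personalized
Stage III output) and a baseline estimate ``Theta_E`` (e.g. the Stage I
population-reference output) against the ground-truth compositions
``Theta_T``:

* ``abd`` — absolute bias difference, sum|Theta_I - Theta| - sum|Theta_E - Theta|
  (negative = the candidate reduces total absolute error);
* ``rabd`` — the same on mean relative absolute errors, in percentage points;
* ``cd`` — difference of Pearson correlations with the truth over the
  flattened matrices (positive = candidate more concordant);
* Lin's concordance correlation coefficient rho_C = 1 - E[(x-y)^2] /
  E_I[(x-y)^2], where E_I is the expected squared difference if x and y were
  independent (sigma_x^2 + sigma_y^2 + (mu_x - mu_y)^2), together with a
  per-sample Euclidean-distance variant and an approximate Aitchison
  (centered-log-ratio) variant for compositions.

Population moments (ddof=0) are used throughout, which makes rho_C equal to
the classical Lin closed form 2*cov / (var_x + var_y + (mu_x - mu_y)^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import ProportionSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "abd",
    "rabd",
    "cd",
    "lin_ccc",
    "lin_ccc_euclidean",
    "lin_ccc_aitchison",
    "evaluate_pair",
]

_RABD_TRUTH_FLOOR = 1e-6
_AITCHISON_PSEUDOCOUNT = 1e-6


def _as_array(x) -> np.ndarray:
    if isinstance(x, ProportionSet):
        return x.values.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def _aligned(*args) -> list[np.ndarray]:
    arrays = [_as_array(a) for a in args]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValidationError(f"shape mismatch between proportion sets: {shapes}")
    return arrays


def abd(theta_I, theta_E, theta_T) -> float:
    """Absolute bias difference; negative means the candidate improves."""
    I, E, T = _aligned(theta_I, theta_E, theta_T)
    return float(np.abs(I - T).sum() - np.abs(E - T).sum())


def rabd(theta_I, theta_E, theta_T) -> float:
    """Relative absolute bias difference in percentage points.

    Truth entries at or below 1e-6 are excluded from the relative-error
    average (the ratio is undefined at zero truth); the exclusion count is
    logged.
    """
    I, E, T = _aligned(theta_I, theta_E, theta_T)
    keep = T > _RABD_TRUTH_FLOOR
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rabd: excluded %d near-zero truth entries", n_dropped)
    if not keep.any():
        raise ValidationError("all truth entries are zero; rABD undefined")
    rel_I = np.abs(I - T)[keep] / T[keep]
    rel_E = np.abs(E - T)[keep] / T[keep]
    return float((rel_I.mean() - rel_E.mean()) * 100.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x, y = x.ravel(), y.ravel()
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValidationError("zero-variance input; correlation undefined")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def cd(theta_I, theta_E, theta_T) -> float:
    """Correlation difference over flattened entries; positive = improvement."""
    I, E, T = _aligned(theta_I, theta_E, theta_T)
    return _pearson(I, T) - _pearson(E, T)


def cd_per_celltype(theta_I, theta_E, theta_T) -> np.ndarray:
    """Column-wise correlation differences (one value per cell type)."""
    I, E, T = _aligned(theta_I, theta_E, theta_T)
    return np.array(
        [_pearson(I[:, k], T[:, k]) - _pearson(E[:, k], T[:, k]) for k in range(T.shape[1])]
    )


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient over flattened entries."""
    X, Y = _aligned(x, y)
    X, Y = X.ravel(), Y.ravel()
    vx, vy = X.var(), Y.var()
    denom = vx + vy + (X.mean() - Y.mean()) ** 2
    if denom == 0:
        raise ValidationError("degenerate inputs: zero variance and equal means")
    num = np.mean((X - Y) ** 2)
    return float(1.0 - num / denom)


def lin_ccc_euclidean(x, y) -> float:
    """Euclidean-distance variant: per-sample squared distances over K components.

    The independence denominator sums the componentwise closed form
    sigma_xk^2 + sigma_yk^2 + (mu_xk - mu_yk)^2 over cell types.
    """
    X, Y = _aligned(x, y)
    denom = float(
        (X.var(axis=0) + Y.var(axis=0) + (X.mean(axis=0) - Y.mean(axis=0)) ** 2).sum()
    )
    if denom == 0:
        raise ValidationError("degenerate inputs: zero variance and equal means")
    num = float(((X - Y) ** 2).sum(axis=1).mean())
    return 1.0 - num / denom


def _clr(comp: np.ndarray) -> np.ndarray:
    comp = comp + _AITCHISON_PSEUDOCOUNT
    comp = comp / comp.sum(axis=1, keepdims=True)
    logc = np.log(comp)
    return logc - logc.mean(axis=1, keepdims=True)


def lin_ccc_aitchison(x, y) -> float:
    """Approximate Aitchison-distance concordance.

    Compositions receive a 1e-6 pseudocount, are re-closed, and mapped by the
    centered log-ratio transform; the Euclidean concordance construction is
    then applied in clr space (squared Euclidean distance of clr vectors is
    the squared Aitchison distance).
    """
    X, Y = _aligned(x, y)
    return lin_ccc_euclidean(_clr(X), _clr(Y))


@dataclass
class MetricReport:
    """All pairwise benchmarking metrics for one (candidate, baseline, truth)."""

    abd: float
    rabd_percent: float
    cd: float
    ccc_imply: float
    ccc_baseline: float
    ccc_e_imply: float
    ccc_e_baseline: float
    delta_ccc: float
    delta_ccc_e: float
    delta_ccc_e_percent: float
    ccc_aitchison_imply: float | None = None
    ccc_aitchison_baseline: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def evaluate_pair(theta_I, theta_E, theta_T, aitchison: bool = True) -> MetricReport:
    """Full metric panel for a candidate/baseline pair against the truth."""
    ccc_i = lin_ccc(theta_T, theta_I)
    ccc_e = lin_ccc(theta_T, theta_E)
    ccc_e_i = lin_ccc_euclidean(theta_T, theta_I)
    ccc_e_e = lin_ccc_euclidean(theta_T, theta_E)
    delta_e = ccc_e_i - ccc_e_e
    return MetricReport(
        abd=abd(theta_I, theta_E, theta_T),
        rabd_percent=rabd(theta_I, theta_E, theta_T),
        cd=cd(theta_I, theta_E, theta_T),
        ccc_imply=ccc_i,
        ccc_baseline=ccc_e,
        ccc_e_imply=ccc_e_i,
        ccc_e_baseline=ccc_e_e,
        delta_ccc=ccc_i - ccc_e,
        delta_ccc_e=delta_e,
        delta_ccc_e_percent=delta_e / ccc_e_e * 100.0 if ccc_e_e != 0 else np.nan,
        ccc_aitchison_imply=lin_ccc_aitchison(theta_T, theta_I) if aitchison else None,
        ccc_aitchison_baseline=lin_ccc_aitchison(theta_T, theta_E) if aitchison else None,
    )
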