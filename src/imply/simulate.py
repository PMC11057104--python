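"""Synthetic longitudinal bulk RNA-seq with full ground truth.

The generative chain mimics a two-group repeated-measures cohort:

1.  Per-gene log mean expression ``M`` and log squared biological
    dispersion ``Phi`` are drawn from multivariate normals correlated across
    the K cell types.  Case means are ``M + Delta`` on a random subset of
    genes (the differential-expression mask) in a configurable set of cell
    types; both groups share ``Phi``.
2.  Pure cell-type-specific expression panels are Gamma draws with
    shape ``1/exp(Phi)`` and scale ``exp(M) * exp(Phi)``, so the panel mean
    is ``exp(M)`` and its squared coefficient of variation is ``exp(Phi)``.
3.  Subject panels perturb the group panel multiplicatively by a signed
    uniform percentage (subject-to-subject variation, SSV), independently
    per (gene, subject, cell type).
4.  Sample compositions are Dirichlet draws (group-specific alpha); the
    expected bulk signal is ``lambda_ni = P_n theta_ni`` and observed counts
    are Poisson around it.
5.  The input signature matrix averages all subject panels and keeps the
    top ``n_markers`` genes by coefficient of variation across cell types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import BulkExperiment, ProportionSet, SignatureMatrix, ValidationError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "draw_cts_parameters",
    "draw_expression_panels",
    "draw_proportions_and_counts",
    "build_signature",
    "simulate",
]


def _corr_cov(sd: np.ndarray, rho: float) -> np.ndarray:
    K = len(sd)
    C = np.full((K, K), rho)
    np.fill_diagonal(C, 1.0)
    return C * np.outer(sd, sd)


def _default_alpha(K: int) -> np.ndarray:
    if K == 6:
        base = np.array([12.0, 10.0, 8.0, 6.0, 3.0, 1.0])
    else:
        base = np.linspace(12.0, 1.0, K)
    return base * 0.8


@dataclass
class SimulationConfig:
    """All knobs of the generative chain, with cohort-style defaults.

    The MVN and Dirichlet hyperparameters are package defaults chosen to
    produce realistic immune-cell-like panels (log-means spread over [2, 6],
    strong cross-cell-type correlation, squared CV near 0.15); they are
    stand-ins, not values fitted to any particular dataset, and every field
    is overridable (e.g. from the YAML config of ``imply simulate``).
    """

    n_genes: int = 1000
    n_celltypes: int = 6
    n_subjects_per_group: int = 100
    repeats_per_subject: int = 3
    lfc: float = 0.5
    de_fraction: float = 0.10
    de_celltypes: tuple = (1, 2, 3, 4)  # 1-based cell-type indices
    ssv_range: tuple = (0.0, 0.05)
    mvn_mean_logmean: np.ndarray | None = None
    mvn_cov_logmean: np.ndarray | None = None
    mvn_mean_logdisp: np.ndarray | None = None
    mvn_cov_logdisp: np.ndarray | None = None
    alpha_ctrl: np.ndarray | None = None
    alpha_case: np.ndarray | None = None
    n_markers: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        K = self.n_celltypes
        if self.mvn_mean_logmean is None:
            # equal grand log-means across cell types: cell types differ per
            # gene (through the imperfect cross-cell-type correlation), not by
            # a systematic whole-transcriptome scale factor
            self.mvn_mean_logmean = np.full(K, 5.0)
        if self.mvn_cov_logmean is None:
            self.mvn_cov_logmean = _corr_cov(np.full(K, 1.0), 0.8)
        if self.mvn_mean_logdisp is None:
            self.mvn_mean_logdisp = np.full(K, math.log(0.15))
        if self.mvn_cov_logdisp is None:
            self.mvn_cov_logdisp = _corr_cov(np.full(K, 0.5), 0.5)
        if self.alpha_ctrl is None:
            self.alpha_ctrl = _default_alpha(K)
        if self.alpha_case is None:
            # mild composition shift between groups: +/-10 % alternating
            signs = np.where(np.arange(K) % 2 == 0, 1.0, -1.0)
            self.alpha_case = np.asarray(self.alpha_ctrl) * (1.0 + 0.1 * signs)
        self.mvn_mean_logmean = np.asarray(self.mvn_mean_logmean, dtype=float)
        self.mvn_cov_logmean = np.asarray(self.mvn_cov_logmean, dtype=float)
        self.mvn_mean_logdisp = np.asarray(self.mvn_mean_logdisp, dtype=float)
        self.mvn_cov_logdisp = np.asarray(self.mvn_cov_logdisp, dtype=float)
        self.alpha_ctrl = np.asarray(self.alpha_ctrl, dtype=float)
        self.alpha_case = np.asarray(self.alpha_case, dtype=float)

        for name, cov in (
            ("mvn_cov_logmean", self.mvn_cov_logmean),
            ("mvn_cov_logdisp", self.mvn_cov_logdisp),
        ):
            if cov.shape != (K, K) or not np.allclose(cov, cov.T):
                raise ValidationError(f"{name} must be a symmetric {K}x{K} matrix")
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValidationError(f"{name} is not positive semi-definite")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValidationError("de_fraction must lie in [0, 1]")
        lo, hi = self.ssv_range
        if not (0.0 <= lo <= hi):
            raise ValidationError("ssv_range must satisfy 0 <= lo <= hi")
        if (self.alpha_ctrl <= 0).any() or (self.alpha_case <= 0).any():
            raise ValidationError("Dirichlet alpha entries must be positive")
        if any(not (1 <= c <= K) for c in self.de_celltypes):
            raise ValidationError(f"de_celltypes must be 1-based indices in [1, {K}]")
        if self.n_markers > self.n_genes:
            raise ValidationError("n_markers cannot exceed n_genes")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index([f"gene{g + 1}" for g in range(self.n_genes)])

    @property
    def cell_types(self) -> pd.Index:
        return pd.Index([f"CT{k + 1}" for k in range(self.n_celltypes)])


@dataclass
class SimulationTruth:
    """Every latent quantity of one simulated dataset."""

    config: SimulationConfig
    M_ctrl: pd.DataFrame
    M_case: pd.DataFrame
    Phi: pd.DataFrame
    de_mask: pd.DataFrame
    P_ctrl: pd.DataFrame
    P_case: pd.DataFrame
    P_n: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    theta_T: ProportionSet | None = None
    lam: pd.DataFrame | None = None
    bulk: BulkExperiment | None = None
    signature: SignatureMatrix | None = None


def draw_cts_parameters(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw per-gene log-means / log-dispersions and the DE mask."""
    G, K = cfg.n_genes, cfg.n_celltypes
    M = rng.multivariate_normal(cfg.mvn_mean_logmean, cfg.mvn_cov_logmean, size=G)
    Phi = rng.multivariate_normal(cfg.mvn_mean_logdisp, cfg.mvn_cov_logdisp, size=G)

    de_mask = np.zeros((G, K), dtype=bool)
    n_de = math.ceil(cfg.de_fraction * G)
    for ct in cfg.de_celltypes:  # independent draws; overlaps across cell types allowed
        de_mask[rng.choice(G, size=n_de, replace=False), ct - 1] = True
    M_case = M + cfg.lfc * de_mask

    genes, cts = cfg.gene_ids, cfg.cell_types
    return (
        pd.DataFrame(M, index=genes, columns=cts),
        pd.DataFrame(M_case, index=genes, columns=cts),
        pd.DataFrame(Phi, index=genes, columns=cts),
        pd.DataFrame(de_mask, index=genes, columns=cts),
    )


def _subject_ids(cfg: SimulationConfig):
    ctrl = [f"ctrl{n + 1}" for n in range(cfg.n_subjects_per_group)]
    case = [f"case{n + 1}" for n in range(cfg.n_subjects_per_group)]
    return ctrl, case


def draw_expression_panels(
    M_ctrl: pd.DataFrame,
    M_case: pd.DataFrame,
    Phi: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
):
    """Gamma group panels and SSV-perturbed per-subject panels.

    The two group panels share one standard Gamma variate per (gene, cell
    type) — the shape depends only on the shared dispersion — scaled by the
    group-specific mean ``exp(M_group) * exp(Phi)``.  Each panel's marginal
    is the stated Gamma, and coupling makes the realized case/control fold
    change exactly ``exp(lfc)`` on differentially expressed entries and
    exactly 1 elsewhere, so a zero effect size yields identical panels.
    """
    shape = 1.0 / np.exp(Phi.to_numpy())
    base = rng.gamma(shape, 1.0)
    P_ctrl = base * np.exp(M_ctrl.to_numpy()) * np.exp(Phi.to_numpy())
    P_case = base * np.exp(M_case.to_numpy()) * np.exp(Phi.to_numpy())

    lo, hi = cfg.ssv_range
    ctrl_ids, case_ids = _subject_ids(cfg)
    P_n: dict[str, pd.DataFrame] = {}
    for ids, P_group in ((ctrl_ids, P_ctrl), (case_ids, P_case)):
        for subj in ids:
            delta = rng.uniform(lo, hi, size=P_group.shape)
            sign = rng.choice([-1.0, 1.0], size=P_group.shape)
            P_n[subj] = pd.DataFrame(
                P_group * (1.0 + sign * delta), index=M_ctrl.index, columns=M_ctrl.columns
            )
    return (
        pd.DataFrame(P_ctrl, index=M_ctrl.index, columns=M_ctrl.columns),
        pd.DataFrame(P_case, index=M_ctrl.index, columns=M_ctrl.columns),
        P_n,
    )


def draw_proportions_and_counts(
    P_n: Mapping[str, pd.DataFrame], cfg: SimulationConfig, rng: np.random.Generator
):
    """Dirichlet compositions, expected signal lambda and Poisson counts."""
    ctrl_ids, case_ids = _subject_ids(cfg)
    t = cfg.repeats_per_subject
    genes, cts = cfg.gene_ids, cfg.cell_types

    sample_ids, theta_rows, lam_cols, count_cols, meta_rows = [], [], [], [], []
    for group, ids, alpha in (
        (0, ctrl_ids, cfg.alpha_ctrl),
        (1, case_ids, cfg.alpha_case),
    ):
        for subj in ids:
            P = P_n[subj].to_numpy()
            for i in range(t):
                theta = rng.dirichlet(alpha)
                lam = P @ theta
                y = rng.poisson(lam)
                sid = f"{subj}_r{i + 1}"
                sample_ids.append(sid)
                theta_rows.append(theta)
                lam_cols.append(lam)
                count_cols.append(y)
                meta_rows.append((sid, subj, i + 1, group))

    theta_T = ProportionSet(
        pd.DataFrame(theta_rows, index=sample_ids, columns=cts), origin="truth"
    )
    lam = pd.DataFrame(np.column_stack(lam_cols), index=genes, columns=sample_ids)
    counts = pd.DataFrame(
        np.column_stack(count_cols), index=genes, columns=sample_ids
    ).astype(float)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "repeat_index", "group"]
    ).set_index("sample_id")
    bulk = BulkExperiment(counts, metadata)
    return theta_T, lam, bulk


def build_signature(
    P_n: Mapping[str, pd.DataFrame], n_markers: int
) -> SignatureMatrix:
    """Average all subject panels and keep the top-CV marker genes.

    The coefficient of variation is computed per gene across the K cell-type
    columns of the averaged panel; genes are ranked descending and the first
    ``n_markers`` retained (stable order on ties).
    """
    panels = list(P_n.values())
    if not panels:
        raise ValidationError("no subject panels to average")
    mean_panel = sum(p.to_numpy() for p in panels) / len(panels)
    if n_markers > mean_panel.shape[0]:
        raise ValidationError("n_markers exceeds the number of simulated genes")
    mu = mean_panel.mean(axis=1)
    sd = mean_panel.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mu > 0, sd / mu, 0.0)
    order = np.argsort(-cv, kind="stable")[:n_markers]
    ref = panels[0]
    values = pd.DataFrame(
        mean_panel[order], index=ref.index[order], columns=ref.columns
    )
    return SignatureMatrix(values)


def simulate(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulationTruth:
    """Run the full generative chain; identical seed + config is bit-reproducible."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    M_ctrl, M_case, Phi, de_mask = draw_cts_parameters(cfg, rng)
    P_ctrl, P_case, P_n = draw_expression_panels(M_ctrl, M_case, Phi, cfg, rng)
    theta_T, lam, bulk = draw_proportions_and_counts(P_n, cfg, rng)
    signature = build_signature(P_n, cfg.n_markers)
    return SimulationTruth(
        config=cfg,
        M_ctrl=M_ctrl,
        M_case=M_case,
        Phi=Phi,
        de_mask=de_mask,
        P_ctrl=P_ctrl,
        P_case=P_case,
        P_n=P_n,
        theta_T=theta_T,
        lam=lam,
        bulk=bulk,
        signature=signature,
    )
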