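"""Core domain containers for personalized deconvolution.

All containers wrap :class:`pandas.DataFrame` objects and validate their
invariants on construction, so that downstream stages can assume clean,
aligned inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BulkExperiment",
    "SignatureMatrix",
    "ProportionSet",
    "GeneLMMFit",
    "PersonalizedPanelSet",
    "SVRConfig",
    "Stage3Config",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input artifact violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BulkExperiment:
    """A genes x samples bulk expression matrix with repeated-measures metadata.

    Parameters
    ----------
    expression
        Non-negative expression (raw counts or normalized), genes as rows,
        samples as columns.
    metadata
        One row per sample (index = sample id) with columns ``subject_id``,
        ``repeat_index`` (integer >= 1) and ``group`` (0 = control, 1 = case).
        Additional numeric columns are carried along as extra covariates.
    """

    expression: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.expression.index, "gene ids")
        _check_unique(self.expression.columns, "sample ids")
        _check_unique(self.metadata.index, "metadata sample ids")

        missing = self.expression.columns.difference(self.metadata.index)
        if len(missing):
            raise ValidationError(
                f"samples present in expression but missing from metadata: "
                f"{missing.tolist()[:5]}"
            )
        # align metadata to expression column order; extra metadata rows dropped
        self.metadata = self.metadata.loc[self.expression.columns].copy()

        for col in ("subject_id", "repeat_index", "group"):
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata is missing required column {col!r}")

        values = self.expression.to_numpy()
        if np.isnan(values).any():
            g, s = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at gene {self.expression.index[g]!r}, "
                f"sample {self.expression.columns[s]!r}"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression at gene {self.expression.index[g]!r}, "
                f"sample {self.expression.columns[s]!r}"
            )

        bad_group = ~self.metadata["group"].isin([0, 1])
        if bad_group.any():
            sid = self.metadata.index[bad_group][0]
            raise ValidationError(
                f"group of sample {sid!r} is {self.metadata.loc[sid, 'group']!r}; "
                "must be 0 or 1"
            )
        # a subject must have one group label
        per_subject = self.metadata.groupby("subject_id")["group"].nunique()
        if (per_subject > 1).any():
            bad = per_subject[per_subject > 1].index[0]
            raise ValidationError(f"subject {bad!r} has inconsistent group labels")
        dup = self.metadata.duplicated(subset=["subject_id", "repeat_index"])
        if dup.any():
            sid = self.metadata.index[dup][0]
            raise ValidationError(
                f"sample {sid!r} duplicates (subject_id, repeat_index) of another sample"
            )

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def subjects(self) -> pd.Index:
        return pd.Index(self.metadata["subject_id"].unique())

    @property
    def subject_of(self) -> pd.Series:
        return self.metadata["subject_id"]

    @property
    def group_of(self) -> pd.Series:
        """Group label (0/1) per subject."""
        return self.metadata.groupby("subject_id")["group"].first()

    def samples_of(self, subject) -> pd.Index:
        mask = self.metadata["subject_id"] == subject
        return self.metadata.index[mask]

    def require_repeated_measures(self) -> None:
        counts = self.metadata.groupby("subject_id").size()
        single = counts[counts < 2]
        if len(single):
            raise ValidationError(
                "personalized panel recovery requires repeated measures; "
                f"subject(s) with a single sample: {single.index.tolist()[:5]}"
            )

    def to_cpm(self) -> "BulkExperiment":
        """Return a copy with every sample scaled to counts-per-million."""
        totals = self.expression.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise ValidationError(f"sample {bad!r} has zero total expression")
        cpm = self.expression * (1e6 / totals)
        return BulkExperiment(cpm, self.metadata.copy())


@dataclass
class SignatureMatrix:
    """Marker-gene x cell-type population reference panel (the design E)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "signature gene ids")
        _check_unique(self.values.columns, "cell type names")
        if self.values.shape[1] < 2:
            raise ValidationError(
                f"signature matrix needs >= 2 cell types, got {self.values.shape[1]}"
            )
        if self.values.shape[0] < self.values.shape[1]:
            raise ValidationError(
                "signature matrix must have at least as many marker genes as cell types"
            )
        arr = self.values.to_numpy()
        if (arr < 0).any():
            g, k = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative signature entry at gene {self.values.index[g]!r}, "
                f"cell type {self.values.columns[k]!r}"
            )
        zero_rows = (arr == 0).all(axis=1)
        if zero_rows.any():
            raise ValidationError(
                f"all-zero signature row(s): {self.values.index[zero_rows].tolist()[:5]}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]


@dataclass
class ProportionSet:
    """Samples x cell-types composition matrix; rows on the unit simplex."""

    values: pd.DataFrame
    origin: Literal["stage1", "stage3", "truth"]
    normalized: bool = True

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "cell type names")
        if self.values.shape[0] == 0:
            raise ValidationError("empty proportion set")
        arr = self.values.to_numpy()
        if (arr < -1e-12).any():
            raise ValidationError("negative proportion entries")
        if not self.normalized:
            return
        sums = arr.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-8:
            i = int(np.abs(sums - 1.0).argmax())
            raise ValidationError(
                f"proportions of sample {self.values.index[i]!r} sum to {sums[i]:.6g}, "
                "expected 1"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    def loc(self, samples) -> np.ndarray:
        return self.values.loc[samples].to_numpy()


@dataclass
class GeneLMMFit:
    """Per-gene mixed-model estimates: fixed slopes and subject BLUPs.

    ``m_hat[k]`` is the control-group mean expression of the gene in cell type
    ``k``; ``beta_hat[k]`` the case-minus-control difference; ``u_hat`` holds
    the predicted subject-level random deviations (BLUPs).
    """

    m_hat: pd.Series
    beta_hat: pd.Series
    u_hat: pd.DataFrame  # subjects x cell types
    varcomp: pd.Series  # random-slope variance per cell type, >= 0
    resid_var: float
    converged: bool
    fallback: Literal["none", "fixed_only"] = "none"

    def __post_init__(self) -> None:
        if (self.varcomp < 0).any():
            raise ValidationError("negative variance component")
        if self.resid_var < 0:
            raise ValidationError("negative residual variance")
        if self.fallback == "fixed_only" and (self.u_hat.to_numpy() != 0).any():
            raise ValidationError("fixed-only fallback must have zero random effects")


@dataclass
class PersonalizedPanelSet:
    """One genes x cell-types reference panel per subject, plus the fits."""

    panels: Mapping[str, pd.DataFrame]
    gene_ids: pd.Index
    cell_types: pd.Index
    fits: Mapping[str, GeneLMMFit] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for subj, panel in self.panels.items():
            if not panel.index.equals(pd.Index(self.gene_ids)):
                raise ValidationError(f"panel of subject {subj!r} has mismatched genes")
            if not panel.columns.equals(pd.Index(self.cell_types)):
                raise ValidationError(
                    f"panel of subject {subj!r} has mismatched cell types"
                )
            if (panel.to_numpy() < 0).any():
                raise ValidationError(f"negative panel entry for subject {subj!r}")

    @property
    def subjects(self):
        return list(self.panels)

    def coefficients_table(self) -> pd.DataFrame:
        """Long-format table of m_hat / beta_hat / u_hat per (gene, cell type)."""
        rows = []
        for gene, fit in self.fits.items():
            for ct in fit.m_hat.index:
                row = {
                    "gene": gene,
                    "cell_type": ct,
                    "m_hat": fit.m_hat[ct],
                    "beta_hat": fit.beta_hat[ct],
                    "varcomp": fit.varcomp[ct],
                }
                for subj in fit.u_hat.index:
                    row[f"u_hat.{subj}"] = fit.u_hat.loc[subj, ct]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SVRConfig:
    """Settings for the linear nu-SVR deconvolution step.

    ``nu_grid`` is searched and the fit with the lowest RMSE between the
    observed and reconstructed expression wins; ties go to the smallest nu.
    """

    nu_grid: tuple = (0.25, 0.50, 0.75)
    penalty_c: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if len(self.nu_grid) == 0:
            raise ValidationError("nu grid must be non-empty")
        if any(not (0 < nu <= 1) for nu in self.nu_grid):
            raise ValidationError("all nu values must lie in (0, 1]")
        if self.penalty_c <= 0:
            raise ValidationError("penalty C must be positive")


@dataclass
class Stage3Config:
    """Settings for the final personalized deconvolution."""

    solver: Literal["nnls", "svr"] = "nnls"
    gene_set: Literal["signature", "all"] = "signature"
    normalize_output: bool = True

    def __post_init__(self) -> None:
        if self.solver not in ("nnls", "svr"):
            raise ValidationError(f"unknown solver {self.solver!r}")
        if self.gene_set not in ("signature", "all"):
            raise ValidationError(f"unknown gene set {self.gene_set!r}")


def warn_degenerate(msg: str) -> None:
    warnings.warn(msg, RuntimeWarning, stacklevel=3)
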