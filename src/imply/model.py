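"""Model/Results interface tying the three stages together.

:class:`PersonalizedDeconvolution` is constructed from a
:class:`~imply.types.BulkExperiment` and a population
:class:`~imply.types.SignatureMatrix`; ``fit()`` runs the coarse nu-SVR
deconvolution (Stage I), the per-gene mixed models that recover one
personalized reference panel per subject (Stage II), and the final
per-subject deconvolution against those panels (Stage III), returning a
:class:`PersonalizedDeconvolutionResults` that carries every intermediate
product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stage1 import run_stage1
from .stage2 import run_stage2
from .stage3 import run_stage3
from .types import (
    BulkExperiment,
    PersonalizedPanelSet,
    ProportionSet,
    SignatureMatrix,
    Stage3Config,
    SVRConfig,
)

logger = logging.getLogger(__name__)

__all__ = ["PersonalizedDeconvolution", "PersonalizedDeconvolutionResults"]


class PersonalizedDeconvolution:
    """Three-stage personalized deconvolution of repeated-measures bulk data.

    Parameters
    ----------
    bulk
        Expression with subject / repeat / group metadata.  Raw counts are
        scaled to counts-per-million unless ``normalize_input=False`` (the
        linear mixing model lives in linear expression space; CPM puts all
        samples on a common scale).
    signature
        Population marker-gene x cell-type reference panel.
    svr_config
        Stage I (and ``imply-s`` Stage III) nu-SVR settings.
    stage3
        Final-stage solver settings (``nnls`` for imply, ``svr`` for imply-s).
    genes
        ``"signature"`` fits Stage II on the marker genes only (the Stage III
        feature space); ``"all"`` fits every bulk gene.

    Examples
    --------
    >>> model = PersonalizedDeconvolution(bulk, signature)
    >>> result = model.fit()
    >>> result.proportions.values.head()
    """

    def __init__(
        self,
        bulk: BulkExperiment,
        signature: SignatureMatrix,
        svr_config: SVRConfig | None = None,
        stage3: Stage3Config | None = None,
        genes: str = "signature",
        normalize_input: bool = True,
    ):
        self.signature = signature
        self.svr_config = svr_config or SVRConfig()
        self.stage3_config = stage3 or Stage3Config(gene_set=genes)
        self.genes = genes
        self.normalize_input = normalize_input
        self.bulk = bulk.to_cpm() if normalize_input else bulk

    @classmethod
    def from_files(cls, expression_path, metadata_path, signature_path, **kwargs):
        """Build the model straight from on-disk artifacts."""
        from . import io

        bulk = io.read_bulk(expression_path, metadata_path)
        signature = io.read_signature(signature_path)
        return cls(bulk, signature, **kwargs)

    def fit(self) -> "PersonalizedDeconvolutionResults":
        """Run Stages I-III and collect all products."""
        self.bulk.require_repeated_measures()
        stage1 = run_stage1(self.bulk, self.signature, self.svr_config)
        if self.genes == "signature":
            gene_set = self.signature.gene_ids.intersection(self.bulk.gene_ids)
        else:
            gene_set = self.bulk.gene_ids
        panels = run_stage2(self.bulk, stage1, genes=gene_set)
        stage3 = run_stage3(self.bulk, panels, self.stage3_config, self.svr_config)
        return PersonalizedDeconvolutionResults(
            model=self,
            stage1_proportions=stage1,
            panels=panels,
            proportions=stage3,
        )


@dataclass
class PersonalizedDeconvolutionResults:
    """Fitted proportions, personalized panels and per-gene mixed-model fits."""

    model: PersonalizedDeconvolution
    stage1_proportions: ProportionSet
    panels: PersonalizedPanelSet
    proportions: ProportionSet
    _summary_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def coarse(self) -> ProportionSet:
        """Alias for the Stage I (population-reference) estimates."""
        return self.stage1_proportions

    def fallback_fraction(self) -> float:
        """Fraction of genes whose mixed model fell back to fixed-effects OLS."""
        fits = self.panels.fits
        if not fits:
            return 0.0
        return float(np.mean([f.fallback != "none" for f in fits.values()]))

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        bulk = self.model.bulk
        props = self.proportions.values
        lines = [
            "Personalized Deconvolution Results",
            "=" * 50,
            f"Samples:               {bulk.n_samples}",
            f"Subjects:              {len(bulk.subjects)}",
            f"Cell types:            {len(self.proportions.cell_types)}",
            f"Marker genes (panel):  {len(self.panels.gene_ids)}",
            f"Stage III solver:      {self.model.stage3_config.solver}",
            f"OLS fallback fraction: {self.fallback_fraction():.3f}",
            "-" * 50,
            "Mean estimated proportions (Stage III | Stage I):",
        ]
        s1 = self.stage1_proportions.values
        for ct in props.columns:
            lines.append(f"  {ct:<16s} {props[ct].mean():.4f} | {s1[ct].mean():.4f}")
        return "\n".join(lines)

    def proportion_changes(self) -> pd.DataFrame:
        """Per-sample Stage III minus Stage I composition shifts."""
        return self.proportions.values - self.stage1_proportions.values

    def plot_compositions(self, ax=None):
        """Stacked bar chart of the Stage III compositions (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        self.proportions.values.plot(kind="bar", stacked=True, ax=ax, width=1.0)
        ax.set_ylabel("estimated proportion")
        ax.set_xlabel("sample")
        ax.set_xticks([])
        return ax
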