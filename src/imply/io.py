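"""Reading and writing of on-disk artifacts.

Expression matrices are genes x samples TSV/CSV (header row = sample ids,
first column = gene ids) or MatrixMarket ``.mtx`` with ``genes.tsv`` /
``samples.tsv`` sidecars; sample metadata and signatures are TSV.  Proportion
estimates are written in long format (sample_id, cell_type, proportion) with
a wide-format mirror; personalized panels as one genes x cell-types TSV per
subject plus a combined coefficients table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import mmread

from .types import (
    BulkExperiment,
    PersonalizedPanelSet,
    ProportionSet,
    SignatureMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_bulk",
    "read_signature",
    "read_proportions",
    "write_proportions",
    "write_panels",
]

_FLOAT_FMT = "%.17g"  # 17 significant digits round-trip IEEE doubles exactly


def _read_matrix(path: Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".mtx":
        m = mmread(path)
        mat = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
        genes = pd.read_csv(path.parent / "genes.tsv", header=None)[0].astype(str)
        samples = pd.read_csv(path.parent / "samples.tsv", header=None)[0].astype(str)
        if mat.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        return pd.DataFrame(mat, index=genes, columns=samples)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def read_bulk(expression_path, metadata_path) -> BulkExperiment:
    """Load and validate a bulk expression matrix with its sample metadata."""
    expr = _read_matrix(Path(expression_path))
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample_id", "subject_id", "repeat_index", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata is missing column(s): {sorted(missing)}")
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    meta = meta.set_index("sample_id")
    bulk = BulkExperiment(expr.astype(float), meta)
    logger.info(
        "read bulk: %d genes x %d samples, %d subjects",
        bulk.n_genes,
        bulk.n_samples,
        len(bulk.subjects),
    )
    return bulk


def read_signature(path) -> SignatureMatrix:
    """Load a marker-gene x cell-type signature TSV."""
    df = _read_matrix(Path(path))
    sig = SignatureMatrix(df.astype(float))
    logger.info("read signature: %d marker genes x %d cell types", *df.shape)
    return sig


def write_proportions(p: ProportionSet, path) -> None:
    """Write a ProportionSet as long-format TSV, plus a wide-format mirror."""
    if p.values.shape[0] == 0:
        raise ValidationError("refusing to write an empty proportion set")
    path = Path(path)
    long = (
        p.values.rename_axis("sample_id")
        .reset_index()
        .melt(id_vars="sample_id", var_name="cell_type", value_name="proportion")
    )
    long.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    wide = path.with_name(path.stem + ".wide.tsv")
    p.values.rename_axis("sample_id").to_csv(wide, sep="\t", float_format=_FLOAT_FMT)


def read_proportions(path, origin="stage1") -> ProportionSet:
    """Read a long-format proportion TSV back into a ProportionSet."""
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="sample_id", columns="cell_type", values="proportion")
    # preserve first-appearance order of samples and cell types
    wide = wide.loc[
        long["sample_id"].drop_duplicates(), long["cell_type"].drop_duplicates()
    ]
    wide.index.name = None
    wide.columns.name = None
    return ProportionSet(wide, origin=origin)


def write_panels(panels: PersonalizedPanelSet, out_dir) -> None:
    """Write one panel TSV per subject plus the combined coefficients table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subject, panel in panels.panels.items():
        panel.rename_axis("gene").to_csv(
            out_dir / f"panel.{subject}.tsv", sep="\t", float_format=_FLOAT_FMT
        )
    if panels.fits:
        panels.coefficients_table().to_csv(
            out_dir / "lmm_coefficients.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
    logger.info("wrote %d subject panels to %s", len(panels.panels), out_dir)


def read_panels(directory, subjects=None) -> Mapping[str, pd.DataFrame]:
    """Read subject panels written by :func:`write_panels`."""
    directory = Path(directory)
    panels = {}
    for f in sorted(directory.glob("panel.*.tsv")):
        subject = f.name[len("panel."):-len(".tsv")]
        if subjects is not None and subject not in subjects:
            continue
        panels[subject] = pd.read_csv(f, sep="\t", index_col=0)
    if not panels:
        raise ValidationError(f"no panel TSVs found in {directory}")
    return panels
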