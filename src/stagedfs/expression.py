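"""Expression matrix I/O, low-expression filtering and log2-CPM normalization.

The matrix is genes x samples with a tumor/normal label per sample.  Genes
expressed in small amounts in most samples are removed with an explicit
CPM-threshold rule (keep a gene iff CPM >= min_cpm in at least a fraction
min_sample_frac of samples), and counts are normalized to log2(1 + CPM).
The downstream stages (fold change, mutual information, tree ensembles) need
only a monotone within-sample normalization, so no between-sample scaling
factors are estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError

logger = logging.getLogger(__name__)

LABELS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample tumor/normal labels.

    ``scale`` records whether ``values`` holds raw counts or log2-CPM.
    """

    values: pd.DataFrame
    labels: pd.Series = field(repr=False)
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in ("counts", "log2cpm"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DataFormatError(f"duplicate gene symbol(s): {', '.join(dups)}")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise DataFormatError(
                f"samples without labels: {', '.join(map(str, missing))}"
            )
        self.labels = self.labels.loc[self.values.columns]
        bad = sorted(set(self.labels.unique()) - set(LABELS))
        if bad:
            raise DataFormatError(f"unknown label value(s): {', '.join(map(str, bad))}")
        if (np.asarray(self.values) < 0).any():
            raise DataFormatError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def tumor_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "tumor"])

    def normal_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "normal"])


def read_expression(path, labels_path) -> ExpressionMatrix:
    """Load a genes-as-rows TSV/CSV and attach the label file.

    The label file is a two-column table (sample, label in {tumor, normal});
    every expression column must be labelled.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    values = pd.read_csv(path, sep=sep, index_col=0)
    labels_df = pd.read_csv(labels_path, sep="\t")
    if labels_df.shape[1] < 2:
        raise DataFormatError(f"label file {labels_path} needs two columns")
    labels = pd.Series(
        labels_df.iloc[:, 1].values, index=labels_df.iloc[:, 0].astype(str), name="label"
    )
    if labels.index.has_duplicates:
        raise DataFormatError(f"duplicate sample barcodes in {labels_path}")
    return ExpressionMatrix(values=values, labels=labels, scale="counts")


def write_expression(matrix: ExpressionMatrix, path, labels_path=None) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    if labels_path is not None:
        matrix.labels.rename_axis("sample").reset_index().to_csv(
            labels_path, sep="\t", index=False
        )


def _cpm(values: pd.DataFrame) -> pd.DataFrame:
    colsums = values.sum(axis=0)
    zero = colsums.index[colsums == 0]
    if len(zero):
        raise DataFormatError(
            f"zero library size for sample(s): {', '.join(map(str, zero))}"
        )
    return values * 1e6 / colsums


def filter_low_expression(
    matrix: ExpressionMatrix, min_cpm: float = 1.0, min_sample_frac: float = 0.1
) -> ExpressionMatrix:
    """Drop genes expressed in small amounts in most samples.

    A gene is kept iff its CPM reaches ``min_cpm`` in at least
    ``min_sample_frac`` of samples.  Operates on raw counts only.
    """
    if matrix.scale != "counts":
        raise ValueError("filter_low_expression applies to raw counts")
    cpm = _cpm(matrix.values)
    keep = (cpm >= min_cpm).mean(axis=1) >= min_sample_frac
    logger.info(
        "low-expression filter (min_cpm=%g, frac=%g): %d -> %d genes",
        min_cpm, min_sample_frac, len(keep), int(keep.sum()),
    )
    return ExpressionMatrix(
        values=matrix.values.loc[keep], labels=matrix.labels, scale="counts"
    )


def normalize_log2cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalize to log2(1 + CPM)."""
    if matrix.scale != "counts":
        raise ValueError("normalize_log2cpm applies to raw counts")
    values = np.log2(1.0 + _cpm(matrix.values))
    return ExpressionMatrix(values=values, labels=matrix.labels, scale="log2cpm")


def linear_cpm(values: np.ndarray) -> np.ndarray:
    """Invert the log2(1 + CPM) transform back to the linear CPM scale."""
    return np.exp2(values) - 1.0
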