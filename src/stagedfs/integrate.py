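"""Map the highly mutated gene set onto the expression matrix.

The integrative dataset is the normalized-expression submatrix over the
frequency-selected mutated genes, with the tumor samples that carry the
mutation calls plus *all* normal samples added as the control group (mutation
calls exist only for tumors; normals enter purely as expression controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError, PipelineError
from .expression import ExpressionMatrix
from .mutation import FrequencySelection

logger = logging.getLogger(__name__)

# TCGA barcodes identify the patient in the first 12 characters; mutation and
# expression files are often at different sample-level granularity.
DEFAULT_PREFIX_LEN = 12


@dataclass
class IntegrativeDataset:
    """Expression submatrix over the mutated gene set, labels 1=tumor 0=normal."""

    values: pd.DataFrame
    labels: pd.Series = field(repr=False)
    provenance: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = self.labels.loc[self.values.columns]
        classes = set(self.labels.unique())
        if not classes <= {0, 1}:
            raise ValueError("labels must be 0 (normal) / 1 (tumor)")
        if classes != {0, 1}:
            raise PipelineError("both classes must be represented")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def X(self) -> np.ndarray:
        """Samples x features design matrix (scikit-learn orientation)."""
        return self.values.to_numpy().T

    def y(self) -> np.ndarray:
        return self.labels.to_numpy().astype(int)


def match_samples(mutation_samples, expression_samples, prefix_len: int = 0) -> dict:
    """Match mutation barcodes to expression barcodes by shared prefix.

    ``prefix_len=0`` means exact match.  Returns the mapping; unmatched
    mutation barcodes are logged.  A mutation barcode whose prefix matches
    several expression barcodes is an ambiguity error.
    """
    expression_samples = list(expression_samples)
    if prefix_len > 0:
        buckets: dict[str, list[str]] = {}
        for s in expression_samples:
            buckets.setdefault(s[:prefix_len], []).append(s)
    else:
        buckets = {s: [s] for s in expression_samples}
    mapping: dict[str, str] = {}
    unmatched = []
    for m in mutation_samples:
        key = m[:prefix_len] if prefix_len > 0 else m
        hits = buckets.get(key, [])
        if len(hits) > 1:
            raise DataFormatError(
                f"mutation barcode {m} matches multiple expression barcodes: "
                + ", ".join(sorted(hits))
            )
        if hits:
            mapping[m] = hits[0]
        else:
            unmatched.append(m)
    if unmatched:
        logger.warning(
            "%d mutation barcode(s) had no expression match: %s",
            len(unmatched), ", ".join(unmatched[:10]),
        )
    return mapping


def build_integrative_dataset(
    expr: ExpressionMatrix, selection: FrequencySelection
) -> IntegrativeDataset:
    """Restrict the normalized expression matrix to the mutated gene set.

    Genes in the selection but absent from (the filtered) expression are
    dropped with a warning; sample columns are the tumor samples plus all
    normal samples as controls.
    """
    if expr.scale != "log2cpm":
        raise ValueError("integrative dataset is built on normalized expression")
    if not selection.selected_genes:
        raise PipelineError("frequency selection is empty")
    expr_genes = set(expr.genes)
    kept = [g for g in selection.selected_genes if g in expr_genes]
    dropped = [g for g in selection.selected_genes if g not in expr_genes]
    if dropped:
        logger.warning(
            "%d selected gene(s) absent from expression, dropped: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    if not kept:
        raise PipelineError(
            "no overlap between the mutated gene set and the expression genes"
        )
    values = expr.values.loc[sorted(kept)]
    labels = (expr.labels == "tumor").astype(int)
    n_t, n_n = int((labels == 1).sum()), int((labels == 0).sum())
    if n_t == 0 or n_n == 0:
        raise PipelineError("a class has zero samples in the integrative dataset")
    logger.info(
        "integrative dataset: %d genes x %d samples (%d tumor / %d normal)",
        values.shape[0], values.shape[1], n_t, n_n,
    )
    return IntegrativeDataset(
        values=values,
        labels=labels,
        provenance={
            "threshold_p": selection.threshold_p,
            "min_count": selection.min_count,
            "selected_genes": len(selection.selected_genes),
            "genes_kept": len(kept),
            "genes_dropped": dropped,
            "n_tumor": n_t,
            "n_normal": n_n,
        },
    )


def expression_only_dataset(expr: ExpressionMatrix) -> IntegrativeDataset:
    """Dataset over *all* expression genes (no mutation-derived restriction)."""
    if expr.scale != "log2cpm":
        raise ValueError("dataset is built on normalized expression")
    labels = (expr.labels == "tumor").astype(int)
    return IntegrativeDataset(
        values=expr.values.sort_index(),
        labels=labels,
        provenance={"mode": "expression_only", "genes_kept": len(expr.genes)},
    )
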