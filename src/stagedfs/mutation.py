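"""Binary somatic-mutation matrix and mutation-frequency gene filtering.

A MAF-style variant table is reduced to a presence/absence incidence of genes
over tumor samples: cell (g, s) is 1 iff at least one variant call pairs gene
g with sample s.  Per-gene mutated-sample counts give the mutation frequency,
and genes mutated in at least a fraction ``p`` of samples form the highly
mutated gene set that seeds the integrative dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataFormatError

logger = logging.getLogger(__name__)

VARIANT_TYPES = ("SNP", "INS", "DEL")

_REQUIRED_MAF_COLUMNS = ("Hugo_Symbol", "Variant_Type", "Tumor_Sample_Barcode")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call: gene symbol, variant type, sample barcode."""

    gene: str
    variant_type: str
    sample: str

    def __post_init__(self) -> None:
        if not self.gene or not self.sample:
            raise ValueError("gene and sample must be non-empty")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(
                f"variant_type must be one of {VARIANT_TYPES}, got {self.variant_type!r}"
            )


class MutationMatrix:
    """Binary gene x sample incidence with per-gene mutated-sample counts.

    Genes and samples are held in canonical (lexicographic) order so that
    every downstream stage is deterministic regardless of input row order.
    """

    def __init__(self, cells: pd.DataFrame):
        if cells.index.has_duplicates or cells.columns.has_duplicates:
            raise ValueError("gene and sample lists must be duplicate-free")
        cells = cells.sort_index(axis=0).sort_index(axis=1).astype(np.int8)
        if not cells.isin([0, 1]).all().all():
            raise ValueError("cells must be binary")
        self.cells = cells

    @property
    def genes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cells.columns)

    @property
    def counts(self) -> pd.Series:
        """Per-gene number of mutated samples (row sums)."""
        return self.cells.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.cells.shape[1]

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationMatrix) and self.cells.equals(other.cells)

    def to_tsv(self, path) -> None:
        out = self.cells.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class FrequencySelection:
    """Outcome of the mutation-frequency threshold: the highly mutated genes."""

    threshold_p: float
    min_count: int
    selected_genes: tuple[str, ...]


def read_maf(path) -> list[MutationRecord]:
    """Parse a MAF-compatible TSV into mutation records.

    Only ``Hugo_Symbol``, ``Variant_Type`` and ``Tumor_Sample_Barcode`` are
    used; extra columns are ignored and ``#``-prefixed lines are skipped.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("MAF file %s is empty", path)
        return []
    missing = [c for c in _REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"MAF file {path} is missing required column(s): {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("MAF file %s has a header but no records", path)
        return []
    return [
        MutationRecord(gene=g, variant_type=v, sample=s)
        for g, v, s in zip(
            df["Hugo_Symbol"], df["Variant_Type"], df["Tumor_Sample_Barcode"]
        )
    ]


def build_mutation_matrix(records: list[MutationRecord]) -> MutationMatrix:
    """Collapse records to the 0/1 incidence matrix (duplicates collapse)."""
    if not records:
        raise ValueError("cannot build a mutation matrix from zero records")
    genes = sorted({r.gene for r in records})
    samples = sorted({r.sample for r in records})
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    cells = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for r in records:
        cells[gi[r.gene], si[r.sample]] = 1
    return MutationMatrix(pd.DataFrame(cells, index=genes, columns=samples))


def mutation_frequencies(matrix: MutationMatrix) -> pd.Series:
    """Fraction of samples mutated per gene: counts / n."""
    if matrix.n_samples == 0:
        raise ValueError("mutation frequency undefined for zero samples")
    return matrix.counts / matrix.n_samples


def filter_by_frequency(matrix: MutationMatrix, p: float = 0.01) -> FrequencySelection:
    """Select genes mutated in at least ``ceil(p * n)`` samples.

    ``p`` is the mutation-frequency threshold as a fraction of total samples;
    the comparison is inclusive (count >= ceil(p*n)).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"threshold p must lie in (0, 1], got {p}")
    min_count = math.ceil(p * matrix.n_samples)
    counts = matrix.counts
    selected = tuple(g for g in matrix.genes if counts[g] >= min_count)
    logger.info(
        "frequency filter p=%g (min_count=%d): %d -> %d genes",
        p, min_count, len(matrix.genes), len(selected),
    )
    return FrequencySelection(threshold_p=p, min_count=min_count, selected_genes=selected)
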