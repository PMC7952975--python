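"""Stages 1-2 of the staged feature selection.

Stage 1 filters to differentially expressed genes by fold change and
false-discovery rate: per gene, the fold change is the ratio of tumor to
normal class means on the linear CPM scale (with a pseudocount guarding zero
denominators), the p-value comes from a two-sided Welch t-test on the
log2-CPM values, and the q-value from Benjamini-Hochberg step-up.  A gene
survives iff q < fdr_threshold and |log2 FC| > lfc_threshold.

Stage 2 ranks the survivors by the mutual information between each gene and
the tumor/normal label, MI(G, L) = H(G) + H(L) - H(G, L) in bits, with the
continuous expression discretized by equal-frequency binning, and keeps the
top M.

Both stages are exposed as scikit-learn selector estimators
(:class:`DifferentialExpressionSelector`, :class:`MutualInfoSelector`) so the
whole method composes with sklearn pipelines, plus thin dataframe-level
functions over :class:`~stagedfs.integrate.IntegrativeDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError
from .expression import linear_cpm
from .integrate import IntegrativeDataset

DEFAULT_FDR = 0.05
DEFAULT_LFC = 1.0
DEFAULT_TOP_M = 50
DEFAULT_BINS = 10
DEFAULT_PSEUDOCOUNT = 1.0  # CPM units, guards zero class means in the FC ratio


# ------------------------------------------------------------------ primitives

def fold_change_from_means(
    mean_tumor: np.ndarray, mean_normal: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
):
    """FC = (mean_tumor + eps) / (mean_normal + eps) on the linear scale."""
    fc = (np.asarray(mean_tumor, float) + pseudocount) / (
        np.asarray(mean_normal, float) + pseudocount
    )
    return fc, np.log2(fc)


def welch_pvalues(x_tumor: np.ndarray, x_normal: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test per row; degenerate rows resolved by the means.

    Rows with zero variance in both classes carry no sampling noise: the
    p-value is 1 when the class means agree and 0 when they differ.
    """
    x_tumor = np.atleast_2d(np.asarray(x_tumor, float))
    x_normal = np.atleast_2d(np.asarray(x_normal, float))
    if x_tumor.shape[1] < 2 or x_normal.shape[1] < 2:
        raise PipelineError("each class needs >= 2 samples for the Welch t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x_tumor, x_normal, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, float)
    degenerate = (x_tumor.var(axis=1) == 0) & (x_normal.var(axis=1) == 0)
    same_mean = np.isclose(x_tumor.mean(axis=1), x_normal.mean(axis=1))
    p[degenerate & same_mean] = 1.0
    p[degenerate & ~same_mean] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, in input order.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _equal_frequency_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into <= bins levels at empirical quantile edges."""
    x = np.asarray(x, float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def _entropy_bits(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(feature_values, labels, bins: int = DEFAULT_BINS) -> float:
    """Plug-in MI(G, L) = H(G) + H(L) - H(G, L) in bits.

    The feature is discretized by equal-frequency binning into at most
    ``bins`` levels; entropies use empirical plug-in probabilities with log
    base 2.  The result is clamped at >= 0 against rounding.
    """
    feature_values = np.asarray(feature_values, float)
    labels = np.asarray(labels)
    if feature_values.shape[0] != labels.shape[0]:
        raise ValueError("feature and labels must have the same length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    g = _equal_frequency_codes(feature_values, bins)
    _, l_codes = np.unique(labels, return_inverse=True)
    joint = g * (l_codes.max() + 1) + l_codes
    mi = _entropy_bits(g) + _entropy_bits(l_codes) - _entropy_bits(joint)
    return max(mi, 0.0)


# ------------------------------------------------------------------ estimators

class DifferentialExpressionSelector(SelectorMixin, BaseEstimator):
    """Select differentially expressed features by fold change and FDR.

    Expects ``X`` on the log2(1+CPM) scale, samples x features; ``y`` binary
    with 1 = tumor, 0 = normal.  Class means for the fold-change ratio are
    taken on the linear CPM scale.

    Attributes
    ----------
    results_ : pd.DataFrame
        Per-feature table: mean_tumor, mean_normal, fc, log2fc, pvalue,
        qvalue, significant.
    support_ : ndarray of bool
    """

    def __init__(
        self,
        fdr_threshold: float = DEFAULT_FDR,
        lfc_threshold: float = DEFAULT_LFC,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ):
        self.fdr_threshold = fdr_threshold
        self.lfc_threshold = lfc_threshold
        self.pseudocount = pseudocount

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("y must contain both classes coded 0/1")
        tum, nrm = X[y == 1], X[y == 0]
        mean_t = linear_cpm(tum).mean(axis=0)
        mean_n = linear_cpm(nrm).mean(axis=0)
        fc, log2fc = fold_change_from_means(mean_t, mean_n, self.pseudocount)
        pvals = welch_pvalues(tum.T, nrm.T)
        qvals = bh_adjust(pvals)
        significant = (qvals < self.fdr_threshold) & (
            np.abs(log2fc) > self.lfc_threshold
        )
        self.results_ = pd.DataFrame(
            {
                "mean_tumor": mean_t,
                "mean_normal": mean_n,
                "fc": fc,
                "log2fc": log2fc,
                "pvalue": pvals,
                "qvalue": qvals,
                "significant": significant,
            }
        )
        self.support_ = significant.to_numpy() if hasattr(significant, "to_numpy") else significant
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return np.asarray(self.support_, dtype=bool)


class MutualInfoSelector(SelectorMixin, BaseEstimator):
    """Keep the top-M features by mutual information with the label.

    Ties are broken by feature position for determinism; the dataframe-level
    :func:`rank_by_mi` additionally uses |log2 FC| and the gene symbol.
    """

    def __init__(self, top_m: int = DEFAULT_TOP_M, bins: int = DEFAULT_BINS):
        self.top_m = top_m
        self.bins = bins

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        mi = np.array(
            [mutual_information(X[:, j], y, self.bins) for j in range(X.shape[1])]
        )
        order = np.lexsort((np.arange(mi.size), -mi))
        keep = order[: min(self.top_m, mi.size)]
        self.mi_ = mi
        self.support_ = np.zeros(mi.size, dtype=bool)
        self.support_[keep] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return np.asarray(self.support_, dtype=bool)


# ---------------------------------------------------------- dataset-level API

@dataclass(frozen=True)
class MIRanking:
    """Top-M genes ranked by mutual information with the label, in bits."""

    entries: tuple  # of (gene, mi_bits, rank)
    M: int
    bins: int

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "mi_bits", "rank"])[
            ["rank", "gene", "mi_bits"]
        ]


def differential_expression(
    dataset: IntegrativeDataset,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene DE table over the integrative dataset (genes as index)."""
    sel = DifferentialExpressionSelector(fdr_threshold, lfc_threshold, pseudocount)
    sel.fit(dataset.X(), dataset.y())
    table = sel.results_.copy()
    table.index = pd.Index(dataset.genes, name="gene")
    return table


def fold_change(dataset: IntegrativeDataset, gene: str, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """(FC, log2 FC) for a single gene; linear-CPM class-mean ratio."""
    if gene not in dataset.values.index:
        raise KeyError(f"gene {gene!r} not in dataset")
    row = dataset.values.loc[gene].to_numpy()
    y = dataset.y()
    mean_t = linear_cpm(row[y == 1]).mean()
    mean_n = linear_cpm(row[y == 0]).mean()
    fc, lfc = fold_change_from_means(mean_t, mean_n, pseudocount)
    return float(fc), float(lfc)


def differential_pvalues(dataset: IntegrativeDataset) -> pd.Series:
    """Welch t-test p-value per gene on the normalized values."""
    y = dataset.y()
    vals = dataset.values.to_numpy()
    p = welch_pvalues(vals[:, y == 1], vals[:, y == 0])
    return pd.Series(p, index=dataset.values.index, name="pvalue")


def select_de_genes(
    results: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
    lfc_threshold: float = DEFAULT_LFC,
) -> list[str]:
    """Genes with q < fdr_threshold and |log2 FC| > lfc_threshold."""
    mask = (results["qvalue"] < fdr_threshold) & (
        results["log2fc"].abs() > lfc_threshold
    )
    survivors = list(results.index[mask])
    if not survivors:
        raise PipelineError(
            "no gene passes the FC/FDR thresholds; consider relaxing "
            f"fdr_threshold={fdr_threshold} or lfc_threshold={lfc_threshold}"
        )
    return survivors


def rank_by_mi(
    dataset: IntegrativeDataset,
    genes=None,
    M: int = DEFAULT_TOP_M,
    bins: int = DEFAULT_BINS,
    log2fc: pd.Series | None = None,
) -> MIRanking:
    """Rank genes by MI with the label and keep the top min(M, available).

    Ties are broken by larger |log2 FC| (when supplied) then by gene symbol,
    so the ranking is fully deterministic.
    """
    genes = list(genes) if genes is not None else dataset.genes
    if not genes:
        raise PipelineError("no genes to rank")
    y = dataset.y()
    mi = {
        g: mutual_information(dataset.values.loc[g].to_numpy(), y, bins)
        for g in genes
    }
    if log2fc is not None:
        sort_key = lambda g: (-mi[g], -abs(log2fc.get(g, 0.0)), g)
    else:
        sort_key = lambda g: (-mi[g], g)
    ranked = sorted(genes, key=sort_key)[: min(M, len(genes))]
    entries = tuple((g, mi[g], i + 1) for i, g in enumerate(ranked))
    return MIRanking(entries=entries, M=M, bins=bins)
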