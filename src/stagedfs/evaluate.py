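"""Repeated-split evaluation protocol and the weighted balanced accuracy.

The dataset is split ``n_rep`` times (default 10) into an 80% learning set
and a 20% held-out test set, and the learning set into a 60% training and a
40% validation subset, all stratified by label.  The model is fitted on the
training subset; its per-class accuracies on the validation subset, averaged
over the repetitions, become the class weights (w_normal, w_tumor).  On the
untouched test sets the usual confusion-matrix metrics are computed, plus the
weighted balanced accuracy

    balanced_acc = acc_normal * w_normal + acc_tumor * w_tumor

with the weights normalized to sum to 1 (the raw, unnormalized variant is
available via ``weight_mode="raw"``).  With equal normalized weights this
reduces exactly to macro-average recall, (SES + SPC) / 2.

Feature selection (fold change + FDR, then mutual information) is re-run
inside every repetition on the learning samples only, so the test set never
participates in any training or selection step.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ConfigError, PipelineError
from .integrate import IntegrativeDataset
from .model import (
    TunedGradientBoostingClassifier,
    baseline_classifier,
    make_gbdt,
)
from .optimize import history_to_rows
from .selection import (
    DifferentialExpressionSelector,
    MutualInfoSelector,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SES", "SPC", "PRC", "F1", "AUC", "balanced_acc")


# ------------------------------------------------------------------- splitting

@dataclass(frozen=True)
class RepetitionSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    @property
    def learning(self) -> np.ndarray:
        return np.sort(np.concatenate([self.train, self.validation]))


@dataclass(frozen=True)
class SplitPlan:
    repetitions: tuple[RepetitionSplit, ...]
    seed: int


def _check_two_class(y, idx, what: str) -> None:
    if len(np.unique(y[idx])) < 2:
        raise PipelineError(f"{what} lost a class during stratification")


def make_splits(
    labels,
    n_rep: int = 10,
    test_frac: float = 0.2,
    val_frac: float = 0.4,
    seed: int = 0,
    mode: str = "repeated",
) -> SplitPlan:
    """Stratified learning/test + train/validation splits for each repetition.

    ``mode="repeated"`` (default): n_rep independent splits of the full
    dataset.  ``mode="partition"``: the dataset is first cut into n_rep
    equal stratified parts and the scheme is applied within each part.
    """
    y = np.asarray(labels).astype(int)
    if not 0 < test_frac < 1 or not 0 < val_frac < 1:
        raise ConfigError("test_frac and val_frac must lie strictly in (0, 1)")
    if n_rep < 1:
        raise ConfigError("n_rep must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_rep + 1) % (2**31)

    if mode == "repeated":
        pools = [np.arange(y.size)] * n_rep
    elif mode == "partition":
        skf = StratifiedKFold(n_splits=n_rep, shuffle=True, random_state=int(seeds[-1]))
        pools = [part for _, part in skf.split(np.zeros(y.size), y)]
    else:
        raise ConfigError(f"unknown split mode {mode!r}")

    reps = []
    for r, pool in enumerate(pools):
        try:
            learn, test = train_test_split(
                pool,
                test_size=test_frac,
                stratify=y[pool],
                random_state=int(seeds[r]),
            )
            train, val = train_test_split(
                learn,
                test_size=val_frac,
                stratify=y[learn],
                random_state=int(seeds[r]),
            )
        except ValueError as exc:
            raise PipelineError(f"stratification failed in repetition {r}: {exc}")
        for name, idx in (("train", train), ("validation", val), ("test", test)):
            if idx.size == 0:
                raise PipelineError(f"{name} set empty in repetition {r}")
            _check_two_class(y, idx, f"{name} set (repetition {r})")
        reps.append(
            RepetitionSplit(
                train=np.sort(train), validation=np.sort(val), test=np.sort(test)
            )
        )
        assert not set(reps[-1].test) & set(reps[-1].learning)
        assert not set(reps[-1].train) & set(reps[-1].validation)
    return SplitPlan(repetitions=tuple(reps), seed=seed)


# --------------------------------------------------------------------- metrics

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with tumor (1) as the positive class."""
    y_true, y_pred = np.asarray(y_true).astype(int), np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (set(np.unique(y_true)) | set(np.unique(y_pred))) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def basic_metrics(counts: ConfusionCounts, scores=None, y_true=None) -> dict:
    """ACC, SES, SPC, PRC, F1 from the counts; AUC from the tumor scores."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    out = {
        "ACC": _ratio(tp + tn, counts.total, "ACC"),
        "SES": _ratio(tp, tp + fn, "SES"),
        "SPC": _ratio(tn, tn + fp, "SPC"),
        "PRC": _ratio(tp, tp + fp, "PRC"),
        "F1": _ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    }
    if scores is not None and y_true is not None and len(np.unique(y_true)) == 2:
        out["AUC"] = float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))
    else:
        out["AUC"] = float("nan")
    return out


@dataclass(frozen=True)
class ClassWeights:
    """Validation-derived per-class weights (raw and sum-to-one normalized)."""

    w_normal_raw: float
    w_tumor_raw: float

    def __post_init__(self) -> None:
        for w in (self.w_normal_raw, self.w_tumor_raw):
            if not 0.0 <= w <= 1.0:
                raise ValueError("raw weights must lie in [0, 1]")
        if self.w_normal_raw + self.w_tumor_raw == 0:
            raise ValueError("cannot normalize all-zero weights")

    @property
    def w_normal(self) -> float:
        return self.w_normal_raw / (self.w_normal_raw + self.w_tumor_raw)

    @property
    def w_tumor(self) -> float:
        return self.w_tumor_raw / (self.w_normal_raw + self.w_tumor_raw)


def class_weights(val_acc_normal, val_acc_tumor) -> ClassWeights:
    """Average the per-repetition validation accuracies into the weights."""
    return ClassWeights(
        w_normal_raw=float(np.mean(val_acc_normal)),
        w_tumor_raw=float(np.mean(val_acc_tumor)),
    )


def balanced_accuracy(
    acc_n: float, acc_t: float, weights: ClassWeights, mode: str = "normalized"
) -> float:
    """acc_n * w_normal + acc_t * w_tumor.

    With ``mode="normalized"`` the weights sum to 1, so the result stays in
    [0, 1] and equals (SES+SPC)/2 when the weights are equal; ``mode="raw"``
    uses the unnormalized validation accuracies as weights.
    """
    if mode == "normalized":
        return acc_n * weights.w_normal + acc_t * weights.w_tumor
    if mode == "raw":
        return acc_n * weights.w_normal_raw + acc_t * weights.w_tumor_raw
    raise ConfigError(f"unknown weight mode {mode!r}")


# ------------------------------------------------------------------- pipeline

@dataclass
class MetricsReport:
    """Per-repetition and aggregated metrics plus the weights and manifest."""

    per_repetition: pd.DataFrame
    aggregate: pd.DataFrame
    weights: ClassWeights
    manifest: dict = field(default_factory=dict, repr=False)

    def to_files(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "per_repetition": directory / "metrics_per_repetition.tsv",
            "aggregate": directory / "metrics_aggregate.tsv",
            "manifest": directory / "run_manifest.json",
        }
        self.per_repetition.rename_axis("repetition").to_csv(
            paths["per_repetition"], sep="\t"
        )
        self.aggregate.rename_axis("metric").to_csv(paths["aggregate"], sep="\t")
        manifest = dict(self.manifest)
        manifest["weights"] = {
            "w_normal_raw": self.weights.w_normal_raw,
            "w_tumor_raw": self.weights.w_tumor_raw,
            "w_normal": self.weights.w_normal,
            "w_tumor": self.weights.w_tumor,
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        if "optimization_history" in self.manifest:
            hist_path = directory / "optimization_history.tsv"
            pd.DataFrame(self.manifest["optimization_history"]).to_csv(
                hist_path, sep="\t", index=False
            )
            paths["optimization_history"] = hist_path
        return paths


def _per_class_accuracy(y_true, y_pred) -> tuple[float, float]:
    """(acc_normal, acc_tumor) on the given predictions."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    acc_n = float((y_pred[y_true == 0] == 0).mean())
    acc_t = float((y_pred[y_true == 1] == 1).mean())
    return acc_n, acc_t


def _select_features(dataset, learn_idx, config, rep_seed) -> tuple[list[str], dict]:
    """Run the configured selection stages on the learning samples only."""
    genes = list(dataset.genes)
    info: dict = {"genes_in": len(genes)}
    X = dataset.X()[learn_idx]
    y = dataset.y()[learn_idx]

    if config.panel:
        panel = [g for g in config.panel if g in set(genes)]
        if not panel:
            raise PipelineError("no panel gene is present in the dataset")
        info["panel_genes"] = len(panel)
        return sorted(panel), info

    if config.case >= 2:
        de = DifferentialExpressionSelector(
            fdr_threshold=config.fdr_threshold, lfc_threshold=config.lfc_threshold
        ).fit(X, y)
        mask = de._get_support_mask()
        if not mask.any():
            raise PipelineError("no gene passes the FC/FDR thresholds")
        genes = [g for g, keep in zip(genes, mask) if keep]
        X = X[:, mask]
        info["genes_after_de"] = len(genes)

    if config.case >= 3:
        mi = MutualInfoSelector(top_m=config.top_m, bins=config.mi_bins).fit(X, y)
        mask = mi._get_support_mask()
        genes = [g for g, keep in zip(genes, mask) if keep]
        info["genes_after_mi"] = len(genes)

    return genes, info


def evaluate_pipeline(dataset: IntegrativeDataset, config) -> MetricsReport:
    """Run the full repeated-split protocol and aggregate the metrics.

    ``config`` is a :class:`~stagedfs.config.PipelineConfig`; its ``case``
    selects the stage subset (1: classifier only, 2: +FC/FDR, 3: +MI,
    4: +Bayesian-optimized GBDT) and ``classifier`` may swap in a fixed
    baseline (SVM/KNN/RF) in place of the GBDT.
    """
    y_all = dataset.y()
    plan = make_splits(
        y_all,
        n_rep=config.n_rep,
        test_frac=config.test_frac,
        val_frac=config.val_frac,
        seed=config.seed,
        mode=config.split_mode,
    )
    rep_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_rep) % (
        2**31
    )
    gene_index = {g: i for i, g in enumerate(dataset.genes)}
    X_all = dataset.X()

    rows, val_n, val_t = [], [], []
    rep_infos, histories = [], []
    for r, split in enumerate(plan.repetitions):
        rep_seed = int(rep_seeds[r])
        genes, info = _select_features(dataset, split.learning, config, rep_seed)
        cols = [gene_index[g] for g in genes]
        Xl = X_all[:, cols]

        if config.classifier in ("SVM", "KNN", "RF"):
            clf = baseline_classifier(config.classifier, seed=rep_seed)
        elif config.case == 4:
            # tune on the same sample scale the final model is fitted at, so
            # the CV objective cannot favour points that degenerate there
            tune_idx = (
                split.train if config.tune_scope == "train" else split.learning
            )
            tuned = TunedGradientBoostingClassifier(
                n_iter=config.n_iter,
                k=config.cv_folds,
                method=config.optimizer,
                space=config.space,
                objective_metric=config.objective_metric,
                random_state=rep_seed,
            )
            tuned.fit(Xl[tune_idx], y_all[tune_idx])
            info["best_params"] = tuned.best_params_
            info["best_cv_loss"] = tuned.best_loss_
            histories.extend(
                {"repetition": r, **row} for row in history_to_rows(tuned.history_)
            )
            clf = make_gbdt(tuned.best_params_, seed=rep_seed)
        else:
            clf = make_gbdt(seed=rep_seed)

        clf.fit(Xl[split.train], y_all[split.train])
        acc_n_val, acc_t_val = _per_class_accuracy(
            y_all[split.validation], clf.predict(Xl[split.validation])
        )
        val_n.append(acc_n_val)
        val_t.append(acc_t_val)

        y_test = y_all[split.test]
        y_pred = clf.predict(Xl[split.test])
        if hasattr(clf, "predict_proba"):
            scores = clf.predict_proba(Xl[split.test])[:, list(clf.classes_).index(1)]
        else:
            scores = clf.decision_function(Xl[split.test])
        counts = confusion(y_test, y_pred)
        metrics = basic_metrics(counts, scores=scores, y_true=y_test)
        acc_n, acc_t = _per_class_accuracy(y_test, y_pred)
        rows.append(
            {
                **metrics,
                "acc_n": acc_n,
                "acc_t": acc_t,
                "val_acc_n": acc_n_val,
                "val_acc_t": acc_t_val,
                "n_features": len(genes),
            }
        )
        info["selected_genes"] = genes
        rep_infos.append(info)
        logger.info("repetition %d: ACC=%.4f, %d features", r, metrics["ACC"], len(genes))

    weights = class_weights(val_n, val_t)
    per_rep = pd.DataFrame(rows)
    per_rep["balanced_acc"] = [
        balanced_accuracy(row["acc_n"], row["acc_t"], weights, config.weight_mode)
        for _, row in per_rep.iterrows()
    ]
    metric_cols = list(METRIC_NAMES) + ["acc_n", "acc_t"]
    aggregate = pd.DataFrame(
        {
            "mean": per_rep[metric_cols].mean(),
            "variance": per_rep[metric_cols].var(ddof=1) if config.n_rep > 1
            else per_rep[metric_cols].var(ddof=0),
        }
    )
    manifest = {
        "config": config.to_dict(),
        "repetitions": rep_infos,
        "provenance": dataset.provenance,
    }
    if histories:
        manifest["optimization_history"] = histories
    return MetricsReport(
        per_repetition=per_rep, aggregate=aggregate, weights=weights, manifest=manifest
    )
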