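"""Pipeline configuration: defaults, file loading, flag overrides, validation.

Defaults are the method's operating point: mutation-frequency threshold
p = 1%, FDR < 0.05, |log2 FC| > 1, top M = 50 features, 300 optimizer
iterations against a fivefold CV loss, and 10 evaluation repetitions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .optimize import HyperparamSpace, ParamRange

_RANGES = {
    "freq_threshold": (0.0, 1.0, "excl_lo"),
    "fdr_threshold": (0.0, 1.0, "excl_lo"),
    "lfc_threshold": (0.0, float("inf"), "incl"),
    "min_cpm": (0.0, float("inf"), "incl"),
    "min_sample_frac": (0.0, 1.0, "incl"),
    "test_frac": (0.0, 1.0, "excl"),
    "val_frac": (0.0, 1.0, "excl"),
}


@dataclass
class PipelineConfig:
    # data paths
    maf: str | None = None
    expression: str | None = None
    labels: str | None = None
    panel_file: str | None = None
    outdir: str = "stagedfs_out"
    # stage thresholds
    freq_threshold: float = 0.01
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0
    top_m: int = 50
    mi_bins: int = 10
    min_cpm: float = 1.0
    min_sample_frac: float = 0.1
    prefix_len: int = 12
    # optimizer
    n_iter: int = 300
    cv_folds: int = 5
    optimizer: str = "tpe"
    objective_metric: str = "accuracy"
    tune_scope: str = "train"
    space: HyperparamSpace = field(default_factory=HyperparamSpace)
    # evaluation protocol
    n_rep: int = 10
    test_frac: float = 0.2
    val_frac: float = 0.4
    weight_mode: str = "normalized"
    split_mode: str = "repeated"
    case: int = 4
    classifier: str = "gbdt"
    seed: int = 0
    # resolved panel gene list (loaded from panel_file)
    panel: list[str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key, (lo, hi, kind) in _RANGES.items():
            v = getattr(self, key)
            ok = lo <= v <= hi
            if kind == "excl":
                ok = lo < v < hi
            elif kind == "excl_lo":
                ok = lo < v <= hi
            if not ok:
                raise ConfigError(f"config key {key}={v} is out of range")
        for key in ("top_m", "mi_bins", "n_iter", "cv_folds", "n_rep"):
            v = getattr(self, key)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"config key {key}={v} must be a positive integer")
        if self.mi_bins < 2:
            raise ConfigError("mi_bins must be >= 2")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.optimizer not in ("tpe", "random"):
            raise ConfigError(f"optimizer must be 'tpe' or 'random', got {self.optimizer!r}")
        if self.objective_metric not in ("accuracy", "balanced_accuracy"):
            raise ConfigError(
                f"objective_metric must be 'accuracy' or 'balanced_accuracy'"
            )
        if self.tune_scope not in ("train", "learning"):
            raise ConfigError("tune_scope must be 'train' or 'learning'")
        if self.weight_mode not in ("normalized", "raw"):
            raise ConfigError(f"weight_mode must be 'normalized' or 'raw'")
        if self.split_mode not in ("repeated", "partition"):
            raise ConfigError(f"split_mode must be 'repeated' or 'partition'")
        if self.case not in (1, 2, 3, 4):
            raise ConfigError(f"case must be 1-4, got {self.case}")
        if self.classifier not in ("gbdt", "SVM", "KNN", "RF"):
            raise ConfigError(f"unknown classifier {self.classifier!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["space"] = {
            name: {"low": pr.low, "high": pr.high, "kind": pr.kind}
            for name, pr in self.space.items()
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _space_from_dict(d: dict) -> HyperparamSpace:
    kwargs = {}
    for name, spec in d.items():
        try:
            kwargs[name] = ParamRange(spec["low"], spec["high"], spec.get("kind", "uniform"))
        except (TypeError, KeyError, ValueError) as exc:
            raise ConfigError(f"invalid space entry for {name!r}: {exc}")
    try:
        return HyperparamSpace(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"unknown hyperparameter in space: {exc}")


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file; keyword flags override it."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    if isinstance(data.get("space"), dict):
        data["space"] = _space_from_dict(data["space"])
    try:
        config = PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc))

    if config.panel_file and config.panel is None:
        lines = Path(config.panel_file).read_text().splitlines()
        config.panel = [ln.strip() for ln in lines if ln.strip()]
        if not config.panel:
            raise ConfigError(f"panel file {config.panel_file} lists no genes")
    return config
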