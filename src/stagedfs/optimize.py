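"""Hyperparameter search: random search and a Tree-structured Parzen Estimator.

The TPE here is the classic sequential model-based scheme: after a handful of
random startup trials, the history is split at a loss quantile into "good"
and "bad" sets; candidate points are drawn from a per-dimension kernel
density over the good set and scored by the density ratio l(x)/g(x), and the
best-scoring candidate is evaluated next.  Dimensions are treated
independently (each is a 1-D Parzen window over its transformed axis:
log-space for log-uniform parameters, integer rounding for integer ones).

Both optimizers are fully deterministic given the seed, record every trial,
and tolerate objective failures (a failed trial is kept in the history with
an infinite loss and skipped when choosing the best).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_N_STARTUP = 10     # random trials before the Parzen model kicks in
_N_CANDIDATES = 24  # candidate draws scored per TPE iteration
_GAMMA = 0.25       # quantile of the history treated as "good"


@dataclass(frozen=True)
class ParamRange:
    low: float
    high: float
    kind: str = "uniform"  # uniform | loguniform | int

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"empty range [{self.low}, {self.high}]")
        if self.kind == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform range must be positive")
        if self.kind not in ("uniform", "loguniform", "int"):
            raise ValueError(f"unknown kind {self.kind!r}")

    # transformed axis on which sampling / KDE happens
    def to_axis(self, value: float) -> float:
        return math.log(value) if self.kind == "loguniform" else float(value)

    def from_axis(self, z: float) -> float:
        lo, hi = self.to_axis(self.low), self.to_axis(self.high)
        z = min(max(z, lo), hi)
        v = math.exp(z) if self.kind == "loguniform" else z
        if self.kind == "int":
            return int(round(min(max(v, self.low), self.high)))
        return float(min(max(v, self.low), self.high))

    def sample(self, rng: np.random.Generator) -> float:
        lo, hi = self.to_axis(self.low), self.to_axis(self.high)
        return self.from_axis(rng.uniform(lo, hi))


@dataclass(frozen=True)
class HyperparamSpace:
    """Search box for the gradient-boosting hyperparameters.

    Default bounds are wide enough to contain the printed best points of both
    optimizers in the source experiments; all bounds are configurable.
    """

    learning_rate: ParamRange = field(
        default_factory=lambda: ParamRange(0.01, 1.0, "loguniform")
    )
    max_depth: ParamRange = field(default_factory=lambda: ParamRange(3, 50, "int"))
    min_samples_leaf: ParamRange = field(
        default_factory=lambda: ParamRange(1, 100, "int")
    )
    min_samples_split: ParamRange = field(
        default_factory=lambda: ParamRange(2, 100, "int")
    )
    n_estimators: ParamRange = field(
        default_factory=lambda: ParamRange(50, 500, "int")
    )
    subsample: ParamRange = field(
        default_factory=lambda: ParamRange(0.5, 1.0, "uniform")
    )

    def items(self):
        return [(f, getattr(self, f)) for f in (
            "learning_rate", "max_depth", "min_samples_leaf",
            "min_samples_split", "n_estimators", "subsample",
        )]

    def sample(self, rng: np.random.Generator) -> dict:
        return {name: rng_range.sample(rng) for name, rng_range in self.items()}


@dataclass(frozen=True)
class Trial:
    params: dict
    cv_loss: float
    iteration: int
    status: str = "ok"  # ok | failed


def _evaluate(objective, params, iteration) -> Trial:
    try:
        loss = float(objective(params))
        if not math.isfinite(loss):
            raise ValueError(f"non-finite loss {loss}")
        return Trial(params=params, cv_loss=loss, iteration=iteration)
    except Exception as exc:  # failed trials are recorded, not fatal
        logger.warning("trial %d failed: %s", iteration, exc)
        return Trial(params=params, cv_loss=math.inf, iteration=iteration, status="failed")


def _best(history: list[Trial]) -> Trial:
    ok = [t for t in history if t.status == "ok"]
    if not ok:
        raise RuntimeError("every trial failed")
    return min(ok, key=lambda t: (t.cv_loss, t.iteration))


def random_search(space: HyperparamSpace, objective, n_iter: int = 300, seed: int = 0):
    """Uniform independent sampling over the space; returns (best, history)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    history = [_evaluate(objective, space.sample(rng), i) for i in range(n_iter)]
    return _best(history), history


def _parzen_logpdf(z: float, points: np.ndarray, bandwidth: float, lo: float, hi: float) -> float:
    """Log density of a Gaussian Parzen mixture plus a uniform prior component."""
    kernels = np.exp(-0.5 * ((z - points) / bandwidth) ** 2) / (
        bandwidth * math.sqrt(2 * math.pi)
    )
    uniform = 1.0 / (hi - lo)
    dens = (kernels.sum() + uniform) / (len(points) + 1)
    return math.log(max(dens, 1e-300))


def tpe_optimize(space: HyperparamSpace, objective, n_iter: int = 300, seed: int = 0):
    """Tree-structured Parzen Estimator minimization; returns (best, history)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    dims = space.items()
    history: list[Trial] = []

    for i in range(n_iter):
        ok = [t for t in history if t.status == "ok"]
        # keep exploring while the history carries no signal: too few trials,
        # or every observed loss identical (nothing to split into good/bad)
        no_signal = len({t.cv_loss for t in ok}) < 2
        if i < _N_STARTUP or no_signal:
            params = space.sample(rng)
        else:
            n_good = max(1, int(math.ceil(_GAMMA * len(ok))))
            ranked = sorted(ok, key=lambda t: t.cv_loss)
            good, bad = ranked[:n_good], ranked[n_good:] or ranked[:n_good]
            best_score, params = -math.inf, None
            for _ in range(_N_CANDIDATES):
                cand, score = {}, 0.0
                for name, pr in dims:
                    lo, hi = pr.to_axis(pr.low), pr.to_axis(pr.high)
                    g_pts = np.array([pr.to_axis(t.params[name]) for t in good])
                    b_pts = np.array([pr.to_axis(t.params[name]) for t in bad])
                    bw = max((hi - lo) / max(len(g_pts), 1) ** 0.5, 1e-3 * (hi - lo))
                    # draw from the good-set mixture (or the uniform prior arm)
                    if rng.random() < 1.0 / (len(g_pts) + 1):
                        z = rng.uniform(lo, hi)
                    else:
                        z = rng.choice(g_pts) + bw * rng.standard_normal()
                        z = min(max(z, lo), hi)
                    v = pr.from_axis(z)
                    z = pr.to_axis(v)  # re-snap so ints score where they land
                    score += _parzen_logpdf(z, g_pts, bw, lo, hi) - _parzen_logpdf(
                        z, b_pts, bw, lo, hi
                    )
                    cand[name] = v
                if score > best_score:
                    best_score, params = score, cand
        history.append(_evaluate(objective, params, i))

    return _best(history), history


def best_so_far(history: list[Trial]) -> list[float]:
    """Running minimum of the loss over iterations (failed trials skipped)."""
    out, cur = [], math.inf
    for t in history:
        if t.status == "ok":
            cur = min(cur, t.cv_loss)
        out.append(cur)
    return out


def history_to_rows(history: list[Trial]) -> list[dict]:
    rows = []
    for t in history:
        row = {"iteration": t.iteration, **t.params, "cv_loss": t.cv_loss, "status": t.status}
        rows.append(row)
    return rows
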