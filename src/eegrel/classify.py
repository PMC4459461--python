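"""SVM-RBF classification of rhythm features with PSO hyperparameter tuning.

The classifier contract is the textbook soft-margin SVM with a Gaussian
kernel K(x, y) = exp(-||x - y||^2 / (2 sigma^2)); the quadratic program
is delegated to scikit-learn's SVC (``gamma = 1 / (2 sigma^2)``).
Multi-class problems use an explicit one-against-all scheme, which with
two classes reduces to the plain binary decision.

Hyperparameters (penalty c, kernel dispersion sigma) are tuned by a
global-best particle swarm in log10 space over a bounded box.  The
tuning objective is validation accuracy on an inner stratified 70/30
split of the training fold only — test labels never reach the tuner.

Evaluation follows the repeated stratified 70/30 hold-out protocol
(10 repetitions by default) and reports accuracy, sensitivity and
specificity per repetition plus their mean and standard deviation;
sensitivity treats the pathological (seizure) class as positive.
A k-nearest-neighbour baseline (k = 3 by default) runs under the same
protocol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import ConfigError, OptimizationFailureError
from .features import ObservationMatrix

logger = logging.getLogger(__name__)

#: Labels recognized as the pathological (positive) class, in priority order.
_POSITIVE_CANDIDATES = ("ictal", "seizure", "E")

#: Classification scenarios: rhythm bands added in decreasing relevance order.
SCENARIO_BANDS = {
    1: ("delta",),
    2: ("delta", "theta"),
    3: ("delta", "theta", "alpha"),
    4: ("delta", "theta", "alpha", "beta"),
}


@dataclass(frozen=True)
class PsoConfig:
    """Global-best particle swarm settings (inertia + cognitive + social)."""

    swarm_size: int = 30
    iterations: int = 50
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    bounds_c: tuple[float, float] = (1e-2, 1e3)
    bounds_sigma: tuple[float, float] = (1e-2, 1e2)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.bounds_c, self.bounds_sigma):
            if not (0 < lo < hi):
                raise ConfigError(f"bounds must satisfy 0 < low < high, got ({lo}, {hi})")


@dataclass(frozen=True)
class SvmConfig:
    """SVM-RBF settings: penalty c, dispersion sigma, and the PSO tuner."""

    c: float = 1.0
    sigma: float = 1.0
    pso: PsoConfig = field(default_factory=PsoConfig)
    one_against_all: bool = True

    def __post_init__(self) -> None:
        if self.c <= 0 or self.sigma <= 0:
            raise ConfigError("c and sigma must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts plus overall correct/total tallies."""

    n_tp: int
    n_fn: int
    n_tn: int
    n_fp: int
    n_c: int | None = None  # correctly classified patterns (overall)
    n_t: int | None = None  # total patterns

    def resolved(self) -> "ConfusionCounts":
        n_c = self.n_c if self.n_c is not None else self.n_tp + self.n_tn
        n_t = self.n_t if self.n_t is not None else (
            self.n_tp + self.n_fn + self.n_tn + self.n_fp
        )
        return ConfusionCounts(self.n_tp, self.n_fn, self.n_tn, self.n_fp, n_c, n_t)


@dataclass
class MetricValues:
    """Accuracy / sensitivity / specificity in percent, with their counts."""

    a_ac: float
    a_se: float
    a_sp: float
    counts: ConfusionCounts


def compute_metrics(counts: ConfusionCounts) -> MetricValues:
    """Accuracy, sensitivity, specificity (percent) from confusion counts.

    a_ac = 100 N_c / N_T; a_se = 100 N_TP / (N_TP + N_FN);
    a_sp = 100 N_TN / (N_TN + N_FP).  An undefined ratio (zero
    denominator) is reported as NaN with a warning.
    """
    c = counts.resolved()
    if min(c.n_tp, c.n_fn, c.n_tn, c.n_fp) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if c.n_t == 0:
        raise ConfigError("empty evaluation: N_T is zero")
    a_ac = 100.0 * c.n_c / c.n_t
    a_se = _safe_rate(c.n_tp, c.n_tp + c.n_fn, "sensitivity")
    a_sp = _safe_rate(c.n_tn, c.n_tn + c.n_fp, "specificity")
    return MetricValues(a_ac=a_ac, a_se=a_se, a_sp=a_sp, counts=c)


def _safe_rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return 100.0 * num / den


@dataclass
class ClassMetrics:
    """Per-repetition metrics and their mean +/- std over repetitions."""

    per_rep: list[MetricValues]
    positive_label: str

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(m, attr) for m in self.per_rep])

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self._vals("a_ac")))

    @property
    def std_accuracy(self) -> float:
        return float(np.nanstd(self._vals("a_ac")))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self._vals("a_se")))

    @property
    def std_sensitivity(self) -> float:
        return float(np.nanstd(self._vals("a_se")))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self._vals("a_sp")))

    @property
    def std_specificity(self) -> float:
        return float(np.nanstd(self._vals("a_sp")))

    def summary(self) -> dict[str, float]:
        return {
            "a_ac_mean": self.mean_accuracy,
            "a_ac_std": self.std_accuracy,
            "a_se_mean": self.mean_sensitivity,
            "a_se_std": self.std_sensitivity,
            "a_sp_mean": self.mean_specificity,
            "a_sp_std": self.std_specificity,
            "reps": len(self.per_rep),
        }


def pso_tune(
    objective: Callable[[float, float], float],
    config: PsoConfig | None = None,
) -> tuple[float, float]:
    """Maximize ``objective(c, sigma)`` with a global-best particle swarm.

    The search runs in log10 space over the configured box; positions are
    clamped to the bounds and velocities to the box width.  Deterministic
    given ``config.seed``.  Raises if no sampled point ever yields a
    finite objective.
    """
    cfg = config or PsoConfig()
    rng = np.random.default_rng(cfg.seed)
    lo = np.log10([cfg.bounds_c[0], cfg.bounds_sigma[0]])
    hi = np.log10([cfg.bounds_c[1], cfg.bounds_sigma[1]])
    span = hi - lo

    def evaluate(pos: np.ndarray) -> float:
        val = objective(10.0 ** pos[0], 10.0 ** pos[1])
        return val if np.isfinite(val) else -np.inf

    pos = lo + rng.random((cfg.swarm_size, 2)) * span
    vel = (rng.random((cfg.swarm_size, 2)) - 0.5) * span
    pbest = pos.copy()
    pbest_val = np.array([evaluate(p) for p in pos])
    g_idx = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g_idx].copy(), pbest_val[g_idx]

    for _ in range(cfg.iterations):
        r1 = rng.random((cfg.swarm_size, 2))
        r2 = rng.random((cfg.swarm_size, 2))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - pos)
            + cfg.social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -span, span)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(cfg.swarm_size):
            val = evaluate(pos[i])
            if val > pbest_val[i]:
                pbest[i], pbest_val[i] = pos[i].copy(), val
                if val > gbest_val:
                    gbest, gbest_val = pos[i].copy(), val
    if not np.isfinite(gbest_val):
        raise OptimizationFailureError("objective was non-finite at every sampled point")
    return float(10.0 ** gbest[0]), float(10.0 ** gbest[1])


def make_svm(c: float, sigma: float, one_against_all: bool = True):
    """SVC with K(x,y) = exp(-||x-y||^2 / (2 sigma^2)), optionally one-vs-all."""
    svc = SVC(C=c, kernel="rbf", gamma=1.0 / (2.0 * sigma**2))
    return OneVsRestClassifier(svc) if one_against_all else svc


def _resolve_positive(labels: Sequence[str], positive_label: str | None) -> str:
    uniq = sorted(set(labels))
    if positive_label is not None:
        if positive_label not in uniq:
            raise ConfigError(f"positive label {positive_label!r} not among {uniq}")
        return positive_label
    for cand in _POSITIVE_CANDIDATES:
        if cand in uniq:
            return cand
    return uniq[-1]


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive_label: str
) -> ConfusionCounts:
    """Confusion counts with the pathological class as positive.

    For more than two classes, sensitivity/specificity counts collapse to
    positive-vs-rest while N_c / N_T keep full multi-class correctness.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        n_tp=int(np.sum(pos_t & pos_p)),
        n_fn=int(np.sum(pos_t & ~pos_p)),
        n_tn=int(np.sum(~pos_t & ~pos_p)),
        n_fp=int(np.sum(~pos_t & pos_p)),
        n_c=int(np.sum(y_true == y_pred)),
        n_t=int(y_true.size),
    )


def _feature_rows(X) -> np.ndarray:
    if isinstance(X, ObservationMatrix):
        return X.X.T.copy()
    return np.asarray(X, dtype=float)


def _check_classes(y: np.ndarray) -> None:
    uniq, counts = np.unique(y, return_counts=True)
    if uniq.size < 2:
        raise ConfigError("need at least 2 classes")
    if counts.min() < 2:
        raise ConfigError(
            f"class {uniq[np.argmin(counts)]!r} has fewer than 2 objects; "
            "stratified 70/30 splitting is impossible"
        )


def _tuning_objective(
    X_train: np.ndarray, y_train: np.ndarray, one_against_all: bool, seed: int
) -> Callable[[float, float], float]:
    X_in, X_val, y_in, y_val = train_test_split(
        X_train, y_train, train_size=0.7, stratify=y_train, random_state=seed % (2**31)
    )

    def objective(c: float, sigma: float) -> float:
        model = make_svm(c, sigma, one_against_all)
        model.fit(X_in, y_in)
        return float(np.mean(model.predict(X_val) == y_val))

    return objective


def cross_validate(
    X,
    labels: Sequence[str],
    config: SvmConfig | None = None,
    reps: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    tune: bool = True,
    positive_label: str | None = None,
) -> ClassMetrics:
    """Repeated stratified hold-out evaluation of the PSO-tuned SVM.

    ``X`` is an :class:`ObservationMatrix` or an (M, d) feature array.
    Each repetition draws a stratified ``train_fraction`` split, tunes
    (c, sigma) on the training fold only, fits, and scores the held-out
    fold.  Deterministic given ``seed``.
    """
    cfg = config or SvmConfig()
    Xf = _feature_rows(X)
    y = np.asarray(labels)
    if Xf.shape[0] != y.size:
        raise ConfigError(f"{Xf.shape[0]} feature rows vs {y.size} labels")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError("train_fraction must lie in (0, 1)")
    _check_classes(y)
    pos = _resolve_positive(y, positive_label)

    splitter = StratifiedShuffleSplit(
        n_splits=reps, train_size=train_fraction, random_state=seed % (2**31)
    )
    per_rep: list[MetricValues] = []
    for rep, (tr, te) in enumerate(splitter.split(Xf, y)):
        if tune:
            objective = _tuning_objective(
                Xf[tr], y[tr], cfg.one_against_all, seed + 1000 * rep + 1
            )
            pso_cfg = PsoConfig(
                **{**cfg.pso.__dict__, "seed": cfg.pso.seed + rep}
            )
            c, sigma = pso_tune(objective, pso_cfg)
        else:
            c, sigma = cfg.c, cfg.sigma
        model = make_svm(c, sigma, cfg.one_against_all)
        model.fit(Xf[tr], y[tr])
        pred = model.predict(Xf[te])
        counts = confusion_from_predictions(y[te], pred, pos)
        per_rep.append(compute_metrics(counts))
        logger.info(
            "rep %d: c=%.4g sigma=%.4g acc=%.2f%%", rep, c, sigma, per_rep[-1].a_ac
        )
    return ClassMetrics(per_rep=per_rep, positive_label=pos)


def knn_fit_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int = 3
) -> np.ndarray:
    """Plain k-nearest-neighbour prediction (Euclidean, majority vote)."""
    model = KNeighborsClassifier(n_neighbors=k)
    model.fit(X_train, y_train)
    return model.predict(X_test)


def knn_baseline(
    X,
    labels: Sequence[str],
    k: int = 3,
    reps: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    positive_label: str | None = None,
) -> ClassMetrics:
    """k-NN under the same repeated stratified hold-out protocol (k=3 default)."""
    Xf = _feature_rows(X)
    y = np.asarray(labels)
    if Xf.shape[0] != y.size:
        raise ConfigError(f"{Xf.shape[0]} feature rows vs {y.size} labels")
    _check_classes(y)
    pos = _resolve_positive(y, positive_label)
    splitter = StratifiedShuffleSplit(
        n_splits=reps, train_size=train_fraction, random_state=seed % (2**31)
    )
    per_rep = []
    for tr, te in splitter.split(Xf, y):
        pred = knn_fit_predict(Xf[tr], y[tr], Xf[te], k=k)
        per_rep.append(compute_metrics(confusion_from_predictions(y[te], pred, pos)))
    return ClassMetrics(per_rep=per_rep, positive_label=pos)


def select_scenario(
    om: ObservationMatrix,
    scenario: int,
    ranking: Sequence[str] | None = None,
) -> ObservationMatrix:
    """Restrict features to the first ``scenario`` rhythms of a ranking.

    The default ranking is the canonical decreasing-relevance order for
    seizure problems (delta; delta+theta; delta+theta+alpha; all four);
    pass an explicit ``ranking`` — e.g. from a relevance fit — to
    override.
    """
    if scenario not in SCENARIO_BANDS:
        raise ConfigError(f"scenario must be 1-4, got {scenario}")
    bands = list(ranking)[:scenario] if ranking is not None else list(
        SCENARIO_BANDS[scenario]
    )
    return om.select(bands=bands)
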