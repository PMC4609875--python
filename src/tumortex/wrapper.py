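"""Wrapper feature selection: agents encode a feature subset + SVM hyperparameters.

An agent position of length n_features + 2 decodes to a binary feature mask
(coordinates above 0.5 are on) and, from the last two coordinates, the SVM
regularization C and RBF width σ on log-uniform ranges. The fitness rewards
cross-validated SVM accuracy and parsimony:

    fitness = θ · accuracy + (1 − θ) / n_selected,   θ = 0.7 by default,

maximized (negated internally for the minimizing search engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gsa import GSAConfig, OptimizeResult, optimize

DEFAULT_C_RANGE = (0.1, 100.0)
DEFAULT_SIGMA_RANGE = (0.1, 10.0)
DEFAULT_THETA = 0.7


@dataclass
class FeatureMask:
    """A decoded agent: binary feature subset plus (C, σ)."""

    mask: np.ndarray
    C: float
    sigma: float

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected_names(self, names) -> list[str]:
        return [n for n, m in zip(names, self.mask) if m]


def _log_decode(u: float, lo: float, hi: float) -> float:
    return float(10 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo))))


def decode_agent(
    position: np.ndarray,
    n_features: int,
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
) -> FeatureMask:
    """Decode a position in [0,1]^(n_features+2) into a FeatureMask.

    An all-off mask is repaired by switching on the feature with the highest
    coordinate, so every candidate is a valid classifier input.
    """
    position = np.asarray(position, dtype=float)
    if position.size != n_features + 2:
        raise ValueError(
            f"position length {position.size} != n_features + 2 = {n_features + 2}"
        )
    mask = position[:n_features] > 0.5
    if not mask.any():
        mask = np.zeros(n_features, dtype=bool)
        mask[int(np.argmax(position[:n_features]))] = True
    C = _log_decode(position[n_features], *c_range)
    sigma = _log_decode(position[n_features + 1], *sigma_range)
    return FeatureMask(mask=mask, C=C, sigma=sigma)


def cv_accuracy(
    mask: FeatureMask, X: np.ndarray, y: np.ndarray, n_splits: int = 5
) -> float:
    """Stratified k-fold cross-validated accuracy of the decoded SVM.

    Features are z-scored inside each training fold (the texture features
    span several orders of magnitude, and the RBF kernel needs commensurate
    scales for σ to be meaningful).
    """
    Xm = X[:, mask.mask]
    n_splits = min(n_splits, int(np.bincount((np.asarray(y) > 0).astype(int)).min()))
    if n_splits < 2:
        return 0.0
    clf = make_pipeline(
        StandardScaler(),
        SVC(C=mask.C, kernel="rbf", gamma=1.0 / (2.0 * mask.sigma**2)),
    )
    cv = StratifiedKFold(n_splits=n_splits, shuffle=False)
    try:
        return float(cross_val_score(clf, Xm, y, cv=cv).mean())
    except Exception:
        return 0.0


def wrapper_fitness(
    mask: FeatureMask,
    X: np.ndarray,
    y: np.ndarray,
    theta: float = DEFAULT_THETA,
    n_splits: int = 5,
    accuracy: float | None = None,
) -> float:
    """θ·accuracy + (1−θ)/n_selected (larger is better).

    ``accuracy`` may be supplied directly (e.g. for closed-form checks);
    otherwise it is the stratified CV accuracy of the decoded SVM.
    """
    if mask.n_selected < 1:
        raise ValueError("empty feature mask")
    if accuracy is None:
        accuracy = cv_accuracy(mask, X, y, n_splits=n_splits)
    return theta * accuracy + (1.0 - theta) / mask.n_selected


@dataclass
class SelectionResult:
    """Outcome of a wrapper-selection run."""

    mask: FeatureMask
    fitness: float  # wrapper fitness of the best agent (maximization scale)
    history: np.ndarray  # best-so-far wrapper fitness per iteration
    raw: OptimizeResult


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    config: GSAConfig | None = None,
    theta: float = DEFAULT_THETA,
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    n_splits: int = 5,
    seed: int | None = None,
) -> SelectionResult:
    """Run (R)GSA over feature subsets and SVM hyperparameters simultaneously."""
    if config is None:
        config = GSAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]

    cache: dict[tuple, float] = {}

    def objective(position: np.ndarray) -> float:
        fm = decode_agent(position, n_features, c_range, sigma_range)
        key = (fm.mask.tobytes(), round(fm.C, 6), round(fm.sigma, 6))
        if key not in cache:
            cache[key] = wrapper_fitness(fm, X, y, theta=theta, n_splits=n_splits)
        return -cache[key]

    res = optimize(objective, n_features + 2, config, seed=seed)
    best_mask = decode_agent(res.position, n_features, c_range, sigma_range)
    return SelectionResult(
        mask=best_mask, fitness=-res.fitness, history=-res.history, raw=res
    )
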