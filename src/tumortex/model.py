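"""Model/Results interface binding wrapper selection and LOO evaluation.

``FeatureSelectionSVM`` is built from a labeled feature matrix (or a feature
table DataFrame); ``fit()`` runs the gravitational-search wrapper to pick a
feature subset and SVM hyperparameters simultaneously, then scores the
selected model by leave-one-out cross-validation. The returned results object
carries the selected features, (C, σ), fitness history, the held-out
evaluation report and a ``summary()`` table; plotting hangs off the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import EvalReport, SVMSettings, loo_evaluate
from .gsa import GSAConfig
from .wrapper import (
    DEFAULT_C_RANGE,
    DEFAULT_SIGMA_RANGE,
    DEFAULT_THETA,
    FeatureMask,
    SelectionResult,
    select_features,
)


class FeatureSelectionSVM:
    """Texture-based lesion classifier with built-in wrapper feature selection.

    Parameters
    ----------
    X : (n, d) feature matrix
    y : labels in {+1, −1} (+1 = malignant)
    feature_names : optional column names, defaulting to x0..x{d-1}
    """

    def __init__(self, X, y, feature_names=None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n, d) with one label per row")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(self.X.shape[1]))
        if len(feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.feature_names = tuple(feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", drop=("id",)):
        cols = [c for c in df.columns if c != label_col and c not in drop]
        return cls(df[cols].to_numpy(float), df[label_col].to_numpy(int), cols)

    def fit(
        self,
        variant: str = "refined",
        n_agents: int = 20,
        n_iters: int = 50,
        theta: float = DEFAULT_THETA,
        p: float = 0.8,
        c_range=DEFAULT_C_RANGE,
        sigma_range=DEFAULT_SIGMA_RANGE,
        n_splits: int = 5,
        seed: int | None = None,
        config: GSAConfig | None = None,
    ) -> "FeatureSelectionResults":
        """Run the wrapper search, then LOO-evaluate the selected model."""
        if config is None:
            config = GSAConfig(
                n_agents=n_agents, n_iters=n_iters, p=p, variant=variant
            )
        sel = select_features(
            self.X, self.y, config=config, theta=theta,
            c_range=c_range, sigma_range=sigma_range,
            n_splits=n_splits, seed=seed,
        )
        settings = SVMSettings(C=sel.mask.C, sigma=sel.mask.sigma)
        report = loo_evaluate(self.X[:, sel.mask.mask], self.y, settings)
        return FeatureSelectionResults(
            model=self, selection=sel, settings=settings, report=report,
            theta=theta, config=config, seed=seed,
        )


@dataclass
class FeatureSelectionResults:
    """Fitted wrapper-selection results with held-out diagnostics."""

    model: FeatureSelectionSVM
    selection: SelectionResult
    settings: SVMSettings
    report: EvalReport
    theta: float
    config: GSAConfig
    seed: int | None

    @property
    def mask(self) -> FeatureMask:
        return self.selection.mask

    @property
    def selected_features(self) -> list[str]:
        return self.mask.selected_names(self.model.feature_names)

    @property
    def fitness_history(self) -> np.ndarray:
        return self.selection.history

    def summary(self) -> str:
        r = self.report
        lines = [
            "Feature-selection SVM results",
            "=" * 46,
            f"{'variant':<28}{self.config.variant}",
            f"{'agents / iterations':<28}{self.config.n_agents} / {self.config.n_iters}",
            f"{'theta (accuracy weight)':<28}{self.theta:g}",
            f"{'subjects':<28}{r.n}",
            f"{'candidate features':<28}{len(self.model.feature_names)}",
            f"{'selected features':<28}{self.mask.n_selected}",
            f"{'C / sigma':<28}{self.settings.C:.4g} / {self.settings.sigma:.4g}",
            f"{'wrapper fitness':<28}{self.selection.fitness:.4f}",
            "-" * 46,
            f"{'LOO accuracy':<28}{r.accuracy:.4f}",
            f"{'LOO sensitivity':<28}{r.sensitivity:.4f}",
            f"{'LOO specificity':<28}{r.specificity:.4f}",
            f"{'LOO AUC (A_z)':<28}{r.auc:.4f}",
            f"{'RMSE / MAE':<28}{r.rmse:.4f} / {r.mae:.4f}",
            "-" * 46,
            "selected: " + ", ".join(self.selected_features[:8])
            + (" ..." if self.mask.n_selected > 8 else ""),
        ]
        return "\n".join(lines)

    def plot_fitness_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.fitness_history) + 1), self.fitness_history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best wrapper fitness")
        ax.set_title(f"{self.config.variant} GSA wrapper search")
        return ax

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.report.roc_fpr, self.report.roc_tpr, marker="o")
        ax.plot([0, 1], [0, 1], ls="--", c="gray")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"LOO ROC (AUC = {self.report.auc:.3f})")
        return ax
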