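"""Spike-count readout: the only trained component of the model.

The feature vector of a sample is the per-neuron spike count of the
excitatory liquid neurons over the whole sample — a memoryless statistic
that discards all spike timing.  A multinomial logistic-regression
classifier with L2 penalty is fit on these integer counts; only its
regularization strength C is selected, by stratified cross-validation
over a small grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .simulate import SpikeRaster

DEFAULT_REG_GRID = (0.01, 0.1, 1.0, 10.0)


def extract_features(raster: SpikeRaster, excitatory_ids: np.ndarray) -> np.ndarray:
    """Spike counts of the excitatory neurons; inhibitory events are ignored."""
    excitatory_ids = np.asarray(excitatory_ids, dtype=np.int64)
    counts = raster.counts()
    return counts[excitatory_ids]


@dataclass
class ReadoutModel:
    classifier: LogisticRegression
    C: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classifier.predict(np.asarray(features))

    def save(self, path) -> None:
        """Serialize coefficients to an .npz archive (no pickling)."""
        clf = self.classifier
        np.savez(
            path,
            coef=clf.coef_,
            intercept=clf.intercept_,
            classes=clf.classes_,
            C=np.asarray(self.C),
        )

    @classmethod
    def load(cls, path) -> "ReadoutModel":
        data = np.load(path)
        clf = LogisticRegression(C=float(data["C"]), max_iter=1)
        clf.coef_ = data["coef"]
        clf.intercept_ = data["intercept"]
        clf.classes_ = data["classes"]
        return cls(classifier=clf, C=float(data["C"]))


def fit_readout(
    features,
    labels,
    reg_grid=DEFAULT_REG_GRID,
    cv: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
) -> ReadoutModel:
    """Fit the multinomial linear readout, selecting C by cross-validation.

    With a single value in ``reg_grid`` the cross-validation is skipped.
    Deterministic given the seed (used only for the CV fold shuffle).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2D array (samples x neurons)")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit the readout")

    grid = [float(c) for c in reg_grid]
    if len(grid) == 1:
        best_C = grid[0]
    else:
        n_splits = int(min(cv, counts.min()))
        if n_splits < 2:
            best_C = grid[len(grid) // 2]
        else:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            scores = []
            for C in grid:
                clf = LogisticRegression(C=C, max_iter=max_iter)
                scores.append(cross_val_score(clf, X, y, cv=skf).mean())
            best_C = grid[int(np.argmax(scores))]
    clf = LogisticRegression(C=best_C, max_iter=max_iter)
    clf.fit(X, y)
    return ReadoutModel(classifier=clf, C=best_C)


def evaluate(model: ReadoutModel, features, labels) -> float:
    """Fraction of correct argmax predictions."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    return float(np.mean(model.predict(X) == y))
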