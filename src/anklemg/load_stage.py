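"""Step one of the two-step decoder: load-level recognition from window RMS.

The per-channel RMS of a 210 ms analysis window tracks contraction
intensity, which scales with the external load; a random forest on the
4-vector of channel RMS values separates the three load levels. RMS must
be computed on the filtered (not z-normalized) signal -- per-trial
normalization would erase exactly the amplitude information this stage
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .features import rms
from .preprocessing import LargeWindow
from .synthetic_data import LOADS

__all__ = ["LoadSample", "window_rms", "LoadClassifier", "fit_load_classifier", "predict_load"]


@dataclass
class LoadSample:
    """Per-channel RMS of one analysis window plus its true load label."""

    rms: np.ndarray
    load: str | None = None

    def __post_init__(self):
        self.rms = np.asarray(self.rms, dtype=float)
        if np.any(self.rms < 0):
            raise ValueError("RMS values must be non-negative")


def window_rms(win: LargeWindow) -> LoadSample:
    """Per-channel RMS over the full large window."""
    return LoadSample(rms=rms(win.data), load=win.load)


class LoadClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest load-level classifier on window RMS vectors.

    A thin, seeded wrapper around
    :class:`sklearn.ensemble.RandomForestClassifier` that fixes the
    package's conventions (200 trees, unlimited depth, string load
    labels).
    """

    def __init__(self, n_trees: int = 200, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least 2 load classes to train")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=1
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def save(self, path) -> None:
        """Persist the fitted forest (joblib) with version metadata."""
        from pathlib import Path

        import joblib
        import sklearn

        check_is_fitted(self, "forest_")
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {
                "forest": self.forest_,
                "n_trees": self.n_trees,
                "random_state": self.random_state,
                "sklearn_version": sklearn.__version__,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "LoadClassifier":
        import joblib

        payload = joblib.load(path)
        model = cls(n_trees=payload["n_trees"], random_state=payload["random_state"])
        model.forest_ = payload["forest"]
        model.classes_ = model.forest_.classes_
        model.n_features_in_ = model.forest_.n_features_in_
        return model


def fit_load_classifier(
    samples: list[LoadSample], n_trees: int = 200, seed: int = 0
) -> LoadClassifier:
    """Train the load stage from a collection of labelled RMS samples."""
    X = np.array([s.rms for s in samples])
    y = np.array([s.load for s in samples])
    return LoadClassifier(n_trees=n_trees, random_state=seed).fit(X, y)


def predict_load(model: LoadClassifier, sample: LoadSample) -> str:
    """Predict the load level of one window; returns low/medium/high."""
    label = model.predict(sample.rms[None, :])[0]
    if label not in LOADS:
        raise ValueError(f"model predicted unknown load label {label!r}")
    return str(label)
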