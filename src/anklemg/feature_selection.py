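"""Boruta all-relevant feature selection with shadow features.

The procedure augments the candidate feature table with "shadow"
features -- independently permuted copies of each column, which preserve
each feature's marginal distribution while destroying any association
with the labels. A random forest is fit on the augmented table; each
column's importance Z-score is the mean of its per-tree importances
divided by their standard deviation. A real feature scores a "hit"
whenever its Z-score exceeds the best shadow Z-score (Z_max). Over
iterations, a binomial test on the hit count marks features *important*
(significantly more hits than the fair-coin null) or *unimportant*
(significantly fewer; such features are removed from later iterations);
the loop stops when nothing is tentative or the iteration cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .features import ALL_FEATURES, FeatureSpec

__all__ = [
    "BorutaConfig",
    "BorutaReport",
    "make_shadows",
    "zscore_importances",
    "boruta_select",
    "select_feature_spec",
    "BorutaSelector",
]

IMPORTANT = "important"
UNIMPORTANT = "unimportant"
TENTATIVE = "tentative"


@dataclass(frozen=True)
class BorutaConfig:
    max_iter: int = 100
    alpha: float = 0.05
    n_trees: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class BorutaReport:
    """Outcome of a Boruta run.

    ``decisions`` maps every candidate feature to important / unimportant /
    tentative. ``z_history`` holds each feature's Z-score per iteration in
    which it was still active (NaN once eliminated); ``shadow_summary``
    holds the max/mean/median/min shadow Z-score per iteration.
    """

    feature_names: tuple
    decisions: dict
    z_history: np.ndarray  # (n_iter, n_features)
    shadow_summary: np.ndarray  # (n_iter, 4): max, mean, median, min
    hits: np.ndarray
    n_iter: int

    def selected(self) -> list[str]:
        return [f for f in self.feature_names if self.decisions[f] == IMPORTANT]

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "decisions": dict(self.decisions),
            "z_history": [[None if np.isnan(v) else float(v) for v in row]
                          for row in self.z_history],
            "shadow_summary": self.shadow_summary.tolist(),
            "hits": self.hits.tolist(),
            "n_iter": int(self.n_iter),
        }


def make_shadows(X: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Append an independently permuted copy of every column.

    Returns an (n, 2F) array: the original columns followed by their
    shadows, in the same column order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least 2 rows and 1 column")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shadows = np.empty_like(X)
    for j in range(X.shape[1]):
        shadows[:, j] = rng.permutation(X[:, j])
    return np.hstack([X, shadows])


def zscore_importances(
    X_aug: np.ndarray, y, config: BorutaConfig = BorutaConfig()
) -> np.ndarray:
    """Per-column importance Z-scores from a random forest.

    Fits a forest on the augmented table and returns, for every column
    (real and shadow alike), the mean per-tree importance divided by the
    standard deviation of the per-tree importances. Per-tree importance
    is the classic out-of-bag permutation importance (accuracy decrease
    when the column is shuffled among the tree's OOB samples): it is
    signed, so an uninformative column fluctuates around zero and gets a
    Z-score near zero, which is what the comparison against the best
    shadow relies on. Columns whose importance never varies get Z = 0.
    """
    X_aug = np.asarray(X_aug, dtype=float)
    y = np.asarray(y)
    if X_aug.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to measure importance")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        random_state=config.seed,
        bootstrap=True,
        n_jobs=1,
    )
    forest.fit(X_aug, y)
    rng = np.random.default_rng(config.seed)
    n, n_cols = X_aug.shape
    per_tree = np.zeros((config.n_trees, n_cols))
    for t, (tree, sampled) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        m = int(oob.sum())
        if m < 2:
            continue
        Xo, yo = X_aug[oob], y[oob]
        perm = rng.permutation(m)
        # one predict call per tree: original block + one block per column
        # with that column permuted
        blocks = np.tile(Xo, (n_cols + 1, 1))
        for j in range(n_cols):
            blocks[(j + 1) * m : (j + 2) * m, j] = Xo[perm, j]
        correct = (tree.predict(blocks) == np.tile(yo, n_cols + 1)).reshape(
            n_cols + 1, m
        )
        acc = correct.mean(axis=1)
        per_tree[t] = acc[0] - acc[1:]
    mean = per_tree.mean(axis=0)
    sd = per_tree.std(axis=0, ddof=1)
    z = np.zeros_like(mean)
    ok = sd > 0
    z[ok] = mean[ok] / sd[ok]
    return z


def _binom_decision(hits: int, n: int, alpha: float) -> str:
    """Two-sided binomial test of the hit count against the fair-coin null."""
    p = stats.binomtest(hits, n, 0.5).pvalue
    if p < alpha:
        return IMPORTANT if hits > n / 2 else UNIMPORTANT
    return TENTATIVE


def boruta_select(
    X: np.ndarray,
    y,
    config: BorutaConfig = BorutaConfig(),
    feature_names: tuple | None = None,
) -> BorutaReport:
    """Run the shadow-feature selection loop.

    Eliminated (unimportant) features are dropped from subsequent forests;
    features still undecided at the iteration cap stay tentative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(X.shape[1]))
    feature_names = tuple(feature_names)
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match column count")

    n_feat = X.shape[1]
    rng = np.random.default_rng(config.seed)
    in_pool = np.ones(n_feat, dtype=bool)  # columns the forest still sees
    undecided = np.ones(n_feat, dtype=bool)  # columns still being hit-tested
    decisions = {f: TENTATIVE for f in feature_names}
    hits = np.zeros(n_feat, dtype=int)
    trials = np.zeros(n_feat, dtype=int)
    z_rows = []
    shadow_rows = []

    n_iter = 0
    for _ in range(config.max_iter):
        n_iter += 1
        idx = np.nonzero(in_pool)[0]
        sub_cfg = BorutaConfig(
            max_iter=config.max_iter,
            alpha=config.alpha,
            n_trees=config.n_trees,
            seed=int(rng.integers(2**31 - 1)),
        )
        X_aug = make_shadows(X[:, idx], seed=rng)
        k = idx.size
        if k < 5:
            # pad to at least 5 shadows so Z_max is a stable null even for
            # small candidate sets (a fixed noise column's spurious label
            # correlation must not beat the best of too few shadows)
            extra_src = rng.choice(idx, size=5 - k)
            extra = np.column_stack(
                [rng.permutation(X[:, j]) for j in extra_src]
            )
            X_aug = np.hstack([X_aug, extra])
        z = zscore_importances(X_aug, y, sub_cfg)
        z_real, z_shadow = z[:k], z[k:]
        z_max = z_shadow.max()

        row = np.full(n_feat, np.nan)
        row[idx] = z_real
        z_rows.append(row)
        shadow_rows.append(
            [z_max, z_shadow.mean(), float(np.median(z_shadow)), z_shadow.min()]
        )

        test_idx = idx[undecided[idx]]
        hits[test_idx] += row[test_idx] > z_max
        trials[test_idx] += 1
        for j in test_idx:
            d = _binom_decision(int(hits[j]), int(trials[j]), config.alpha)
            if d != TENTATIVE:
                decisions[feature_names[j]] = d
                undecided[j] = False
                if d == UNIMPORTANT:
                    # eliminated features leave the table; important ones
                    # stay as context but are no longer re-tested
                    in_pool[j] = False
        if not undecided.any():
            break

    return BorutaReport(
        feature_names=feature_names,
        decisions=decisions,
        z_history=np.array(z_rows),
        shadow_summary=np.array(shadow_rows),
        hits=hits,
        n_iter=n_iter,
    )


def select_feature_spec(
    report: BorutaReport,
    threshold_uv: float = 50.0,
    include_tentative: bool = False,
) -> FeatureSpec:
    """Turn a report on the eight candidate features into a FeatureSpec.

    Keeps features marked important (optionally also tentative), in
    canonical order. Raises if nothing survives, suggesting the fallback
    of using all candidates.
    """
    keep_states = {IMPORTANT} | ({TENTATIVE} if include_tentative else set())
    kept = [
        f for f in ALL_FEATURES
        if f in report.decisions and report.decisions[f] in keep_states
    ]
    if not kept:
        raise ValueError(
            "no features were marked important; consider falling back to the "
            "full candidate set FeatureSpec()"
        )
    return FeatureSpec(names=tuple(kept), threshold_uv=threshold_uv)


class BorutaSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn selector wrapping the shadow-feature procedure.

    Parameters mirror :class:`BorutaConfig`. After ``fit``, ``support_``
    holds the boolean mask of important features (optionally including
    tentative ones) and ``report_`` the full per-iteration record.
    """

    def __init__(
        self,
        max_iter: int = 100,
        alpha: float = 0.05,
        n_trees: int = 200,
        include_tentative: bool = False,
        random_state: int = 0,
    ):
        self.max_iter = max_iter
        self.alpha = alpha
        self.n_trees = n_trees
        self.include_tentative = include_tentative
        self.random_state = random_state

    def fit(self, X, y, feature_names: tuple | None = None):
        X = np.asarray(X, dtype=float)
        config = BorutaConfig(
            max_iter=self.max_iter,
            alpha=self.alpha,
            n_trees=self.n_trees,
            seed=self.random_state,
        )
        self.report_ = boruta_select(X, y, config, feature_names=feature_names)
        keep = {IMPORTANT} | ({TENTATIVE} if self.include_tentative else set())
        self.support_ = np.array(
            [self.report_.decisions[f] in keep for f in self.report_.feature_names]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
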