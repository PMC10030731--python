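import numpy as np
import pytest

from anklemg.feature_selection import (
    IMPORTANT,
    TENTATIVE,
    UNIMPORTANT,
    BorutaConfig,
    BorutaReport,
    BorutaSelector,
    boruta_select,
    make_shadows,
    select_feature_spec,
    zscore_importances,
)
from anklemg.features import ALL_FEATURES


def planted_problem(seed, n=500):
    """Two strong copies of the label plus two pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = np.column_stack(
        [
            y + rng.normal(0, 0.3, n),
            y + rng.normal(0, 0.5, n),
            rng.normal(0, 1, n),
            rng.normal(0, 1, n),
        ]
    )
    return X, y


class TestMakeShadows:
    def test_originals_preserved_and_doubled(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        aug = make_shadows(X, seed=1)
        assert aug.shape == (50, 6)
        np.testing.assert_array_equal(aug[:, :3], X)

    def test_shadows_are_permutations(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 4))
        aug = make_shadows(X, seed=2)
        for j in range(4):
            np.testing.assert_array_equal(
                np.sort(aug[:, 4 + j]), np.sort(X[:, j])
            )

    def test_permutation_destroys_association(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 1000).astype(float)
        X = y[:, None].copy()  # feature identical to the label
        aug = make_shadows(X, seed=3)
        assert abs(np.corrcoef(aug[:, 1], y)[0, 1]) < 0.1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            make_shadows(np.empty((0, 3)))


class TestZScores:
    def test_label_copy_beats_every_shadow(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 500)
        X = np.column_stack([y.astype(float), rng.normal(0, 1, 500)])
        z = zscore_importances(make_shadows(X, seed=4), y, BorutaConfig(n_trees=100, seed=4))
        assert z[0] > z[2:].max()

    def test_noise_rarely_beats_best_shadow(self):
        # A noise column is exchangeable with every shadow, so it beats the
        # max of S shadows with probability ~1/(S+1); with 20 shadows that
        # floor is ~5%, and the seeded Monte-Carlo must stay near it.
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 200)
            X = np.column_stack(
                [y + rng.normal(0, 0.5, 200)]
                + [rng.normal(0, 1, 200) for _ in range(19)]
            )
            z = zscore_importances(
                make_shadows(X, seed=seed), y, BorutaConfig(n_trees=50, seed=seed)
            )
            wins += z[1] > z[20:].max()  # designated noise column vs max shadow
        assert wins <= 5  # below the max shadow in >= 90% of 50 runs

    def test_duplicate_columns_score_alike(self):
        diffs, spreads = [], []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            y = rng.integers(0, 2, 300)
            base = y + rng.normal(0, 0.5, 300)
            X = np.column_stack([base, base, rng.normal(0, 1, 300)])
            z = zscore_importances(
                make_shadows(X, seed=seed), y, BorutaConfig(n_trees=100, seed=seed)
            )
            diffs.append(z[0] - z[1])
            spreads.append(z[0])
        assert abs(np.mean(diffs)) <= 2 * np.std(spreads, ddof=1)

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 4))
        with pytest.raises(ValueError):
            zscore_importances(X, np.zeros(20))


class TestBorutaSelect:
    def test_planted_informative_and_noise(self):
        X, y = planted_problem(seed=3)
        report = boruta_select(X, y, BorutaConfig(max_iter=50, n_trees=200, seed=3))
        assert report.decisions["f0"] == IMPORTANT
        assert report.decisions["f1"] == IMPORTANT
        assert report.decisions["f2"] == UNIMPORTANT
        assert report.decisions["f3"] == UNIMPORTANT

    def test_single_iteration_cap(self):
        X, y = planted_problem(seed=1)
        report = boruta_select(X, y, BorutaConfig(max_iter=1, seed=1))
        assert report.n_iter == 1
        assert all(d == TENTATIVE for d in report.decisions.values())

    def test_label_copy_never_unimportant(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 300)
            X = np.column_stack([y.astype(float), rng.normal(0, 1, (300, 2)).T[0],
                                 rng.normal(0, 1, 300)])
            report = boruta_select(X, y, BorutaConfig(max_iter=15, n_trees=100, seed=seed))
            assert report.decisions["f0"] != UNIMPORTANT

    def test_rerun_without_eliminated_feature_is_stable(self):
        X, y = planted_problem(seed=3)
        first = boruta_select(X, y, BorutaConfig(max_iter=30, n_trees=100, seed=3))
        keep = [j for j, f in enumerate(first.feature_names)
                if first.decisions[f] != UNIMPORTANT]
        second = boruta_select(
            X[:, keep], y, BorutaConfig(max_iter=30, n_trees=100, seed=3),
            feature_names=tuple(first.feature_names[j] for j in keep),
        )
        for f, d in first.decisions.items():
            if d == IMPORTANT:
                assert second.decisions[f] != UNIMPORTANT

    def test_shadow_columns_absent_from_report(self):
        X, y = planted_problem(seed=2)
        report = boruta_select(X, y, BorutaConfig(max_iter=8, n_trees=50, seed=2))
        assert set(report.decisions) == {"f0", "f1", "f2", "f3"}
        assert report.z_history.shape[1] == 4

    def test_too_few_samples_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(ValueError):
            boruta_select(X, np.array([0, 1, 0, 1, 0]))


class TestSelectFeatureSpec:
    def _report(self, decisions):
        return BorutaReport(
            feature_names=ALL_FEATURES,
            decisions=decisions,
            z_history=np.zeros((1, 8)),
            shadow_summary=np.zeros((1, 4)),
            hits=np.zeros(8, dtype=int),
            n_iter=1,
        )

    def test_excluding_wa_gives_seven_features(self):
        decisions = {f: IMPORTANT for f in ALL_FEATURES}
        decisions["WA"] = UNIMPORTANT
        spec = select_feature_spec(self._report(decisions))
        assert spec.names == ("RMS", "MAV", "WL", "ZC", "SSC", "VAR", "LogD")

    def test_all_important_keeps_all(self):
        spec = select_feature_spec(self._report({f: IMPORTANT for f in ALL_FEATURES}))
        assert spec.names == ALL_FEATURES

    def test_nothing_important_raises(self):
        with pytest.raises(ValueError, match="falling back"):
            select_feature_spec(self._report({f: UNIMPORTANT for f in ALL_FEATURES}))

    def test_tentative_excluded_by_default(self):
        decisions = {f: IMPORTANT for f in ALL_FEATURES}
        decisions["WA"] = TENTATIVE
        assert "WA" not in select_feature_spec(self._report(decisions)).names
        assert "WA" in select_feature_spec(
            self._report(decisions), include_tentative=True
        ).names


class TestBorutaSelector:
    def test_sklearn_selector_interface(self):
        X, y = planted_problem(seed=5)
        sel = BorutaSelector(max_iter=30, n_trees=100, random_state=5).fit(X, y)
        assert sel.support_.tolist() == [True, True, False, False]
        assert sel.transform(X).shape == (len(X), 2)
        params = sel.get_params()
        assert params["max_iter"] == 30
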