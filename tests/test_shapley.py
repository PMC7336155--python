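"""Shapley axioms, the permutation estimator, bootstrap, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tractmsa.predictor import GradedDataset, PredictorSpec, train
from tractmsa.shapley import (
    CharacteristicFunction,
    ContributionResult,
    bootstrap_contributions,
    classify_contributors,
    estimated_shapley,
    exact_shapley,
    flag_significance,
    normalize_contributions,
    shapley_from_orderings,
)


def _game_from_table(values):
    """Characteristic function from a dict {bitmask: worth} over M players."""
    M = max(values).bit_length()
    return CharacteristicFunction(
        lambda C: np.array(
            [values[int(np.dot(c, 1 << np.arange(M)))] for c in C.astype(int)]
        ),
        M,
    )


def _additive_game(w):
    return CharacteristicFunction(lambda C: C @ np.asarray(w), len(w))


class TestExact:
    def test_two_player_worked_example(self):
        # v(empty)=0, v({1})=1, v({2})=0, v({1,2})=2; orderings (1,2): 1,1 and (2,1): 0,2
        v = _game_from_table({0b00: 0, 0b01: 1, 0b10: 0, 0b11: 2})
        np.testing.assert_allclose(exact_shapley(v), [1.5, 0.5])

    def test_additive_game_returns_weights(self):
        w = [0.3, -0.2, 0.5, 0.1]
        np.testing.assert_allclose(exact_shapley(_additive_game(w)), w)

    def test_symmetric_game(self):
        v = CharacteristicFunction(lambda C: C.sum(axis=1), 3)
        np.testing.assert_allclose(exact_shapley(v), [1, 1, 1])

    def test_efficiency_random_games(self, rng):
        for _ in range(20):
            M = int(rng.integers(2, 7))
            table = {m: float(rng.normal()) for m in range(2**M)}
            v = _game_from_table(table)
            phi = exact_shapley(v)
            assert phi.sum() == pytest.approx(table[2**M - 1] - table[0], abs=1e-10)

    def test_dummy_player_zero(self, rng):
        """A player that never changes v gets exactly 0."""
        inner = {m: float(rng.normal()) for m in range(2**3)}
        table = {m: inner[m & 0b111] for m in range(2**4)}  # player 3 inert
        phi = exact_shapley(_game_from_table(table))
        assert phi[3] == 0.0

    def test_enumeration_bound(self):
        v = CharacteristicFunction(lambda C: C.sum(axis=1), 21)
        with pytest.raises(ValueError, match="estimated_shapley"):
            exact_shapley(v)


class TestEstimated:
    def test_determinism(self):
        v = _additive_game([1.0, -0.5, 0.25])
        a = estimated_shapley(v, n_perms=50, seed=3)
        b = estimated_shapley(v, n_perms=50, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_full_enumeration_equals_exact(self, rng):
        """Averaging marginals over all M! orderings is the exact value."""
        for M in (3, 4, 5):
            table = {m: float(rng.normal()) for m in range(2**M)}
            v = _game_from_table(table)
            orders = np.array(list(itertools.permutations(range(M))))
            marg = shapley_from_orderings(v, orders)
            np.testing.assert_allclose(marg.mean(axis=0), exact_shapley(v), atol=1e-12)

    def test_rows_telescope_to_efficiency(self, rng):
        table = {m: float(rng.normal()) for m in range(2**4)}
        v = _game_from_table(table)
        orders = np.array([rng.permutation(4) for _ in range(20)])
        marg = shapley_from_orderings(v, orders)
        np.testing.assert_allclose(
            marg.sum(axis=1), np.full(20, table[15] - table[0]), atol=1e-12
        )

    def test_predictor_backed_within_three_se(self, cohort):
        """1,000 sampled permutations agree with full enumeration."""
        v = _predictor_game(cohort)
        phi = exact_shapley(v)
        est, se = estimated_shapley(v, n_perms=1000, seed=12)
        assert np.all(np.abs(est - phi) <= 3 * se + 1e-12)

    def test_error_shrinks_with_permutations(self, cohort):
        v = _predictor_game(cohort)
        phi = exact_shapley(v)
        maes = []
        for n_perms in (10, 100, 1000):
            errs = [
                np.abs(estimated_shapley(v, n_perms, seed=s)[0] - phi).mean()
                for s in range(5)
            ]
            maes.append(np.mean(errs))
        assert maes[0] > maes[1] > maes[2]


def _predictor_game(cohort):
    test = "line_bisection"
    X = np.vstack([p.intact for p in cohort.profiles])
    y = cohort.performance[test]
    ds = GradedDataset(
        test=test, X=X, y=y,
        patient_ids=tuple(str(i) for i in range(len(y))),
        player_names=cohort.profiles[0].player_names,
    )
    v = CharacteristicFunction.from_predictor(train(ds, PredictorSpec("linear")))
    v.tabulate()
    return v


class TestNormalize:
    def test_stated_rule(self):
        np.testing.assert_allclose(
            normalize_contributions(np.array([2.0, -1.0, 1.0])), [0.5, -0.25, 0.25]
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_contributions(np.zeros(3))

    def test_preserves_rank_of_magnitudes(self, rng):
        raw = rng.normal(size=8)
        norm = normalize_contributions(raw)
        assert list(np.argsort(np.abs(raw))) == list(np.argsort(np.abs(norm)))
        assert np.abs(norm).sum() == pytest.approx(1.0)

    def test_efficiency_mode(self):
        raw = np.array([2.0, -1.0, 1.0])
        np.testing.assert_allclose(
            normalize_contributions(raw, mode="efficiency"), [1.0, -0.5, 0.5]
        )


def _result_with_replicates(reps):
    reps = np.asarray(reps, dtype=float)
    mean = reps.mean(axis=0)
    return ContributionResult(
        test="bells",
        player_names=tuple(f"p{j}" for j in range(reps.shape[1])),
        mean=mean,
        boot_sd=reps.std(axis=0, ddof=1),
        mean_se=np.zeros(reps.shape[1]),
        replicates=reps,
        n_perms=1,
    )


class TestSignificance:
    def test_all_positive_replicates(self, rng):
        res = _result_with_replicates(rng.uniform(0.1, 1.0, size=(100, 2)))
        out = flag_significance(res)
        assert out.significant.all()
        assert (out.sign == "positive").all()

    def test_symmetric_replicates_not_significant(self, rng):
        half = rng.uniform(0.1, 1.0, size=(100, 1))
        res = _result_with_replicates(np.vstack([half, -half]))
        assert not flag_significance(res).significant.any()

    def test_tail_mass_vs_level(self):
        """Central 95% interval: 3% below zero straddles it, 2% does not."""
        reps3 = np.concatenate([np.full(3, -1.0), np.full(97, 1.0)])[:, None]
        assert not flag_significance(_result_with_replicates(reps3)).significant[0]
        reps2 = np.concatenate([np.full(2, -1.0), np.full(98, 1.0)])[:, None]
        assert flag_significance(_result_with_replicates(reps2)).significant[0]

    def test_few_replicates_flagged_unreliable(self, rng):
        res = _result_with_replicates(rng.uniform(0.1, 1.0, size=(10, 2)))
        with pytest.warns(UserWarning, match="unreliable"):
            out = flag_significance(res)
        assert not out.interval_reliable


@pytest.fixture(scope="module")
def bells_dataset(cohort):
    X = np.vstack([p.intact for p in cohort.profiles])
    y = cohort.performance["bells"]
    return GradedDataset(
        test="bells", X=X, y=y,
        patient_ids=tuple(str(i) for i in range(len(y))),
        player_names=cohort.profiles[0].player_names,
    )


class TestBootstrap:

    def test_single_resample_bound(self, bells_dataset):
        res = bootstrap_contributions(bells_dataset, n_boot=1, n_perms=20, seed=0)
        assert res.replicates.shape == (1, bells_dataset.n_players)
        np.testing.assert_array_equal(res.mean, res.replicates[0])

    def test_dispersion_positive_under_noise(self, bells_dataset):
        res = bootstrap_contributions(bells_dataset, n_boot=15, n_perms=30, seed=1)
        assert (res.boot_sd > 0).any()

    def test_determinism(self, bells_dataset):
        a = bootstrap_contributions(bells_dataset, n_boot=5, n_perms=20, seed=2)
        b = bootstrap_contributions(bells_dataset, n_boot=5, n_perms=20, seed=2)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_hopeless_dataset_errors(self):
        X = np.random.default_rng(0).uniform(size=(6, 3))
        y = np.array([0, 1, 1, 1, 1, 1])
        ds = GradedDataset(
            test="letter", X=X, y=y,
            patient_ids=tuple("abcdef"), player_names=("x", "y", "z"),
        )
        # max_redraws=0 makes any single-class resample fatal on first failure
        with pytest.raises(RuntimeError):
            bootstrap_contributions(ds, n_boot=50, n_perms=5, seed=0, max_redraws=0)


class TestClassification:
    def _result(self, test, means, significant):
        means = np.asarray(means, dtype=float)
        reps = np.tile(means, (30, 1))
        res = ContributionResult(
            test=test,
            player_names=("A", "B", "C", "RoB"),
            mean=means,
            boot_sd=np.zeros_like(means),
            mean_se=np.zeros_like(means),
            replicates=reps,
            n_perms=1,
            normalized=normalize_contributions(means),
        )
        return ContributionResult(
            **{**res.__dict__, "significant": np.asarray(significant), "level": 0.05}
        )

    def test_invariant_and_dependent_patterns(self):
        results = {
            "line_bisection": self._result(
                "line_bisection", [0.5, -0.2, 0.3, 0.1], [True, True, True, True]
            ),
            "bells": self._result(
                "bells", [0.4, -0.3, -0.2, 0.1], [True, True, True, True]
            ),
            "letter": self._result(
                "letter", [0.2, -0.1, 0.4, 0.1], [True, True, False, True]
            ),
        }
        table = classify_contributors(results)
        assert table.loc["A", "classification"] == "task-invariant positive"
        assert table.loc["B", "classification"] == "task-invariant negative"
        assert table.loc["C", "classification"] == "task-dependent"
        assert table.loc["C", "bells"] == "-"
        assert table.loc["C", "letter"] == "n.s."
        assert "RoB" not in table.index  # diagnostic player excluded by default
        assert "RoB" in classify_contributors(results, include_rob=True).index

    def test_mismatched_players_rejected(self):
        a = self._result("bells", [0.1, 0.2, 0.3, 0.1], [True] * 4)
        b = ContributionResult(
            test="letter",
            player_names=("A", "B", "X", "RoB"),
            mean=np.ones(4),
            boot_sd=np.zeros(4),
            mean_se=np.zeros(4),
            replicates=np.ones((30, 4)),
            n_perms=1,
            normalized=np.full(4, 0.25),
            significant=np.ones(4, bool),
            level=0.05,
        )
        with pytest.raises(ValueError, match="mismatched"):
            classify_contributors({"bells": a, "letter": b})

    def test_needs_two_tests(self):
        a = self._result("bells", [0.1, 0.2, 0.3, 0.1], [True] * 4)
        with pytest.raises(ValueError):
            classify_contributors({"bells": a})
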