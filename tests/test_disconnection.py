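"""Disconnection fractions, RoB, profiles, and lesion covariance."""

import numpy as np
import pytest

from tractmsa.disconnection import (
    ROB,
    DisconnectionProfile,
    GridMismatchError,
    binarize_tract,
    disconnection_fraction,
    lesion_correlation_matrix,
    profile_patient,
    rob_fraction,
)


class TestBinarizeTract:
    def test_uniform_above_threshold(self):
        mask = binarize_tract(np.full((4, 4, 4), 0.6), 0.5)
        assert mask.all()

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            mask = binarize_tract(np.zeros((4, 4, 4)), 0.5)
        assert not mask.any()

    def test_exact_voxel_selection(self, rng):
        vol = rng.uniform(0, 0.49, size=(5, 5, 5))
        idx = rng.choice(125, size=10, replace=False)
        vol.flat[idx] = rng.uniform(0.5, 1.0, size=10)
        mask = binarize_tract(vol, 0.5)
        assert mask.sum() == 10
        assert set(np.flatnonzero(mask.ravel())) == set(idx)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_bounds(self, threshold):
        with pytest.raises(ValueError):
            binarize_tract(np.ones((4, 4, 4)), threshold)


class TestDisconnectionFraction:
    def test_disjoint_and_superset(self):
        tract = np.zeros((6, 6, 6), bool)
        tract[:2] = True
        lesion = np.zeros_like(tract)
        assert disconnection_fraction(lesion, tract) == 0.0
        assert disconnection_fraction(np.ones_like(tract), tract) == 1.0

    def test_brute_force_count(self, rng):
        """Fraction equals an independent voxel-by-voxel recount."""
        tract = rng.uniform(size=(7, 7, 7)) < 0.3
        lesion = rng.uniform(size=(7, 7, 7)) < 0.4
        got = disconnection_fraction(lesion, tract)
        hits = sum(
            1
            for i in range(7) for j in range(7) for k in range(7)
            if tract[i, j, k] and lesion[i, j, k]
        )
        assert got == pytest.approx(hits / tract.sum())

    def test_three_of_ten(self):
        tract = np.zeros((10, 1, 1), bool)
        tract[:10] = True
        lesion = np.zeros_like(tract)
        lesion[:3] = True
        assert disconnection_fraction(lesion, tract) == pytest.approx(0.3)

    def test_empty_tract_and_grid_mismatch(self):
        with pytest.raises(ValueError, match="empty tract"):
            disconnection_fraction(np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool))
        with pytest.raises(GridMismatchError):
            disconnection_fraction(np.ones((4, 4, 4), bool), np.ones((5, 5, 5), bool))

    def test_monotone_under_lesion_growth(self, rng):
        """Adding lesion voxels never decreases any damage fraction."""
        tract = rng.uniform(size=(6, 6, 6)) < 0.4
        lesion = np.zeros((6, 6, 6), bool)
        prev = 0.0
        for flat in rng.permutation(216)[:60]:
            lesion.flat[flat] = True
            d = disconnection_fraction(lesion, tract)
            assert d >= prev
            assert 0.0 <= d <= 1.0
            prev = d


class TestRoB:
    def _toy(self):
        player = np.zeros((6, 6, 6), bool)
        player[0] = True
        pool = np.zeros_like(player)
        pool[3:5] = True  # 72 voxels, disjoint from player
        return {"t": player}, {"p": pool}

    def test_lesion_within_players_only(self):
        players, pool = self._toy()
        lesion = players["t"].copy()
        assert rob_fraction(lesion, players, pool) == 0.0

    def test_full_pool_coverage(self):
        players, pool = self._toy()
        assert rob_fraction(pool["p"].copy(), players, pool) == 1.0

    def test_half_coverage(self):
        players, pool = self._toy()
        lesion = np.zeros_like(pool["p"])
        lesion[3] = True  # half the pool union
        assert rob_fraction(lesion, players, pool) == pytest.approx(0.5)

    def test_player_overlap_not_double_counted(self):
        players, pool = self._toy()
        pool["p"][0] = True  # overlap with player tract
        lesion = players["t"].copy()
        # lesion covers only the overlap, which is excluded from RoB
        assert rob_fraction(lesion, players, pool) == 0.0

    def test_empty_pool_rejected(self):
        players, _ = self._toy()
        with pytest.raises(ValueError):
            rob_fraction(players["t"], players, {})


class TestProfile:
    def test_empty_and_full_lesion(self, small_atlas):
        shape = small_atlas.grid_shape
        empty = profile_patient(np.zeros(shape, bool), small_atlas, patient_id="a")
        assert np.all(empty.d == 0) and np.all(empty.intact == 1)
        full = profile_patient(np.ones(shape, bool), small_atlas, patient_id="b")
        assert np.all(full.d == 1)
        assert full.player_names[-1] == ROB

    def test_oracle_recount(self, small_atlas, rng):
        lesion = rng.uniform(size=small_atlas.grid_shape) < 0.3
        prof = profile_patient(lesion, small_atlas, threshold=0.5)
        masks = small_atlas.binary_masks(0.5)
        for k, name in enumerate(small_atlas.names):
            expect = (lesion & masks[name]).sum() / masks[name].sum()
            assert prof.d[k] == pytest.approx(expect)

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            DisconnectionProfile("x", ("a",), np.array([1.2]))


class TestCorrelation:
    def _profiles(self, d_matrix):
        names = tuple(f"t{j}" for j in range(d_matrix.shape[1]))
        return [
            DisconnectionProfile(str(i), names, row) for i, row in enumerate(d_matrix)
        ]

    def test_identical_columns_r_one(self):
        col = np.array([0.1, 0.4, 0.8, 0.2])
        res = lesion_correlation_matrix(self._profiles(np.column_stack([col, col])))
        assert res.r.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_column_flagged_undefined(self):
        d = np.column_stack([np.full(4, 0.5), [0.1, 0.2, 0.3, 0.4]])
        res = lesion_correlation_matrix(self._profiles(d))
        assert res.undefined == ["t0"]
        assert np.isnan(res.r.iloc[0, 1])

    def test_matches_textbook_pearson(self):
        """Hand-built 4-patient set against the closed-form r."""
        a = np.array([0.0, 0.2, 0.5, 0.9])
        b = np.array([0.1, 0.1, 0.6, 0.7])
        res = lesion_correlation_matrix(self._profiles(np.column_stack([a, b])))
        am, bm = a - a.mean(), b - b.mean()
        expect = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert res.r.iloc[0, 1] == pytest.approx(expect)

    def test_symmetry_and_unit_diagonal(self, rng):
        d = rng.uniform(size=(8, 4))
        res = lesion_correlation_matrix(self._profiles(d))
        r = res.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            lesion_correlation_matrix(self._profiles(np.ones((2, 3)) * 0.5))
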