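"""Bootstrap inversion of dF/G data into resting/active distances."""

import numpy as np
import pytest

from depet.distance_fit import (
    DepetModel,
    QuenchingDataset,
    bootstrap_resample,
    build_seed_grid,
    fit_dual_pair,
    fit_single_pair,
    forward_deltaF,
)
from depet.synthetic_fixtures import example_fdq_family, synth_quenching_dataset

TRUTH = dict(d_r=7.0, d_a=13.5, c=3e5)


def _grid3():
    return build_seed_grid({"d_r": (3, 28), "d_a": (3, 28), "c": (1e3, 1e7)})


def _grid5():
    return build_seed_grid(
        {"a": (3, 28), "b": (3, 28), "c_": (3, 28), "d": (3, 28), "c": (1e3, 1e7)}
    )


class TestForwardModel:
    def test_identical_states_give_zero(self, fdq_family):
        assert forward_deltaF(fdq_family[0], 9.0, 9.0, 1e5) == 0.0

    def test_antisymmetric_in_states(self, fdq_family):
        a = forward_deltaF(fdq_family[2], 7.0, 13.5, 2e5)
        b = forward_deltaF(fdq_family[2], 13.5, 7.0, 2e5)
        assert a == pytest.approx(-b, rel=1e-12)

    def test_hand_computed_difference(self, fdq_family):
        m = fdq_family[0]
        expected = 3e5 * (m(7.0) - m(13.5))
        assert forward_deltaF(m, 7.0, 13.5, 3e5) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_c_rejected(self, fdq_family):
        with pytest.raises(ValueError):
            forward_deltaF(fdq_family[0], 7.0, 13.5, 0.0)


class TestBootstrapResample:
    def test_singletons_reproduce_the_means(self):
        ds = QuenchingDataset({"a": [1.5], "b": [-2.0], "c": [0.7]})
        sets = bootstrap_resample(ds, n_sets=50, seed=0)
        assert np.allclose(sets, np.tile([1.5, -2.0, 0.7], (50, 1)))

    def test_requested_number_of_sets(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.1, n_replicates=5, seed=0)
        sets = bootstrap_resample(ds, n_sets=10_000, seed=1)
        assert sets.shape == (10_000, 6)

    def test_grand_mean_consistency(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.1, n_replicates=8, seed=2)
        sets = bootstrap_resample(ds, n_sets=5000, seed=3)
        for j, tag in enumerate(ds.fluorophores):
            boot_se = sets[:, j].std()
            assert abs(sets[:, j].mean() - ds.replicates[tag].mean()) <= 3 * boot_se

    def test_deterministic_under_seed(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.1, n_replicates=4, seed=4)
        a = bootstrap_resample(ds, n_sets=100, seed=9)
        b = bootstrap_resample(ds, n_sets=100, seed=9)
        assert np.array_equal(a, b)


class TestSeedGrid:
    def test_three_parameters_give_125_seeds(self):
        assert _grid3().size == 125

    def test_five_parameters_give_3125_seeds(self):
        assert _grid5().size == 3125

    def test_bounds_endpoints_present(self):
        grid = _grid3()
        for name, values in zip(grid.param_names, grid.param_values):
            if name == "c":
                assert values[0] == pytest.approx(1e3)
                assert values[-1] == pytest.approx(1e7)
            else:
                assert values[0] == 3.0 and values[-1] == 28.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            build_seed_grid({"d": (5.0, 5.0)})


class TestSinglePairFit:
    def test_noiseless_round_trip(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.0, n_replicates=1, seed=0)
        d_r, d_a, c, sse = fit_single_pair(ds.means(), fdq_family, _grid3())
        assert d_r == pytest.approx(TRUTH["d_r"], abs=0.1)
        assert d_a == pytest.approx(TRUTH["d_a"], abs=0.1)
        assert c == pytest.approx(TRUTH["c"], rel=0.01)

    def test_zero_sample_degenerates_to_equal_distances(self, fdq_family):
        d_r, d_a, c, sse = fit_single_pair(np.zeros(6), fdq_family, _grid3())
        assert sse == pytest.approx(0.0, abs=1e-18)
        assert forward_deltaF(fdq_family[0], d_r, d_a, c) == pytest.approx(0.0, abs=1e-9)

    def test_more_seeds_never_worse(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.1, n_replicates=3, seed=5)
        y = ds.means()
        sparse = build_seed_grid({"d_r": (3, 28), "d_a": (3, 28), "c": (1e3, 1e7)}, increments=2)
        dense = build_seed_grid({"d_r": (3, 28), "d_a": (3, 28), "c": (1e3, 1e7)}, increments=5)
        _, _, _, sse_sparse = fit_single_pair(y, fdq_family, sparse)
        _, _, _, sse_dense = fit_single_pair(y, fdq_family, dense)
        assert sse_dense <= sse_sparse + 1e-12

    def test_too_few_fluorophores_rejected(self, fdq_family):
        with pytest.raises(ValueError):
            fit_single_pair(np.zeros(2), fdq_family[:2], _grid3())


class TestDualPairFit:
    def test_noiseless_round_trip(self, fdq_family, fdq_family_ab):
        # geometrically consistent truth: alpha-beta distances 1 Angstrom shorter
        y = np.array(
            [forward_deltaF(m, TRUTH["d_r"], TRUTH["d_a"], TRUTH["c"]) for m in fdq_family]
        )
        daar, daaa, dabr, daba, c, sse = fit_dual_pair(y, fdq_family, fdq_family_ab, _grid5())
        assert daar == pytest.approx(TRUTH["d_r"], abs=0.2)
        assert daaa == pytest.approx(TRUTH["d_a"], abs=0.2)
        assert dabr == pytest.approx(TRUTH["d_r"] - 1.0, abs=0.2)
        assert daba == pytest.approx(TRUTH["d_a"] - 1.0, abs=0.2)
        assert abs(daar - dabr) <= 1.54
        assert abs(daaa - daba) <= 1.54

    def test_constraint_boundary_inclusive(self, fdq_family, fdq_family_ab):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.0, n_replicates=1, seed=0)
        model = DepetModel(ds, fdq_family, fdq_family_ab)
        res = model.fit(n_bootstrap=3, seed=0)
        # the synthetic ab-shift is 1.0 < 1.54, so every draw must be retained
        assert res.retained_fraction == 1.0
        for d_aa, d_ab in (("d_aa_r", "d_ab_r"), ("d_aa_a", "d_ab_a")):
            diff = np.abs(res.distribution(d_aa) - res.distribution(d_ab))
            assert np.all(diff <= 1.54 + 1e-9)


class TestDepetModelFit:
    def test_total_fit_count_accounting(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.1, n_replicates=3, seed=6)
        res = DepetModel(ds, fdq_family).fit(n_bootstrap=8, seed=0)
        assert res.grid.size == 125
        assert res.total_fits == 8 * 125

    def test_zero_noise_gives_tight_ci(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.0, n_replicates=3, seed=0)
        res = DepetModel(ds, fdq_family).fit(n_bootstrap=20, seed=1)
        for name in ("d_aa_r", "d_aa_a"):
            lo, hi = res.conf_int(name)
            assert hi - lo < 0.1

    def test_bitwise_determinism(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.1, n_replicates=4, seed=7)
        r1 = DepetModel(ds, fdq_family).fit(n_bootstrap=10, seed=3)
        r2 = DepetModel(ds, fdq_family).fit(n_bootstrap=10, seed=3)
        assert np.array_equal(r1.solutions, r2.solutions)

    def test_fitted_deltaF_close_to_observed(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.05, n_replicates=5, seed=8)
        res = DepetModel(ds, fdq_family).fit(n_bootstrap=20, seed=2)
        table = res.fitted_deltaF()
        scale = np.abs(table["observed_mean"]).max()
        assert np.allclose(table["fitted_mean"], table["observed_mean"], atol=0.2 * scale)

    def test_summary_mentions_parameters(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.1, n_replicates=3, seed=9)
        res = DepetModel(ds, fdq_family).fit(n_bootstrap=5, seed=0)
        text = res.summary()
        assert "d_aa_r" in text and "d_aa_a" in text and "95% CI" in text


class TestOrientationSummary:
    def _results_from_distributions(self, fdq_family, fdq_family_ab, d_aa, d_ab):
        """Build a DepetResults with prescribed distance distributions."""
        from depet.distance_fit import DepetResults, SeedGrid

        n = len(d_aa)
        ds = QuenchingDataset({m.fluorophore_tag: [0.0] for m in fdq_family})
        model = DepetModel(ds, fdq_family, fdq_family_ab)
        sol = np.column_stack(
            [d_aa, d_aa + 5.0, d_ab, d_ab + 5.0, np.full(n, 1e5), np.zeros(n)]
        )
        grid = SeedGrid(["x"], [np.array([0.0])])
        return DepetResults(
            model=model, mode="aa_ab", solutions=sol, n_bootstrap=n,
            retained_fraction=1.0, seed=0, grid=grid, total_fits=n,
        )

    def test_collinear_draws_give_zero_angle(self, fdq_family, fdq_family_ab):
        d_aa = np.full(50, 10.0)
        res = self._results_from_distributions(fdq_family, fdq_family_ab, d_aa, d_aa - 1.54)
        summary = res.orientation_summary()
        # arccos near cos=1 amplifies float rounding; 1e-5 deg is numerically exact
        assert summary["resting"]["angle_mean"] == pytest.approx(0.0, abs=1e-5)

    def test_known_angle_recovered(self, fdq_family, fdq_family_ab):
        from depet.geometry import planar_coordinates
        import math

        rng = np.random.default_rng(0)
        true_angle = 41.0
        d_aa = 10.0 + 0.1 * rng.standard_normal(200)
        coords = [planar_coordinates(d, true_angle) for d in d_aa]
        d_ab = np.array([math.hypot(c.x, c.y - 1.54) for c in coords])
        res = self._results_from_distributions(fdq_family, fdq_family_ab, d_aa, d_ab)
        summary = res.orientation_summary()
        jitter_se = 0.5  # generous bound: angle jitter from 1% distance jitter
        assert summary["resting"]["angle_mean"] == pytest.approx(true_angle, abs=3 * jitter_se)

    def test_side_chain_pointing_away_gives_obtuse_angles(self, fdq_family, fdq_family_ab):
        rng = np.random.default_rng(1)
        d_aa = 8.0 + 0.05 * rng.standard_normal(100)
        d_ab = d_aa + 1.2  # alpha-beta longer: side-chain points away
        res = self._results_from_distributions(fdq_family, fdq_family_ab, d_aa, d_ab)
        summary = res.orientation_summary()
        assert summary["resting"]["angle_mean"] > 90.0
        assert summary["resting"]["angle_ci"][0] > 90.0

    def test_aa_only_mode_rejected(self, fdq_family):
        ds = synth_quenching_dataset(fdq_family, **TRUTH, noise_cv=0.0, n_replicates=1, seed=0)
        res = DepetModel(ds, fdq_family).fit(n_bootstrap=3, seed=0)
        with pytest.raises(ValueError):
            res.orientation_summary()
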