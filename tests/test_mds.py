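import numpy as np
import pytest
from scipy import optimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import special_ortho_group
from sklearn import manifold

from emospace import (
    Configuration,
    MultiSourceMDS,
    init_configuration,
    kruskal_label,
    normalized_raw_stress,
    procrustes_align,
    scree,
    select_dimensionality,
    simulate_sources,
    smacof_multi,
    total_fit,
)
from emospace.exceptions import AlignmentError, DegenerateInputError
from emospace.proximity import ProximityMatrix


def _distance_source(coords, labels=None):
    labels = labels or [f"o{i}" for i in range(len(coords))]
    return ProximityMatrix(labels, squareform(pdist(coords)), "configuration_distance")


def brute_force_stress(source_matrices, coords):
    """Independent double-loop evaluation of normalized raw stress."""
    num = den = 0.0
    n = coords.shape[0]
    for delta in source_matrices:
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(coords[i] - coords[j])
                num += (delta[i, j] - d) ** 2
                den += delta[i, j] ** 2
    return num / den


class TestNormalizedRawStress:
    def test_exact_distances_give_zero_stress(self):
        rng = np.random.default_rng(0)
        coords = rng.standard_normal((6, 2))
        source = _distance_source(coords)
        config = Configuration(source.labels, coords)
        assert normalized_raw_stress([source], config) == pytest.approx(0.0, abs=1e-15)

    def test_coincident_points_give_stress_one(self):
        rng = np.random.default_rng(1)
        coords = rng.standard_normal((5, 2))
        source = _distance_source(coords)
        config = Configuration(source.labels, np.zeros((5, 2)))
        assert normalized_raw_stress([source], config) == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        deltas = []
        for _ in range(3):
            d = squareform(rng.uniform(0.1, 2.0, size=6))
            deltas.append(d)
        sources = [ProximityMatrix(list("abcd"), d, "configuration_distance") for d in deltas]
        coords = rng.standard_normal((4, 2))
        config = Configuration(list("abcd"), coords)
        assert normalized_raw_stress(sources, config) == pytest.approx(
            brute_force_stress(deltas, coords), abs=1e-12
        )

    def test_rigid_motions_leave_stress_unchanged(self):
        rng = np.random.default_rng(3)
        coords = rng.standard_normal((7, 3))
        source = _distance_source(coords)
        base = normalized_raw_stress([source], Configuration(source.labels, coords * 1.3))
        for seed in range(3):
            Q = special_ortho_group.rvs(3, random_state=seed)
            moved = coords * 1.3 @ Q + rng.standard_normal(3)
            transformed = normalized_raw_stress(
                [source], Configuration(source.labels, moved)
            )
            assert transformed == pytest.approx(base, abs=1e-12)

    def test_label_mismatch_and_degenerate_inputs_raise(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        source = _distance_source(coords)
        with pytest.raises(AlignmentError):
            normalized_raw_stress([source], Configuration(["x", "y", "z"], coords))
        zero = ProximityMatrix(source.labels, np.zeros((3, 3)), "configuration_distance")
        with pytest.raises(DegenerateInputError):
            normalized_raw_stress([zero], Configuration(source.labels, coords))


class TestInitConfiguration:
    def test_classical_recovers_a_planted_configuration(self):
        rng = np.random.default_rng(4)
        coords = rng.standard_normal((8, 3))
        coords -= coords.mean(axis=0)
        source = _distance_source(coords)
        init = init_configuration(8, 3, method="classical", sources=[source])
        planted = Configuration(source.labels, coords, centered=True)
        _, disparity = procrustes_align(planted, init)
        assert disparity < 1e-8

    def test_simplex_start_is_equilateral_for_three_objects(self):
        init = init_configuration(3, 2, method="simplex")
        d = pdist(init.coordinates)
        assert np.ptp(d) < 1e-12
        assert init.is_centered(1e-12)

    def test_random_start_is_seed_deterministic(self):
        a = init_configuration(5, 2, method="random", seed=11)
        b = init_configuration(5, 2, method="random", seed=11)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_classical_rank_limit(self):
        rng = np.random.default_rng(5)
        source = _distance_source(rng.standard_normal((4, 2)))
        with pytest.raises(ValueError):
            init_configuration(4, 4, method="classical", sources=[source])


class TestSmacof:
    def test_zero_noise_recovery_of_a_planted_space(self, planted_configuration):
        sources = simulate_sources(planted_configuration, n_sources=1, noise_sd=0.0)
        result = smacof_multi(sources, p=3, tol=1e-12)
        assert result.stress < 1e-6
        _, disparity = procrustes_align(planted_configuration, result.configuration)
        assert disparity < 1e-3

    def test_stress_is_monotone_under_majorization(self, planted_configuration):
        sources = simulate_sources(planted_configuration, n_sources=4,
                                   noise_sd=0.1, seed=9)
        result = smacof_multi(sources, p=3, init="random", seed=2, tol=1e-10)
        improvements = [step.improvement for step in result.trajectory[1:]]
        assert min(improvements) >= -1e-12

    def test_final_stress_matches_a_multistart_optimizer_oracle(self):
        """On a 5-object 2D problem, direct numerical minimisation over all
        coordinates should not beat the majorizer by more than 1e-4."""
        rng = np.random.default_rng(6)
        delta = squareform(rng.uniform(0.5, 2.0, size=10))
        source = ProximityMatrix([f"o{i}" for i in range(5)], delta,
                                 "configuration_distance")
        den = np.sum(squareform(delta) ** 2)

        def objective(flat):
            coords = flat.reshape(5, 2)
            d = pdist(coords)
            return float(np.sum((squareform(delta) - d) ** 2) / den)

        best = np.inf
        for s in range(50):
            x0 = np.random.default_rng(s).standard_normal(10)
            res = optimize.minimize(objective, x0, method="L-BFGS-B")
            best = min(best, res.fun)

        result = smacof_multi([source], p=2, tol=1e-12, max_iter=5000,
                              n_restarts=10, seed=0)
        assert result.stress <= best + 1e-4

    def test_agrees_with_sklearn_smacof_on_the_pooled_problem(self, planted_configuration):
        """Pooled multi-source stress equals weighted single-matrix stress on
        the mean source; sklearn's SMACOF on that mean matrix is an
        independent route to (nearly) the same optimum."""
        sources = simulate_sources(planted_configuration, n_sources=4,
                                   noise_sd=0.05, seed=3)
        mean_delta = np.mean([s.values for s in sources], axis=0)
        emb, _ = manifold.smacof(
            mean_delta, metric=True, n_components=3, n_init=8, random_state=0,
            eps=1e-9, max_iter=500, normalized_stress=False,
        )
        sk_config = Configuration(list(planted_configuration.labels), emb)
        ours = smacof_multi(sources, p=3, tol=1e-10)
        sk_stress = normalized_raw_stress(sources, sk_config)
        assert ours.stress <= sk_stress + 1e-4

    def test_deterministic_given_seed(self, planted_configuration):
        sources = simulate_sources(planted_configuration, 4, 0.05, seed=5)
        a = smacof_multi(sources, p=3, init="random", seed=7)
        b = smacof_multi(sources, p=3, init="random", seed=7)
        np.testing.assert_array_equal(a.configuration.coordinates,
                                      b.configuration.coordinates)
        assert a.stress == b.stress

    def test_result_configuration_is_centered_and_fit_complements_stress(
        self, planted_configuration
    ):
        sources = simulate_sources(planted_configuration, 4, 0.05, seed=8)
        result = smacof_multi(sources, p=3)
        assert result.configuration.is_centered(1e-9)
        assert result.fit + result.stress == 1.0
        assert result.converged

    def test_estimator_follows_sklearn_conventions(self, planted_configuration):
        est = MultiSourceMDS(n_components=2, random_state=0)
        params = est.get_params()
        assert params["n_components"] == 2
        est.set_params(n_components=3)
        sources = simulate_sources(planted_configuration, 2, 0.02, seed=1)
        emb = est.fit_transform(sources)
        assert emb.shape == (16, 3)
        assert est.fit_ == pytest.approx(1.0 - est.stress_)

    def test_simplex_start_also_converges(self, planted_configuration):
        sources = simulate_sources(planted_configuration, 4, 0.0)
        result = smacof_multi(sources, p=3, init="simplex", tol=1e-12, max_iter=5000)
        assert result.stress < 1e-6


class TestFitAndLabels:
    def test_total_fit_complements_stress(self):
        assert total_fit(0.04) == pytest.approx(0.96)
        assert total_fit(0.0) == 1.0
        assert total_fit(1.0) == 0.0

    def test_total_fit_rejects_out_of_range_stress(self):
        with pytest.raises(ValueError):
            total_fit(1.5)
        with pytest.raises(ValueError):
            total_fit(-0.1)

    @pytest.mark.parametrize(
        "stress,label",
        [
            (0.0, "perfect"),
            (0.01, "excellent"),
            (0.025, "excellent"),
            (0.05, "good"),
            (0.07, "fair"),
            (0.1, "fair"),
            (0.2, "poor"),
            (0.3, "unacceptable"),
        ],
    )
    def test_kruskal_rule_of_thumb_bins(self, stress, label):
        assert kruskal_label(stress) == label

    def test_negative_stress_is_rejected(self):
        with pytest.raises(ValueError):
            kruskal_label(-0.01)


class TestScree:
    def test_planted_3d_data_saturates_at_three_dimensions(self, planted_configuration):
        sources = simulate_sources(planted_configuration, 4, 0.0)
        table = scree(sources, p_range=range(1, 6), tol=1e-12).table
        fit3 = table.loc[table["p"] == 3, "fit"].iloc[0]
        gain4 = table.loc[table["p"] == 4, "gain"].iloc[0]
        assert fit3 == pytest.approx(1.0, abs=1e-9)
        assert gain4 < 1e-6

    def test_warm_started_fit_is_nondecreasing_in_p(self, planted_configuration):
        sources = simulate_sources(planted_configuration, 4, 0.1, seed=13)
        table = scree(sources, p_range=range(1, 6), warm_start=True).table
        fits = table["fit"].to_numpy()
        assert np.all(np.diff(fits) >= -1e-9)

    def test_single_dimensionality_gives_one_row(self, planted_configuration):
        sources = simulate_sources(planted_configuration, 4, 0.0)
        table = scree(sources, p_range=[1]).table
        assert len(table) == 1
        assert np.isnan(table["gain"].iloc[0])


class TestSelectDimensionality:
    def _table(self, fits):
        import pandas as pd

        from emospace import ScreeTable

        gains = [np.nan] + list(np.diff(fits))
        return ScreeTable(pd.DataFrame({
            "p": range(1, len(fits) + 1),
            "stress": 1 - np.asarray(fits),
            "fit": fits,
            "gain": gains,
        }))

    def test_first_subthreshold_successor_wins(self):
        fits = np.cumsum([0.5, 0.2, 0.1, 0.005, 0.004])
        chosen = select_dimensionality(self._table(fits), gain_threshold=0.01)
        assert chosen.p == 3
        assert not chosen.saturated_range

    def test_all_gains_above_threshold_returns_max_p_with_warning(self):
        fits = np.cumsum([0.3, 0.2, 0.2])
        with pytest.warns(UserWarning):
            chosen = select_dimensionality(self._table(fits), gain_threshold=0.01)
        assert chosen.p == 3
        assert chosen.saturated_range

    def test_planted_2d_noiseless_data_selects_two_dimensions(self):
        rng = np.random.default_rng(21)
        coords = rng.standard_normal((10, 2))
        coords -= coords.mean(axis=0)
        config = Configuration([f"o{i}" for i in range(10)], coords, centered=True)
        sources = simulate_sources(config, 4, 0.0)
        table = scree(sources, p_range=range(1, 5), tol=1e-12)
        assert select_dimensionality(table).p == 2
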