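import numpy as np
import pytest
from scipy import stats

from osteomorph import (allometry_test, cluster_consistency, dimorphism_scan,
                        fit_gmm_1d, gpa, label_accuracy, pca, repeatability_experiment)
from osteomorph.io_formats import LandmarkConfiguration
from osteomorph.morphostats import _em_1d, _quantile_init


def _config(points, sid="s"):
    p = len(points)
    return LandmarkConfiguration(sid, "complete_femur", "left", points,
                                 np.full(p, "anatomical"), np.full(p, -1))


class TestPCA:
    def test_single_direction_of_variation(self, rng):
        # aligned shapes varying along exactly one direction in shape space
        from osteomorph.geometry_core import GPAResult
        base = rng.normal(size=(10, 3))
        direction = rng.normal(size=(10, 3))
        aligned = [base + t * direction for t in (-0.02, 0.0, 0.02)]
        g = GPAResult(aligned=aligned, consensus=np.mean(aligned, axis=0),
                      centroid_sizes=np.ones(3), specimen_ids=list("abc"),
                      iterations=1, converged=True)
        p = pca(g)
        assert p.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_completeness(self, rng):
        configs = [_config(rng.normal(size=(10, 3)), sid=f"s{i}") for i in range(10)]
        g = gpa(configs)
        p = pca(g)
        X = np.stack([a.ravel() for a in g.aligned])
        recon = p.mean_flat + p.scores @ p.loadings
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal_scores_centered_fractions_sum(self, default_population):
        p = pca(gpa([s.config for s in default_population]))
        np.testing.assert_allclose(p.loadings @ p.loadings.T,
                                   np.eye(p.n_components), atol=1e-8)
        np.testing.assert_allclose(p.scores.mean(axis=0), 0.0, atol=1e-10)
        assert p.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(p.variance_fraction) <= 1e-12)

    def test_sign_convention(self, default_population):
        p = pca(gpa([s.config for s in default_population]))
        k = np.argmax(np.abs(p.loadings), axis=1)
        assert np.all(p.loadings[np.arange(p.n_components), k] > 0)

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            pca(gpa([_config(rng.normal(size=(5, 3)), sid=f"s{i}") for i in range(2)]))


class TestGMM1D:
    def test_separable_five_values(self):
        with pytest.warns(UserWarning, match="distinct"):
            r = fit_gmm_1d(np.array([0.0, 0.0, 0.0, 10.0, 10.0]))
        assert r.selected_G == 2
        assert (r.assignments == np.array([0, 0, 0, 1, 1])).all()
        np.testing.assert_allclose(r.mixing_proportions, [0.6, 0.4], atol=1e-6)

    def test_identical_values_warn_and_return_g1(self):
        with pytest.warns(UserWarning, match="distinct"):
            r = fit_gmm_1d(np.full(10, 3.0))
        assert r.selected_G == 1 and r.variances[0] == 0.0

    def test_bic_table_is_complete_and_selection_maximal(self, rng):
        r = fit_gmm_1d(rng.normal(size=100), G_max=4, seed=3)
        assert set(r.bic_table) == {(v, g) for v in ("equal_variance", "variable_variance")
                                    for g in range(1, 5)}
        assert r.bic_table[(r.selected_model, r.selected_G)] == max(r.bic_table.values())

    def test_posteriors_and_proportions_normalised(self, rng):
        x = np.concatenate([rng.normal(-2, 1, 60), rng.normal(2, 1, 60)])
        r = fit_gmm_1d(x, seed=0)
        np.testing.assert_allclose(r.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert r.mixing_proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_em_loglik_monotone(self, rng):
        x = np.concatenate([rng.normal(-1, 1, 50), rng.normal(3, 0.5, 50)])
        mu0, var0, pi0 = _quantile_init(x, 3)
        *_, hist = _em_1d(x, mu0[None], var0[None], pi0[None], False, track_history=True)
        ll = hist[:, 0]
        ll = ll[np.isfinite(ll)]
        assert np.all(np.diff(ll) >= -1e-7 * np.maximum(np.abs(ll[:-1]), 1.0))

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_gmm_1d(np.arange(4.0))


class TestAllometry:
    def test_perfect_correlation(self, rng):
        lcs = rng.normal(size=20)
        r = allometry_test(2.0 * lcs, lcs)
        assert r.r == pytest.approx(1.0)

    def test_orthogonal_scores(self):
        lcs = np.array([-1.0, 0.0, 1.0, 2.0])
        scores = np.array([1.0, -1.0, -1.0, 1.0])
        scores -= scores.mean()
        lcs_c = lcs - lcs.mean()
        scores -= (scores @ lcs_c) / (lcs_c @ lcs_c) * lcs_c
        assert abs(allometry_test(scores, lcs).r) < 1e-12

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        res = allometry_test(y, x)
        # independent hand evaluation of the product-moment formula
        r_hand = (((x - 3) * (y - 3)).sum()
                  / np.sqrt(((x - 3) ** 2).sum() * ((y - 3) ** 2).sum()))
        assert res.r == pytest.approx(r_hand, rel=1e-12)
        assert res.p_value == pytest.approx(stats.pearsonr(y, x).pvalue, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate variance"):
            allometry_test(np.ones(10), np.arange(10.0))


class TestDimorphismScan:
    def test_recovers_planted_dimorphism(self, small_template, default_population):
        g = gpa([s.config for s in default_population])
        p = pca(g)
        scan = dimorphism_scan(p, g, seed=0)
        flagged = [ax for ax, s in scan.items() if s.flagged]
        assert flagged == [1]
        truth = np.array([s.truth["morph"] for s in default_population])
        assert label_accuracy(scan[1].gmm.assignments, truth) >= 0.9

    def test_size_confounded_axis_not_flagged(self, small_template):
        from osteomorph import PopulationSpec, generate_population
        pop = generate_population(
            PopulationSpec(n=40, seed=0, size_morph_coupling=0.2), small_template
        )
        g = gpa([s.config for s in pop])
        p = pca(g)
        scan = dimorphism_scan(p, g, seed=0)
        assert scan[1].allometry.p_value < 0.05
        assert not scan[1].flagged


class TestRepeatability:
    def test_thirty_configurations_and_separation(self, small_template, rng):
        base = small_template.config.points
        specimens = [
            _config(base + rng.normal(0, 2.0, base.shape), sid=f"b{i}") for i in range(3)
        ]
        res = repeatability_experiment(specimens, n_rep=10, operator_noise=0.2, seed=1)
        assert len(res["configs"]) == 30
        assert res["separation"] > 1.0

    def test_identical_specimens_warn(self, small_template):
        base = small_template.config
        specimens = [base.with_points(base.points, specimen_id=f"b{i}") for i in range(3)]
        with pytest.warns(UserWarning, match="separation"):
            res = repeatability_experiment(specimens, operator_noise=0.5, seed=0)
        assert res["separation"] <= 1.0

    def test_argument_validation(self, small_template):
        base = small_template.config
        with pytest.raises(ValueError, match="exactly 3"):
            repeatability_experiment([base, base], operator_noise=1.0)
        with pytest.raises(ValueError, match="positive"):
            repeatability_experiment([base] * 3, operator_noise=0.0)


class TestClusterConsistency:
    def test_identical_assignments(self):
        a = {f"s{i}": i % 2 for i in range(6)}
        assert cluster_consistency(a, a) == {"n_shared": 6, "n_consistent": 6}

    def test_label_swap_invariance(self):
        a = {f"s{i}": i % 2 for i in range(6)}
        b = {k: 1 - v for k, v in a.items()}
        assert cluster_consistency(a, b)["n_consistent"] == 6

    def test_matches_bruteforce_bijection_search(self, rng):
        for _ in range(20):
            ids = [f"s{i}" for i in range(10)]
            a = dict(zip(ids, rng.integers(0, 2, 10)))
            b = dict(zip(ids, rng.integers(0, 2, 10)))
            res = cluster_consistency(a, b)
            brute = max(
                sum(mapping[b[i]] == a[i] for i in ids)
                for mapping in ({0: 0, 1: 1}, {0: 1, 1: 0})
            )
            assert res["n_consistent"] == brute

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            cluster_consistency({"a": 0}, {"b": 1})
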