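import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from pharmaniche.io_geo import OccurrenceSet, extract_values
from pharmaniche.sdm_maxent import (auc, auc_grade, fit_maxent, fit_replicates,
                                    jackknife_gains, percent_contribution,
                                    permutation_importance, predict_suitability,
                                    response_curve, sample_background,
                                    train_test_split)


def _toy_data(seed=0, n_p=40, n_b=400, beta1=2.0):
    """Presences drawn from exp(beta1·x1) over a background of two covariates."""
    rng = np.random.default_rng(seed)
    bg = pd.DataFrame({"x1": rng.normal(size=n_b), "x2": rng.normal(size=n_b)})
    w = np.exp(beta1 * bg["x1"])
    idx = rng.choice(n_b, size=n_p, replace=False, p=w / w.sum())
    return bg.iloc[idx].reset_index(drop=True), bg


class TestFit:
    def test_zero_iterations_gives_uniform_model(self):
        pres, bg = _toy_data()
        m = fit_maxent(pres, bg, max_iter=0)
        assert np.all(m.lam == 0)
        scores = m.raw_scores(bg)
        np.testing.assert_allclose(scores, 1 / m.n_sample, rtol=1e-9)

    def test_sign_recovery_on_simulated_presences(self):
        pres, bg = _toy_data(seed=1)
        m = fit_maxent(pres, bg, seed=1)
        j = next(i for i, d in enumerate(m.features.definitions)
                 if d.layer == "x1" and d.kind == "linear")
        assert m.lam[j] > 0

    def test_huge_regularization_shrinks_everything_to_zero(self):
        pres, bg = _toy_data(seed=2)
        m = fit_maxent(pres, bg, reg_multiplier=1e6)
        assert np.all(np.abs(m.lam) < 1e-6)

    def test_raw_distribution_sums_to_one_on_fitting_sample(self):
        pres, bg = _toy_data(seed=3)
        m = fit_maxent(pres, bg, seed=3)
        union = pd.concat([pres, bg], ignore_index=True)
        assert m.raw_scores(union).sum() == pytest.approx(1.0, abs=1e-8)
        assert m.entropy_H >= 0

    def test_nonfinite_covariates_rejected(self):
        pres, bg = _toy_data()
        pres.loc[0, "x1"] = np.nan
        with pytest.raises(ValueError):
            fit_maxent(pres, bg)

    def test_constant_feature_dropped(self):
        pres, bg = _toy_data()
        pres["x3"] = 1.0
        bg["x3"] = 1.0
        m = fit_maxent(pres, bg)
        assert all(d.layer != "x3" for d in m.features.definitions)


class TestPredict:
    def test_uniform_model_raw_constant(self, small_scene):
        stack, _, occ = small_scene
        tab = extract_values(stack, occ)
        tab = tab[tab["valid"]]
        bg = sample_background(stack, seed=0)
        kinds = {l.name: l.kind for l in stack.layers}
        m = fit_maxent(tab, bg, kinds, max_iter=0)
        raw = predict_suitability(m, stack, output="raw")
        np.testing.assert_allclose(raw.values.compressed(), 1 / m.n_sample)

    def test_cloglog_monotone_in_raw(self):
        pres, bg = _toy_data(seed=4)
        m = fit_maxent(pres, bg, seed=4)
        raw = m.raw_scores(bg)
        clog = m.transform(raw, "cloglog")
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= 0)
        assert np.all((clog >= 0) & (clog <= 1))

    def test_logistic_fixed_point(self):
        pres, bg = _toy_data()
        m = fit_maxent(pres, bg, max_iter=0)
        # choose raw with q·e^H = 1
        raw = np.array([np.exp(-m.entropy_H)])
        assert m.transform(raw, "logistic")[0] == pytest.approx(0.5)

    def test_missing_layer_named_in_error(self, small_scene):
        stack, _, occ = small_scene
        tab = extract_values(stack, occ)
        tab = tab[tab["valid"]]
        bg = sample_background(stack, seed=0)
        kinds = {l.name: l.kind for l in stack.layers}
        m = fit_maxent(tab, bg, kinds, max_iter=50)
        partial = stack.subset([n for n in stack.names if n != "env01"])
        with pytest.raises(ValueError, match="env01"):
            predict_suitability(m, partial)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 1, 1], [0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.3, 0.3], [0.3, 0.3, 0.3]) == 0.5

    def test_small_enumerated_instance(self):
        # 4 pairs: 0.9 beats both; 0.8 beats 0.7, loses to 0.85 -> 3/4
        assert auc([0.9, 0.8], [0.7, 0.85]) == pytest.approx(0.75)

    def test_equals_mann_whitney_u_over_n1n2(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 20, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            u = mannwhitneyu(a, b, alternative="two-sided").statistic
            assert auc(a, b) == pytest.approx(u / (n1 * n2))

    def test_grades(self):
        assert auc_grade(0.55) == "fails"
        assert auc_grade(0.65) == "poor"
        assert auc_grade(0.85) == "good"
        assert auc_grade(0.95) == "excellent"


class TestSplit:
    def test_published_sample_size_split(self):
        occ = OccurrenceSet("A", [(i * 0.001, 0.0) for i in range(207)])
        train, test = train_test_split(occ, 0.25, seed=0)
        assert len(test) == 52 and len(train) == 155

    def test_disjoint_union(self):
        occ = OccurrenceSet("A", [(i * 0.001, 0.0) for i in range(40)])
        train, test = train_test_split(occ, 0.25, seed=1)
        assert sorted(train.points + test.points) == sorted(occ.points)

    def test_same_seed_same_split(self):
        occ = OccurrenceSet("A", [(i * 0.001, 0.0) for i in range(40)])
        assert train_test_split(occ, 0.25, seed=5)[1].points == \
            train_test_split(occ, 0.25, seed=5)[1].points

    def test_empty_test_set_rejected(self):
        occ = OccurrenceSet("A", [(i * 0.001, 0.0) for i in range(10)])
        with pytest.raises(ValueError):
            train_test_split(occ, 0.01)


class TestContribution:
    def test_single_layer_gets_everything(self):
        pres, bg = _toy_data(seed=6)
        m = fit_maxent(pres[["x1"]], bg[["x1"]], {"x1": "continuous"}, seed=6)
        pc = percent_contribution(m)
        assert pc["x1"] == pytest.approx(100.0)

    def test_sums_to_100(self):
        pres, bg = _toy_data(seed=7)
        m = fit_maxent(pres, bg, seed=7)
        assert percent_contribution(m).sum() == pytest.approx(100.0, abs=0.1)

    def test_dominant_generating_layer_ranks_first(self):
        """A single strongly weighted layer should top the contribution table
        in nearly every replicate."""
        from pharmaniche.synthetic_data import gen_env_stack, gen_occurrences
        wins = 0
        for seed in range(10):
            stack, truth = gen_env_stack(nrows=60, ncols=60, n_continuous=4,
                                         n_categorical=0, collinear_pairs=0,
                                         smoothness=4, seed=seed)
            truth.true_weights = {"env02": 2.5}
            occ = gen_occurrences(stack, truth, n_points=120, seed=seed)
            tab = extract_values(stack, occ)
            tab = tab[tab["valid"]]
            bg = sample_background(stack, seed=seed)
            m = fit_maxent(tab, bg, {n: "continuous" for n in stack.names},
                           seed=seed)
            if percent_contribution(m).idxmax() == "env02":
                wins += 1
        assert wins >= 9


class TestPermutationImportance:
    def test_unused_layer_zero_and_sum_100(self):
        pres, bg = _toy_data(seed=8)
        pres["x3"] = np.random.default_rng(8).normal(size=len(pres))
        bg["x3"] = np.random.default_rng(9).normal(size=len(bg))
        m = fit_maxent(pres, bg, seed=8)
        # force x3's features to zero weight
        for i, d in enumerate(m.features.definitions):
            if d.layer == "x3":
                m.lam[i] = 0.0
        imp = permutation_importance(m, pres, bg, n_perm=3, seed=8)
        assert imp["x3"] == pytest.approx(0.0)
        assert imp.sum() == pytest.approx(100.0, abs=0.1)

    def test_dominant_layer_ranks_first(self):
        wins = 0
        for seed in range(10):
            pres, bg = _toy_data(seed=seed, beta1=2.5)
            m = fit_maxent(pres, bg, seed=seed)
            imp = permutation_importance(m, pres, bg, n_perm=3, seed=seed)
            if imp.idxmax() == "x1":
                wins += 1
        assert wins >= 9


class TestJackknife:
    def test_redundant_duplicate_and_noise_layer(self):
        pres, bg = _toy_data(seed=10, n_p=60, n_b=600)
        rng = np.random.default_rng(10)
        pres = pres.copy()
        bg = bg.copy()
        pres["x1dup"] = pres["x1"]
        bg["x1dup"] = bg["x1"]
        pres["noise"] = rng.normal(size=len(pres))
        bg["noise"] = rng.normal(size=len(bg))
        kinds = {c: "continuous" for c in bg.columns}
        jk = jackknife_gains(pres, bg, kinds, seed=10)
        full = jk.attrs["gain_full"]
        assert np.all(jk["gain_with_only"] >= 0)
        assert np.all(jk["gain_without"] <= full + 1e-6)
        # removing one member of a duplicated pair costs almost nothing
        assert abs(jk.loc["x1dup", "gain_without"] - full) < 0.05
        # a pure-noise layer explains almost nothing alone
        assert jk.loc["noise", "gain_with_only"] < 0.05


class TestResponseCurve:
    def test_flat_for_uniform_model(self):
        pres, bg = _toy_data()
        m = fit_maxent(pres, bg, max_iter=0)
        rc = response_curve(m, "x1", bg)
        assert np.ptp(rc.suitability) < 1e-12

    def test_threshold_ranges_match_dense_scan(self):
        pres, bg = _toy_data(seed=11)
        m = fit_maxent(pres, bg, seed=11)
        rc = response_curve(m, "x1", bg, n_grid=200)
        above = rc.suitability > 0.30
        # oracle: re-derive intervals from the dense curve directly
        edges = np.flatnonzero(np.diff(above.astype(int)))
        n_runs = int(above[0]) + (np.diff(above.astype(int)) == 1).sum()
        assert len(rc.suitable_range_030) == n_runs
        for lo, hi in rc.suitable_range_030:
            assert lo <= hi

    def test_categorical_layer_rejected(self, small_scene):
        stack, _, occ = small_scene
        tab = extract_values(stack, occ)
        tab = tab[tab["valid"]]
        bg = sample_background(stack, seed=0)
        kinds = {l.name: l.kind for l in stack.layers}
        m = fit_maxent(tab, bg, kinds, max_iter=20)
        with pytest.raises(ValueError):
            response_curve(m, "soil01", bg)


class TestReplicates:
    def test_average_within_replicate_envelope_and_determinism(self, small_scene):
        stack, _, occ = small_scene
        mean_map, metrics = fit_replicates(occ, stack, n_replicates=3, seed=4,
                                           max_iter=100)
        maps = metrics.attrs["replicate_maps"]
        stackv = np.ma.stack([m.values for m in maps])
        assert np.all(mean_map.values >= stackv.min(axis=0) - 1e-12)
        assert np.all(mean_map.values <= stackv.max(axis=0) + 1e-12)
        mean2, metrics2 = fit_replicates(occ, stack, n_replicates=3, seed=4,
                                         max_iter=100)
        np.testing.assert_array_equal(np.ma.filled(mean_map.values, -1),
                                      np.ma.filled(mean2.values, -1))
        pd.testing.assert_frame_equal(metrics[["auc_train", "auc_test"]],
                                      metrics2[["auc_train", "auc_test"]])

    def test_single_replicate_equals_single_fit_map(self, small_scene):
        stack, _, occ = small_scene
        mean_map, metrics = fit_replicates(occ, stack, n_replicates=1, seed=9,
                                           max_iter=100)
        only = metrics.attrs["replicate_maps"][0]
        np.testing.assert_allclose(np.ma.filled(mean_map.values, -1),
                                   np.ma.filled(only.values, -1))
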