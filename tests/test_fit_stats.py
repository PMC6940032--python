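"""Fit statistics: closed-form examples, invariances, and small oracles."""

import itertools

import numpy as np
import pytest

import irtqol as q
from irtqol.fit_stats import _implied_score_correlations, _lw_rest_distribution
from irtqol.items import category_probabilities

from conftest import frozen_model, make_grm_items


class TestInformationCriteria:
    def test_aic_formula(self, uni_fit):
        _, _, model = uni_fit
        fake = frozen_model(model.structure, model.items)
        fake.loglik, fake.n_params, fake.n_persons = -100.0, 5, 100
        aic, bic = q.information_criteria(fake)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(223.0259, abs=1e-4)

    def test_nonconverged_rejected(self, uni_fit):
        _, _, model = uni_fit
        bad = frozen_model(model.structure, model.items)
        bad.converged = False
        with pytest.raises(ValueError, match="converged"):
            q.information_criteria(bad)

    def test_nested_models_deviance_ordering(self, uni_fit):
        spec, data, model = uni_fit
        null = q.fit_null(data, spec.structure)
        # the larger (fitted) model can never have larger -2 loglik
        assert -2 * model.loglik <= -2 * null.loglik


class TestM2:
    def test_saturated_independence_gives_zero(self):
        """When model margins equal observed margins exactly, M2 = 0."""
        patterns = np.array(list(itertools.product([0, 1], repeat=2)))
        values = np.repeat(patterns, 25, axis=0)  # perfectly balanced
        data = q.ResponseMatrix(values, ("a", "b"))
        s = q.build_structure("unidimensional", 2)
        null = q.fit_null(data, s)
        m2, df, p = q.m2_statistic(data, null)
        assert m2 == pytest.approx(0.0, abs=1e-16)

    def test_person_order_invariance(self, uni_fit):
        spec, data, model = uni_fit
        m2a, dfa, _ = q.m2_statistic(data, model)
        perm = np.random.default_rng(1).permutation(data.n_persons)
        m2b, dfb, _ = q.m2_statistic(data.subset(perm), model)
        assert dfa == dfb
        assert m2a == pytest.approx(m2b, rel=1e-10)

    def test_degrees_of_freedom_accounting(self, uni_fit):
        spec, data, model = uni_fit
        _, df, _ = q.m2_statistic(data, model)
        Ks = model.n_categories()
        s_stats = sum(k - 1 for k in Ks) + sum(
            (Ks[i] - 1) * (Ks[j] - 1)
            for i, j in itertools.combinations(range(5), 2))
        assert df == s_stats - model.n_params

    def test_frozen_uses_full_df(self, uni_fit):
        spec, data, model = uni_fit
        m2f, dff, _ = q.m2_statistic(data, model, frozen=True)
        _, df, _ = q.m2_statistic(data, model)
        assert dff == df + model.n_params
        assert m2f >= 0

    def test_bifactor_margins_match_simulation(self, hads_fit):
        """Model-implied bivariate margins under dimension reduction agree
        with a direct Monte-Carlo simulation from the same parameters."""
        spec, data, model = hads_fit
        from irtqol.fit_stats import _MarginEngine

        me = _MarginEngine(model)
        sim_spec = q.SimulationSpec(model.structure, model.items, 200_000,
                                    seed=303)
        sim = q.simulate(sim_spec)
        pair = (0, 7)  # items in different clusters
        table = me.joint_table(pair)
        emp = np.zeros_like(table)
        for k in range(4):
            for l in range(4):
                emp[k, l] = np.mean((sim.values[:, pair[0]] == k)
                                    & (sim.values[:, pair[1]] == l))
        assert np.abs(table - emp).max() < 0.005


class TestRmsea:
    def test_zero_when_m2_below_df(self):
        point, (lo, hi) = q.rmsea_from_m2(25.0, 25, 1000)
        assert point == 0.0
        assert lo <= point <= hi + 1e-12

    def test_direct_formula(self):
        point, _ = q.rmsea_from_m2(50.0, 25, 1000)
        assert point == pytest.approx(0.031639, abs=1e-6)

    def test_interval_brackets_point(self):
        point, (lo, hi) = q.rmsea_from_m2(80.0, 30, 500)
        assert lo <= point <= hi

    def test_zero_df_rejected(self):
        with pytest.raises(ValueError):
            q.rmsea_from_m2(10.0, 0, 100)


class TestTliCfi:
    def test_direct_formula(self):
        tli, cfi = q.tli_cfi(50.0, 25, 1000.0, 50)
        assert tli == pytest.approx(0.947368, abs=1e-6)
        assert cfi == pytest.approx(0.973684, abs=1e-6)

    def test_perfect_fit(self):
        _, cfi = q.tli_cfi(25.0, 25, 1000.0, 50)
        assert cfi == 1.0

    def test_model_equal_null_gives_zero_tli(self):
        tli, _ = q.tli_cfi(1000.0, 50, 1000.0, 50)
        assert tli == pytest.approx(0.0)


class TestSrmsrAndResiduals:
    def test_implied_correlations_match_simulation_oracle(self, uni_setup):
        spec, data = uni_setup
        model = frozen_model(spec.structure, spec.items)
        implied = _implied_score_correlations(model)
        big = q.SimulationSpec(spec.structure, spec.items, 300_000, seed=71)
        sim = q.simulate(big)
        emp = np.corrcoef(sim.values.T)
        iu = np.triu_indices(5, k=1)
        assert np.abs(implied[iu] - emp[iu]).max() < 0.01

    def test_srmsr_nonnegative_and_small_under_truth(self, uni_setup):
        spec, data = uni_setup
        model = frozen_model(spec.structure, spec.items)
        v = q.srmsr(data, model)
        assert 0 <= v < 0.2

    def test_residuals_symmetric_zero_diagonal(self, uni_fit):
        spec, data, model = uni_fit
        resid, summary = q.residual_correlations(data, model)
        np.testing.assert_array_equal(resid, resid.T)
        np.testing.assert_array_equal(np.diag(resid), 0.0)

    def test_threshold_count_matches_manual(self, uni_fit):
        spec, data, model = uni_fit
        resid, summary = q.residual_correlations(data, model, threshold=0.02)
        iu = np.triu_indices(5, k=1)
        assert summary["n_above_threshold"] == int(
            np.sum(np.abs(resid[iu]) > 0.02))

    def test_residuals_shrink_with_n(self, uni_setup):
        """Self-simulation residuals shrink with N (in expectation, so
        averaged over a few independent seeds per sample size)."""
        spec, _ = uni_setup
        model = frozen_model(spec.structure, spec.items)
        maxima = {}
        for n in (2000, 20000):
            vals = []
            for seed in (5, 6, 7):
                sim = q.SimulationSpec(spec.structure, spec.items, n,
                                       seed=seed + 10 * (n == 20000))
                _, summary = q.residual_correlations(q.simulate(sim), model)
                vals.append(summary["max_abs"])
            maxima[n] = np.mean(vals)
        assert maxima[20000] < maxima[2000]
        assert maxima[20000] <= 0.03

    def test_constant_item_rejected(self, uni_setup):
        spec, data = uni_setup
        vals = data.values.copy()
        vals[:, 0] = 1
        const = q.ResponseMatrix(vals, data.item_labels)
        model = frozen_model(spec.structure, spec.items)
        with pytest.raises(ValueError, match="constant"):
            q.srmsr(const, model)


class TestSX2:
    def test_recursion_matches_enumeration(self):
        """Rest-score distribution equals exhaustive pattern enumeration."""
        rng = np.random.default_rng(7)
        for n_items, K in ((2, 3), (3, 4)):
            s = q.build_structure("unidimensional", n_items)
            items = make_grm_items(rng, n_items, K)
            model = frozen_model(s, items, quad=q.QuadratureSpec(11))
            theta = model.quadrature.nodes[:, None]
            S = _lw_rest_distribution(model, 0, theta)
            np.testing.assert_allclose(S.sum(axis=0), 1.0, atol=1e-12)
            enum = np.zeros_like(S)
            others = [p for j, p in enumerate(items) if j != 0]
            for pattern in itertools.product(*(range(K) for _ in others)):
                for qi, t in enumerate(theta[:, 0]):
                    prob = 1.0
                    for p, x in zip(others, pattern):
                        prob *= category_probabilities(p, [t])[x]
                    enum[sum(pattern), qi] += prob
            np.testing.assert_allclose(S, enum, atol=1e-12)

    def test_statistic_on_self_fit(self, uni_fit):
        spec, data, model = uni_fit
        stat, df, p, table = q.item_fit_sx2(data, model, 1)
        assert stat >= 0 and df >= 1
        assert 0 <= p <= 1
        # observed counts total the complete cases
        n_complete = data.complete_cases().n_persons
        assert table["observed"].sum() == pytest.approx(n_complete)

    def test_rejection_rate_near_nominal(self):
        """Under the generating model the S-X2 type-I error is near the
        nominal 5% level (200 replicates, all 5 items pooled)."""
        rng = np.random.default_rng(3)
        s = q.build_structure("unidimensional", 5)
        items = make_grm_items(rng, 5, 3)
        rejections = 0
        total = 0
        for r in range(200):
            data = q.simulate(q.SimulationSpec(s, items, 500, seed=20_000 + r))
            model = q.fit_em(data, s, seed=1, tol=1e-3)
            for j in range(5):
                _, _, p, _ = q.item_fit_sx2(data, model, j)
                rejections += p < 0.05
                total += 1
        assert 0.02 <= rejections / total <= 0.10

    def test_multidimensional_redirects(self, bifactor_toy):
        spec, data = bifactor_toy
        model = frozen_model(spec.structure, spec.items)
        with pytest.raises(ValueError, match="observed_expected_by_score"):
            q.item_fit_sx2(data, model, 0)


class TestObservedExpected:
    def test_proportions_sum_to_one(self, uni_fit):
        spec, data, model = uni_fit
        table = q.observed_expected_by_score(data, model, item=2, n_groups=5)
        for g, grp in table.groupby("group"):
            assert grp["observed"].sum() == pytest.approx(1.0, abs=1e-9)
            assert grp["expected"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_group_matches_margins(self, uni_fit):
        spec, data, model = uni_fit
        table = q.observed_expected_by_score(data, model, item=0, n_groups=1)
        col = data.values[:, 0]
        obs = col[col >= 0]
        for k in range(model.items[0].n_categories):
            row = table[table["category"] == k].iloc[0]
            assert row["observed"] == pytest.approx(np.mean(obs == k), abs=1e-12)

    def test_close_under_self_simulation(self, uni_setup):
        spec, _ = uni_setup
        big = q.SimulationSpec(spec.structure, spec.items, 10_000, seed=9)
        data = q.simulate(big)
        model = frozen_model(spec.structure, spec.items)
        table = q.observed_expected_by_score(data, model, item=3, n_groups=8)
        assert (table["observed"] - table["expected"]).abs().max() <= 0.05


class TestZh:
    def test_moments_match_enumeration(self):
        """Expectation/variance over all K^2 patterns of a 2-item toy."""
        rng = np.random.default_rng(11)
        s = q.build_structure("unidimensional", 2)
        items = make_grm_items(rng, 2, 3)
        model = frozen_model(s, items)
        theta = np.array([[0.37]])
        probs, l0s = [], []
        for pattern in itertools.product(range(3), repeat=2):
            prob = 1.0
            l0 = 0.0
            for p, x in zip(items, pattern):
                cp = category_probabilities(p, theta[0])
                prob *= cp[x]
                l0 += np.log(cp[x])
            probs.append(prob)
            l0s.append(l0)
        probs = np.array(probs)
        l0s = np.array(l0s)
        E = probs @ l0s
        V = probs @ l0s**2 - E**2
        # zh for each pattern must equal (l0 - E)/sqrt(V)
        values = np.array(list(itertools.product(range(3), repeat=2)))
        data = q.ResponseMatrix(values, ("a", "b"))
        scores = q.PersonScores(np.tile(theta, (9, 1)), np.ones((9, 1)),
                                "TRUE", tuple(range(9)), ("theta",))
        pf = q.zh_person_fit(data, model, scores)
        np.testing.assert_allclose(pf.zh, (l0s - E) / np.sqrt(V), atol=1e-10)
        # probability-weighted mean of zh is zero by construction
        assert probs @ pf.zh == pytest.approx(0.0, abs=1e-10)

    def test_undefined_below_two_responses(self, uni_setup):
        spec, data = uni_setup
        vals = data.values[:5].copy()
        vals[0, 1:] = -1  # one observed response only
        sub = q.ResponseMatrix(vals, data.item_labels)
        model = frozen_model(spec.structure, spec.items)
        scores = q.eap_scores(sub, model)
        pf = q.zh_person_fit(sub, model, scores)
        assert np.isnan(pf.zh[0])
        assert np.isfinite(pf.zh[1:]).all()

    def test_summary_percentages(self, uni_fit):
        spec, data, model = uni_fit
        scores = q.eap_scores(data, model)
        pf = q.zh_person_fit(data, model, scores)
        z = pf.zh[np.isfinite(pf.zh)]
        assert pf.summary["pct_misfit"] == pytest.approx(100 * np.mean(z < -2))
        assert pf.summary["pct_overfit"] == pytest.approx(100 * np.mean(z > 2))


def test_fit_report_fields(uni_fit):
    spec, data, model = uni_fit
    rep = q.fit_report(data, model)
    assert rep.df_m2 > 0
    assert rep.rmsea >= 0 and rep.srmsr >= 0
    assert 0 <= rep.cfi <= 1
    assert np.isfinite(rep.aic) and np.isfinite(rep.bic)
    row = rep.to_row()
    assert set(row) >= {"aic", "bic", "m2", "df", "rmsea", "srmsr", "tli", "cfi"}
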