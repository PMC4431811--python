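import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tracknest.io import trackset_from_frame
from tracknest.lmm import NestedLMM
from tracknest.motility import compute_steps
from tracknest.simulate import Design, SimConfig, simulate_experiment
from tracknest.stats import (
    IdentifiabilityError,
    ModelSpec,
    MotilityANOVA,
    analysis_ladder,
    fit_model,
    mann_whitney,
    rank_transform,
    t_test,
)

from conftest import make_track_frame


# ---------------------------------------------------------------------------
# rank transformation


class TestRankTransform:
    def test_distinct_values(self):
        np.testing.assert_array_equal(rank_transform([3.0, 1.0, 2.0]), [3, 1, 2])

    def test_ties_get_average_ranks(self):
        np.testing.assert_array_equal(rank_transform([5, 5, 1]), [2.5, 2.5, 1])

    def test_missing_stays_missing(self):
        out = rank_transform([2.0, np.nan, 1.0])
        assert np.isnan(out[1])
        assert out[0] == 2 and out[2] == 1

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            rank_transform([np.nan, np.nan])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
    def test_rank_sum_and_idempotence(self, values):
        r = rank_transform(values)
        n = len(values)
        assert np.sum(r) == pytest.approx(n * (n + 1) / 2)
        np.testing.assert_allclose(rank_transform(r), r)


# ---------------------------------------------------------------------------
# two-group tests


class TestTTest:
    def test_identical_groups(self):
        res = t_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        res = t_test(np.zeros(4) + rng.normal(0, 1e-6, 4),
                     np.ones(4) + rng.normal(0, 1e-6, 4))
        assert res.p_value < 1e-10

    def test_hand_computed_pooled_t(self):
        # groups (1..5) and (3..7): means 3 and 5, pooled var 2.5,
        # se = sqrt(2.5 * 2/5) = 1, t = -2, df = 8
        res = t_test([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert res.statistic == pytest.approx(-2.0)
        assert res.p_value == pytest.approx(2 * sps.t.sf(2.0, 8), abs=1e-12)
        assert res.group_estimates == {"group1": 3.0, "group2": 5.0}

    def test_both_groups_constant_and_equal(self):
        res = t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        assert res.flags


def exact_u_pvalue(g1, g2):
    """Brute-force two-sided Mann-Whitney p by enumerating all rank splits."""
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(g1), len(g2)
    mu = n1 * n2 / 2
    r1 = ranks[:n1].sum()
    u_obs = r1 - n1 * (n1 + 1) / 2
    dev = abs(u_obs - mu)
    count = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - mu) >= dev - 1e-12
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups_maximal_p(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        # U = 0; one-sided exact p = 1/C(6,3) = 1/20, two-sided = 1/10
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(2 / 20)
        assert res.group_estimates == {"group1": 2.0, "group2": 11.0}

    def test_small_sample_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(3, 9, 2)
            g1, g2 = rng.normal(0, 1, n1), rng.normal(0.5, 1, n2)
            res = mann_whitney(g1, g2)
            assert res.p_value == pytest.approx(exact_u_pvalue(g1, g2), abs=1e-12)

    def test_rank_route_matches_normal_approximation(self):
        """Conover-Iman route ~ tie-corrected normal MW for moderate n."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            g1 = rng.normal(0, 1, 30)
            g2 = rng.normal(0.3, 1.2, 35)
            p_rank = mann_whitney(g1, g2, small_n=0).p_value
            p_norm = sps.mannwhitneyu(g1, g2, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert p_rank == pytest.approx(p_norm, abs=0.01)


# ---------------------------------------------------------------------------
# model fitting


def balanced_2x2_steps(cell_means, n_cells=2, n_steps=3, noise=0.0, seed=0):
    """Step table with constant response per (population, dye) cell."""
    rng = np.random.default_rng(seed)
    frames = []
    tid = 0
    for (pop, dye), m in cell_means.items():
        for c in range(n_cells):
            xs = np.arange(n_steps + 1) * m  # speed == m um/min at dt=60s
            frames.append(make_track_frame(
                {f"c{tid}": {"points": [(x + rng.normal(0, noise), 0, 0) for x in xs],
                             "population": pop, "dye": dye}}))
            tid += 1
    ts = trackset_from_frame(pd.concat(frames, ignore_index=True))
    return compute_steps(ts)


class TestFactorialANOVA:
    def test_additive_2x2_recovery(self):
        steps = balanced_2x2_steps({
            ("WT", "CFSE"): 10, ("WT", "CMTMR"): 12,
            ("KO", "CFSE"): 20, ("KO", "CMTMR"): 22,
        })
        fit = fit_model(steps, ModelSpec())
        assert fit.grand_mean == pytest.approx(16.0)
        assert fit.population_effects["KO"] == pytest.approx(5.0)
        assert fit.population_effects["WT"] == pytest.approx(-5.0)
        assert fit.dye_effects["CFSE"] == pytest.approx(-1.0)
        assert fit.interaction_effects[("KO", "CFSE")] == pytest.approx(0.0, abs=1e-10)
        assert fit.variance_components["residual"] == pytest.approx(0.0, abs=1e-12)
        assert fit.population_estimates["KO"] == pytest.approx(21.0)

    def test_interaction_recovered(self):
        # hand solution of the sum-to-zero 2x2 system for means (10,12,20,18)
        steps = balanced_2x2_steps({
            ("WT", "CFSE"): 10, ("WT", "CMTMR"): 12,
            ("KO", "CFSE"): 20, ("KO", "CMTMR"): 18,
        })
        fit = fit_model(steps, ModelSpec())
        assert fit.grand_mean == pytest.approx(15.0)
        assert fit.population_effects["KO"] == pytest.approx(4.0)
        assert fit.dye_effects["CFSE"] == pytest.approx(0.0, abs=1e-10)
        assert fit.interaction_effects[("KO", "CFSE")] == pytest.approx(1.0)
        assert fit.interaction_effects[("WT", "CFSE")] == pytest.approx(-1.0)

    def test_two_group_ols_equals_t_test(self, null_sim):
        ts, _ = null_sim
        steps = compute_steps(ts)
        fit = fit_model(steps, ModelSpec(fixed=("population",)))
        pops = sorted(steps["population"].unique())
        a = steps.loc[steps.population == pops[0], "speed"]
        b = steps.loc[steps.population == pops[1], "speed"]
        tt = t_test(a, b)
        assert fit.p_population == pytest.approx(tt.p_value, rel=1e-10)
        assert fit.population_estimates[pops[0]] == pytest.approx(a.mean())

    def test_rank_two_group_fit_matches_mann_whitney(self, null_sim):
        ts, _ = null_sim
        steps = compute_steps(ts)
        fit = fit_model(steps, ModelSpec(fixed=("population",), rank_transform=True))
        pops = sorted(steps["population"].unique())
        a = steps.loc[steps.population == pops[0], "speed"].to_numpy()
        b = steps.loc[steps.population == pops[1], "speed"].to_numpy()
        p_norm = sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue
        assert fit.p_population == pytest.approx(p_norm, abs=0.01)
        # back-mapped estimates land near the group medians
        assert fit.population_estimates[pops[0]] == pytest.approx(
            np.median(a), rel=0.05)

    def test_sum_to_zero_and_nonnegative_variance(self):
        for seed in range(4):
            cfg = SimConfig(design=Design(1, 1, 1, 2, cells_per_field=12,
                                          max_frames=10),
                            sigma_cell=0.3, sigma_step=0.3,
                            censor_on_exit=False, seed=seed)
            ts, _ = simulate_experiment(cfg)
            steps = compute_steps(ts)
            fit = fit_model(steps, ModelSpec(random_chain=("cell",)))
            assert sum(fit.population_effects.values()) == pytest.approx(0, abs=1e-10)
            if fit.dye_effects:
                assert sum(fit.dye_effects.values()) == pytest.approx(0, abs=1e-10)
            assert all(v >= 0 for v in fit.variance_components.values())

    def test_marginal_means_invariant_to_dye_relabelling(self, null_sim):
        ts, _ = null_sim
        steps = compute_steps(ts)
        fit1 = fit_model(steps, ModelSpec())
        relabelled = steps.copy()
        relabelled["dye"] = relabelled["dye"].map(
            {"CFSE": "ZZZ-dye", "CMTMR": "AAA-dye"})
        fit2 = fit_model(relabelled, ModelSpec())
        for pop in fit1.population_estimates:
            assert fit2.population_estimates[pop] == pytest.approx(
                fit1.population_estimates[pop], abs=1e-8)

    def test_unidentifiable_interaction_raises(self):
        steps = balanced_2x2_steps({
            ("WT", "CFSE"): 10, ("KO", "CMTMR"): 20,
        })
        with pytest.raises(IdentifiabilityError):
            fit_model(steps, ModelSpec())

    def test_single_population_raises(self):
        steps = balanced_2x2_steps({("WT", "CFSE"): 10, ("WT", "CMTMR"): 12})
        with pytest.raises(IdentifiabilityError, match="two populations"):
            fit_model(steps, ModelSpec())


class TestMixedModel:
    def test_reml_matches_statsmodels(self, null_sim):
        """Independent oracle: statsmodels MixedLM on the same model."""
        import statsmodels.formula.api as smf

        ts, _ = null_sim
        steps = compute_steps(ts)
        fit = fit_model(steps, ModelSpec(fixed=("population",),
                                         random_chain=("cell",)))
        sm_fit = smf.mixedlm("speed ~ C(population, Sum)", data=steps,
                             groups=steps["uid_track"]).fit(reml=True)
        sg2_sm = float(sm_fit.cov_re.iloc[0, 0])
        # both optimisers agree to their convergence tolerance (ours attains
        # the lower REML criterion, so differences are statsmodels slack)
        assert fit.variance_components["cell"] == pytest.approx(sg2_sm, rel=5e-4)
        assert fit.variance_components["residual"] == pytest.approx(
            sm_fit.scale, rel=5e-4)
        assert fit.grand_mean == pytest.approx(sm_fit.params["Intercept"], rel=1e-6)

    def test_zero_cell_variance_reduces_to_factorial(self):
        cfg = SimConfig(design=Design(1, 1, 1, 2, cells_per_field=16, max_frames=12),
                        sigma_cell=0.0, sigma_step=0.3, censor_on_exit=False,
                        seed=9)
        ts, _ = simulate_experiment(cfg)
        steps = compute_steps(ts)
        mixed = fit_model(steps, ModelSpec(random_chain=("cell",)))
        fact = fit_model(steps, ModelSpec())
        for pop in fact.population_estimates:
            assert mixed.population_estimates[pop] == pytest.approx(
                fact.population_estimates[pop], abs=0.05)

    def test_boundary_flagged_when_component_vanishes(self):
        rng = np.random.default_rng(2)
        cell = np.repeat(np.arange(20), 5)
        y = rng.normal(0, 1, 100)  # no cell effect at all
        m = NestedLMM(np.ones((100, 1)), [("cell", cell)], y)
        fit = m.fit()
        if fit.variance_components["cell"] == 0.0:
            assert fit.boundary["cell"]

    def test_satterthwaite_df_balanced_one_way(self):
        """For K cells x n steps and an intercept contrast, df ~ K - 1."""
        rng = np.random.default_rng(4)
        K, n = 25, 8
        cell = np.repeat(np.arange(K), n)
        y = rng.normal(0, 1.0, K)[cell] + rng.normal(0, 0.5, K * n)
        m = NestedLMM(np.ones((K * n, 1)), [("cell", cell)], y)
        fit = m.fit()
        df = m.satterthwaite_df(fit, np.array([1.0]))
        assert df == pytest.approx(K - 1, rel=0.05)


class TestLadder:
    def test_eight_rows_and_labels(self, null_sim):
        ts, _ = null_sim
        steps = compute_steps(ts)
        rows = analysis_ladder(steps, response="speed")
        assert len(rows) == 8
        assert not any(r.skipped for r in rows)

    def test_single_dye_drops_terms_but_runs(self):
        cfg = SimConfig(design=Design(1, 1, 1, 1, cells_per_field=20, max_frames=10),
                        dye_weights={"WT": 1.0, "KO": 1.0},
                        censor_on_exit=False, seed=3)
        ts, _ = simulate_experiment(cfg)
        steps = compute_steps(ts)
        rows = analysis_ladder(steps, response="speed")
        fits = [r.result for r in rows if not r.skipped and hasattr(r.result, "dropped_terms")]
        assert fits and all("dye" in f.dropped_terms for f in fits)

    def test_single_population_rows_marked_skipped(self):
        steps = balanced_2x2_steps({("WT", "CFSE"): 10, ("WT", "CMTMR"): 12})
        rows = analysis_ladder(steps, response="speed")
        assert all(r.skipped for r in rows)
        assert "two populations" in rows[0].reason

    def test_angle_analyses_exclude_missing_listwise(self, null_sim):
        ts, _ = null_sim
        steps = compute_steps(ts)
        rows = analysis_ladder(steps, response="angle")
        fit = rows[2].result
        assert fit.n_obs == steps["angle"].notna().sum()


class TestAliasing:
    def _aliased_sim(self):
        cfg = SimConfig(design=Design(n_dates=3, n_mice=3, n_nodes=4, n_fields=6,
                                      cells_per_field=5, max_frames=12),
                        sigma_cell=0.3, sigma_step=0.3, sigma_mouse=0.1,
                        censor_on_exit=False, seed=17)
        ts, _ = simulate_experiment(cfg)
        return compute_steps(ts)

    def test_date_dropped_and_logged(self, caplog):
        steps = self._aliased_sim()
        with caplog.at_level("INFO", logger="tracknest.stats"):
            fit = fit_model(steps, ModelSpec(
                random_chain=("date", "mouse", "lymph_node", "field", "cell")))
        assert fit.dropped_random == ["date"]
        assert "date" not in fit.variance_components
        assert any("aliased" in rec.message for rec in caplog.records)

    def test_estimates_match_fit_without_date(self):
        steps = self._aliased_sim()
        full = fit_model(steps, ModelSpec(
            random_chain=("date", "mouse", "lymph_node", "field", "cell")))
        manual = fit_model(steps, ModelSpec(
            random_chain=("mouse", "lymph_node", "field", "cell")))
        for pop in full.population_estimates:
            assert full.population_estimates[pop] == pytest.approx(
                manual.population_estimates[pop], abs=1e-8)
        assert full.p_population == pytest.approx(manual.p_population, abs=1e-8)
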