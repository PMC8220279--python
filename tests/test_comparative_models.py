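"""Regression machinery, influence diagnostics and phylogenetic models vs oracles."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eggsig import (
    ScenarioConfig,
    build_design,
    classify_parasitism,
    cooks_distance,
    estimate_lambda,
    fit_interaction_model,
    fit_ols,
    fit_pgls,
    generate_scenario_table,
    generate_tree,
    lambda_over_trees,
    phylo_covariance,
    rank_transform,
    run_full_battery,
    simulate_trait_with_lambda,
)
from tests.conftest import make_eggs


def star_tree(n=8, length=1.0):
    newick = "(" + ",".join(f"t{i}:{length}" for i in range(n)) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


class TestClassifyParasitism:
    def _eggs(self, n_par, n_unpar, elsewhere=False, species="spX"):
        eggs = make_eggs([2] * (n_par + n_unpar), species=species)
        clutches = list(dict.fromkeys(eggs["clutch_id"]))
        eggs["parasitized"] = eggs["clutch_id"].isin(clutches[:n_par])
        eggs["parasitized_elsewhere"] = elsewhere
        return eggs

    @pytest.mark.parametrize("rate", [0.0217, 0.10, 0.427])
    def test_any_nonzero_rate_is_parasitized(self, rate):
        n = 46  # enough clutches to realize small observed rates exactly
        n_par = max(1, round(rate * n))
        status = classify_parasitism(self._eggs(n_par, n - n_par))
        assert status.loc[0, "status_local"] == "parasitized"
        assert status.loc[0, "parasitism_rate_local"] == pytest.approx(n_par / n)

    def test_zero_rate_no_elsewhere(self):
        status = classify_parasitism(self._eggs(0, 20))
        assert status.loc[0, "status_local"] == "unparasitized"
        assert status.loc[0, "status_restrictive"] == "unparasitized"

    def test_elsewhere_records_promote_restrictive_only(self):
        status = classify_parasitism(self._eggs(0, 20, elsewhere=True))
        assert status.loc[0, "status_local"] == "unparasitized"
        assert status.loc[0, "status_restrictive"] == "parasitized"


class TestOls:
    def _problem(self, rng, n=50, p=4, noise=1.0):
        X = pd.DataFrame(
            rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)]
        )
        X.insert(0, "Intercept", 1.0)
        beta = rng.standard_normal(p + 1)
        y = X.to_numpy() @ beta + noise * rng.standard_normal(n)
        return y, X, beta

    def test_exact_linear_response_recovered(self, rng):
        y, X, beta = self._problem(rng, noise=0.0)
        fit = fit_ols(y, X)
        assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        y, X, _ = self._problem(rng)
        fit = fit_ols(y, X)
        x = X.to_numpy()
        oracle = np.linalg.pinv(x.T @ x) @ x.T @ y
        assert fit.params.to_numpy() == pytest.approx(oracle, abs=1e-10)
        # SE oracle
        r = y - x @ oracle
        s2 = r @ r / (len(y) - x.shape[1])
        se = np.sqrt(np.diag(s2 * np.linalg.pinv(x.T @ x)))
        assert fit.bse.to_numpy() == pytest.approx(se, abs=1e-10)
        assert fit.tvalues.to_numpy() == pytest.approx(
            fit.params.to_numpy() / fit.bse.to_numpy(), abs=1e-10
        )

    def test_duplicated_rows_with_half_weights_equal_unweighted(self, rng):
        y, X, _ = self._problem(rng, n=30)
        fit_plain = fit_ols(y, X)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        fit_dup = fit_ols(y2, X2, weights=np.full(60, 0.5))
        assert fit_dup.params.to_numpy() == pytest.approx(fit_plain.params.to_numpy(), abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        y, X, _ = self._problem(rng)
        X["x_dup"] = X["x0"]
        with pytest.raises(ValueError, match="x_dup|x0"):
            fit_ols(y, X)

    def test_df_bookkeeping_matches_study_shapes(self, rng):
        # 25 species, 3 predictors + intercept -> t with 21 df; 22 species
        # (after immaculate exclusions) -> 18 df
        for n, expected_df in [(25, 21), (22, 18)]:
            y, X, _ = self._problem(rng, n=n, p=3)
            assert fit_ols(y, X).df_resid == expected_df


class TestInteractionModel:
    def test_interaction_equals_group_slope_difference(self):
        table = generate_scenario_table(ScenarioConfig(seed=5))
        res = fit_interaction_model(
            table, "combinatorial_distinctiveness", covariates=[]
        )
        inter = res["interaction"].params["combinatorial_distinctiveness:status[parasitized]"]
        slope_par = res["groups"]["parasitized"].params["combinatorial_distinctiveness"]
        slope_unpar = res["groups"]["unparasitized"].params["combinatorial_distinctiveness"]
        assert inter == pytest.approx(slope_par - slope_unpar, abs=1e-10)

    def test_equal_slopes_give_small_interaction_t(self):
        tvals = []
        for seed in range(40):
            cfg = ScenarioConfig(seed=seed, slope_parasitized=-0.1, slope_unparasitized=-0.1)
            res = fit_interaction_model(generate_scenario_table(cfg), "combinatorial_distinctiveness")
            tvals.append(
                res["interaction"].tvalues["combinatorial_distinctiveness:status[parasitized]"]
            )
        assert abs(np.mean(tvals)) < 0.5
        assert np.mean(np.abs(np.array(tvals)) > 2.12) < 0.2  # ~5% nominal

    def test_single_group_rejected(self):
        table = generate_scenario_table(ScenarioConfig(seed=1, parasitized_fraction=1.0))
        with pytest.raises(ValueError, match="both parasitism groups"):
            fit_interaction_model(table, "combinatorial_distinctiveness")


class TestCooksDistance:
    def _fit(self, rng, n=50, outlier=None):
        X = pd.DataFrame({"Intercept": np.ones(n), "x": rng.standard_normal(n)})
        y = 1.0 + 2.0 * X["x"].to_numpy() + 0.3 * rng.standard_normal(n)
        if outlier is not None:
            y[outlier] += 10.0
        return fit_ols(y, X)

    def test_gross_outlier_flagged_with_max_d(self, rng):
        fit = self._fit(rng, outlier=17)
        d = cooks_distance(fit)
        assert d["cooks_d"].idxmax() == 17
        assert d.loc[17, "flagged"]

    def test_matches_leave_one_out_refit_oracle(self, rng):
        fit = self._fit(rng, n=50)
        d = cooks_distance(fit)["cooks_d"].to_numpy()
        x = fit.design.to_numpy()
        y = fit.response
        n, p = x.shape
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        s2 = float((y - x @ beta) @ (y - x @ beta)) / (n - p)
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.solve(x[keep].T @ x[keep], x[keep].T @ y[keep])
            shift = beta - beta_i
            oracle = float(shift @ (x.T @ x) @ shift) / (p * s2)
            assert d[i] == pytest.approx(oracle, abs=1e-10)

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm

        fit = self._fit(rng)
        ours = cooks_distance(fit)["cooks_d"].to_numpy()
        res = sm.OLS(fit.response, fit.design).fit()
        theirs = res.get_influence().cooks_distance[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_perfect_fit_gives_zero(self):
        X = pd.DataFrame({"Intercept": np.ones(10), "x": np.arange(10.0)})
        y = 3.0 + 0.5 * np.arange(10.0)
        d = cooks_distance(fit_ols(y, X))
        assert np.allclose(d["cooks_d"], 0.0, atol=1e-10)


class TestRankTransform:
    def test_sorted_distinct_values(self):
        assert np.array_equal(rank_transform([10.0, 20.0, 30.0]), [1, 2, 3])

    def test_ties_get_average_ranks(self):
        assert np.array_equal(rank_transform([1.0, 5.0, 5.0, 9.0]), [1, 2.5, 2.5, 4])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-1000, max_value=1000), min_size=2, max_size=30, unique=True))
    def test_invariant_under_monotone_transforms(self, values):
        v = np.asarray(values, dtype=float) / 20.0  # well-separated values
        base = rank_transform(v)
        assert np.array_equal(base, rank_transform(np.exp(v / 25.0)))
        assert np.array_equal(base, rank_transform(np.arctan(v) * 3 + 7))


class TestPhyloCovariance:
    def test_lambda_zero_is_diagonal(self, yule_tree_30):
        _, vcv = phylo_covariance(yule_tree_30, 0.0)
        assert np.allclose(vcv - np.diag(np.diag(vcv)), 0.0)

    def test_cherry_closed_form(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):2,c:3);", schema="newick")
        labels, vcv = phylo_covariance(tree, 1.0)
        i, j = labels.index("a"), labels.index("b")
        assert vcv[i, j] == pytest.approx(2.0)  # shared stem
        assert vcv[i, i] == pytest.approx(3.0)
        k = labels.index("c")
        assert vcv[i, k] == 0.0

    def test_matches_dendropy_patristic_oracle(self, yule_tree_30):
        labels, vcv = phylo_covariance(yule_tree_30, 1.0)
        pdm = yule_tree_30.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in yule_tree_30.taxon_namespace}
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in yule_tree_30.leaf_node_iter()
        }
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i == j:
                    expected = depths[a]
                else:
                    patristic = pdm.patristic_distance(taxa[a], taxa[b])
                    expected = (depths[a] + depths[b] - patristic) / 2.0
                assert vcv[i, j] == pytest.approx(expected, abs=1e-9)

    def test_lambda_bounds(self, yule_tree_30):
        with pytest.raises(ValueError):
            phylo_covariance(yule_tree_30, 1.2)


class TestEstimateLambda:
    def test_star_tree_is_unidentifiable(self):
        tree = star_tree(8)
        trait = pd.Series(
            np.random.default_rng(0).standard_normal(8), index=[f"t{i}" for i in range(8)]
        )
        fit = estimate_lambda(trait, tree)
        assert fit.unidentifiable
        assert fit.p_value == 1.0

    def test_high_signal_trait_recovers_high_lambda(self, yule_tree_30):
        lams = [
            estimate_lambda(simulate_trait_with_lambda(yule_tree_30, 1.0, seed=s), yule_tree_30).lam
            for s in range(10)
        ]
        assert np.median(lams) > 0.7

    def test_missing_tip_named_in_error(self, yule_tree_30):
        trait = pd.Series([1.0, 2.0, 3.0, 4.0], index=["t0", "t1", "t2", "absent_sp"])
        with pytest.raises(ValueError, match="absent_sp"):
            estimate_lambda(trait, yule_tree_30)


class TestPgls:
    def _data(self, tree, seed=0, p=2):
        rng = np.random.default_rng(seed)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        n = len(labels)
        X = pd.DataFrame(
            np.column_stack([np.ones(n), rng.standard_normal((n, p))]),
            columns=["Intercept"] + [f"x{i}" for i in range(p)],
            index=labels,
        )
        y = pd.Series(X.to_numpy() @ rng.standard_normal(p + 1) + rng.standard_normal(n), index=labels)
        return y, X

    def test_lambda_zero_reduces_to_ols(self, yule_tree_30):
        y, X = self._data(yule_tree_30)
        pgls = fit_pgls(y, X, yule_tree_30, lam=0.0)
        # tips have equal depth on an ultrametric tree, so lam=0 is iid error
        ols = fit_ols(y.loc[X.index], X)
        assert pgls.params.to_numpy() == pytest.approx(ols.params.to_numpy(), abs=1e-8)

    def test_star_tree_lambda_one_equals_ols(self):
        tree = star_tree(20)
        y, X = self._data(tree, seed=3)
        pgls = fit_pgls(y, X, tree, lam=1.0)
        ols = fit_ols(y.loc[X.index], X)
        assert pgls.params.to_numpy() == pytest.approx(ols.params.to_numpy(), abs=1e-8)

    def test_matches_whitening_oracle(self, yule_tree_30):
        y, X = self._data(yule_tree_30, seed=11)
        for lam in (0.3, 1.0):
            pgls = fit_pgls(y, X, yule_tree_30, lam=lam)
            labels, vcv = phylo_covariance(yule_tree_30, lam)
            order = pgls.design.index.tolist()
            idx = [labels.index(t) for t in order]
            V = vcv[np.ix_(idx, idx)]
            L = np.linalg.cholesky(V)
            xw = np.linalg.solve(L, pgls.design.to_numpy())
            yw = np.linalg.solve(L, y.loc[order].to_numpy())
            oracle, *_ = np.linalg.lstsq(xw, yw, rcond=None)
            assert pgls.params.to_numpy() == pytest.approx(oracle, abs=1e-8)


class TestLambdaOverTrees:
    def test_identical_trees_have_zero_sd(self, yule_tree_30):
        trait = simulate_trait_with_lambda(yule_tree_30, 1.0, seed=0)
        summary = lambda_over_trees(trait, [yule_tree_30] * 4)
        assert summary.lam_sd == 0.0
        assert summary.n_failed == 0

    def test_summary_mean_matches_loop_oracle(self):
        labels = [f"t{i}" for i in range(20)]
        trees = [generate_tree(20, seed=s, taxon_labels=labels) for s in range(5)]
        trait = simulate_trait_with_lambda(trees[0], 1.0, seed=1)
        summary = lambda_over_trees(trait, trees)
        per_tree = [estimate_lambda(trait, t).lam for t in trees]
        assert summary.lam_mean == pytest.approx(np.mean(per_tree), abs=1e-12)
        assert summary.p_min <= summary.p_max


class TestBattery:
    def test_strategy_blocking_recovered_end_to_end(self):
        table = generate_scenario_table(ScenarioConfig(seed=2))
        statuses = table[["species", "status_local", "status_restrictive"]].copy()
        sig = table.drop(columns=["status_local", "status_restrictive"])
        sig["entropy"] = sig["absolute_distinctiveness"] + sig["combinatorial_distinctiveness"]
        sig["mdps_distinctiveness"] = 1.0
        results = run_full_battery(sig, statuses, variants=["baseline"])
        par = results[
            (results.model_id == "consistency~combinatorial_distinctiveness+group[parasitized]")
            & (results.term == "combinatorial_distinctiveness")
        ]
        unpar = results[
            (results.model_id == "consistency~combinatorial_distinctiveness+group[unparasitized]")
            & (results.term == "combinatorial_distinctiveness")
        ]
        assert par.estimate.iloc[0] < -0.05
        assert abs(unpar.estimate.iloc[0]) < 0.15
        inter = results[
            (results.model_id == "consistency~combinatorial_distinctiveness+interaction")
            & (results.term == "combinatorial_distinctiveness:status[parasitized]")
        ]
        assert inter.estimate.iloc[0] < 0

    def test_battery_is_deterministic(self, small_dataset):
        from eggsig import species_signatures

        sig = species_signatures(small_dataset.eggs, seed=3)
        statuses = classify_parasitism(small_dataset.eggs)
        a = run_full_battery(sig, statuses, eggs=small_dataset.eggs, seed=9,
                             variants=["baseline", "rank", "resampled"])
        b = run_full_battery(sig, statuses, eggs=small_dataset.eggs, seed=9,
                             variants=["baseline", "rank", "resampled"])
        pd.testing.assert_frame_equal(a, b)

    def test_failures_are_recorded_not_fatal(self):
        table = generate_scenario_table(ScenarioConfig(seed=4))
        statuses = table[["species", "status_local", "status_restrictive"]]
        sig = table.drop(columns=["status_local", "status_restrictive"])
        sig["entropy"] = np.nan
        sig["mdps_distinctiveness"] = np.nan
        results = run_full_battery(sig, statuses, variants=["baseline", "pgls"])
        pgls_rows = results[results.variant == "pgls"]
        assert (pgls_rows.note != "").any()  # no trees supplied -> recorded
        assert (results[results.variant == "baseline"].note == "").any()
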