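"""Analysis pipeline: cleaning, transforms, regression, ANOVA, costs."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from statsmodels.stats.anova import AnovaRM

from conftest import make_trial
from rsk import analysis as ana
from rsk import design as dsg


def _log(rows):
    return pd.DataFrame(rows)


class TestCleaning:
    @pytest.fixture()
    def raw(self):
        return _log(
            [
                make_trial(trial_index=1, rt_ms=150.0, response="right", correct=True),
                make_trial(trial_index=0, rt_ms=600.0, response="right", correct=True),
                make_trial(trial_index=2, rt_ms=600.0, response="left", correct=False),
                make_trial(trial_index=3, rt_ms=700.0, response="right", correct=True),
                make_trial(trial_index=4, rt_ms=np.nan, response=pd.NA, correct=pd.NA),
            ]
        )

    def test_exclusion_rules(self, raw):
        rt_log, acc_log, report = ana.clean_trials(raw)
        # anticipations and block-first trials are gone from both sets
        assert 1 not in rt_log["trial_index"].values
        assert 0 not in acc_log["trial_index"].values
        # the error trial stays in the accuracy set but not the RT set
        assert 2 in acc_log["trial_index"].values
        assert 2 not in rt_log["trial_index"].values
        # the timeout becomes an error
        timeout_row = acc_log[acc_log["trial_index"] == 4]
        assert not bool(timeout_row["correct"].iloc[0])
        assert report == {
            "n_input": 5,
            "n_fast": 1,
            "n_block_first": 1,
            "n_timeout": 1,
            "n_error_excluded_from_rt": 1,
            "n_accuracy": 3,
            "n_rt": 1,
        }

    def test_order_invariant(self, raw):
        rt_a, acc_a, _ = ana.clean_trials(raw)
        shuffled = raw.sample(frac=1.0, random_state=3)
        rt_b, acc_b, _ = ana.clean_trials(shuffled)
        assert sorted(rt_a["trial_index"]) == sorted(rt_b["trial_index"])
        assert sorted(acc_a["trial_index"]) == sorted(acc_b["trial_index"])

    def test_missing_columns_named(self):
        with pytest.raises(ana.SchemaError, match="rt_ms"):
            ana.clean_trials(pd.DataFrame({"task": ["motion"]}))


class TestTransforms:
    def test_arcsine_known_values(self):
        assert ana.transform_acc(1.0) == pytest.approx(np.pi / 2)
        assert ana.transform_acc(0.5) == pytest.approx(np.pi / 4)
        with pytest.raises(ValueError):
            ana.transform_acc(1.5)

    @pytest.mark.parametrize("rt", [250.0, 640.0, 2000.0])
    def test_rt_transform_inverse(self, rt):
        assert ana.back_transform_rt(ana.transform_rt(rt)) == pytest.approx(rt)

    @pytest.mark.parametrize("p", [0.0, 0.25, 0.97, 1.0])
    def test_acc_transform_inverse(self, p):
        assert ana.back_transform_acc(ana.transform_acc(p)) == pytest.approx(p)

    def test_back_transformed_mean_log_rt_is_geometric_mean(self):
        rng = np.random.default_rng(0)
        rts = rng.uniform(250, 1500, size=200)
        ours = ana.back_transform_rt(np.mean(ana.transform_rt(rts)))
        assert ours == pytest.approx(st.gmean(rts), rel=1e-9)


def _regression_log(n_participants, betas, noise_sd, seed):
    """Synthetic bivalent log with a known linear structure in log RT."""
    rng = np.random.default_rng(seed)
    grid = dsg._exp2_stimulus_grid(rng)
    rows = []
    for pid in range(n_participants):
        for _, s in grid.iterrows():
            t = make_trial(
                participant_id=pid,
                task=dsg.COLOR,
                motion_coherence=s["motion_coherence"],
                direction=s["direction"],
                color_coherence=s["color_coherence"],
                majority_color=s["majority_color"],
                correct_response="right",
                response="right",
                correct=True,
            )
            rows.append(t)
    log = pd.DataFrame(rows)
    target = 100.0 * log["color_coherence"]
    dist = np.array(
        [dsg.signed_distractor_congruence(r) for _, r in log.iterrows()]
    )
    z = lambda x: (x - np.mean(x)) / np.std(x, ddof=1)
    y = betas[0] * z(target) + betas[1] * z(dist) + noise_sd * rng.standard_normal(len(log))
    log["rt_ms"] = np.exp(6.0 + 0.1 * y)
    return log


class TestRegression:
    def test_recovers_known_slope(self):
        log = _regression_log(40, betas=(-0.5, 0.0), noise_sd=1.0, seed=1)
        res = ana.regress_target_distractor(log, dsg.COLOR, "rt")
        assert res.coefficients.loc["target_coherence", "beta"] == pytest.approx(
            -0.5 / np.sqrt(0.25 + 1.0), abs=0.03
        )
        assert abs(res.coefficients.loc["distractor_congruence", "beta"]) < 0.03

    def test_matches_normal_equations(self):
        """OLS output equals an explicit normal-equations solve, many instances."""
        for seed in range(30):
            log = _regression_log(
                4, betas=(0.3 * np.cos(seed), 0.2 * np.sin(seed)),
                noise_sd=0.5 + 0.1 * (seed % 5), seed=seed,
            )
            res = ana.regress_target_distractor(log, dsg.COLOR, "rt")
            X, y = res.design, res.outcome_values
            brute = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(res.params, brute, atol=1e-10)
            # reported betas are the non-constant coefficients
            np.testing.assert_allclose(
                res.coefficients["beta"].to_numpy(), brute[1:], atol=1e-10
            )

    def test_pure_noise_adjusted_r2_near_zero(self):
        log = _regression_log(100, betas=(0.0, 0.0), noise_sd=1.0, seed=5)
        res = ana.regress_target_distractor(log, dsg.COLOR, "rt")
        assert res.nobs == 10_000
        assert abs(res.adj_r_squared) < 0.01
        assert res.adj_r_squared <= res.r_squared


class TestRmAnova:
    def _random_tidy(self, seed, n=12, factors=(("fa", 2), ("fb", 3))):
        rng = np.random.default_rng(seed)
        import itertools

        rows = []
        levels = [[f"{name}{i}" for i in range(k)] for name, k in factors]
        for s in range(n):
            for combo in itertools.product(*levels):
                row = {"participant_id": s, "y": rng.normal()}
                row.update({f[0]: c for f, c in zip(factors, combo)})
                rows.append(row)
        return pd.DataFrame(rows)

    def test_two_level_factor_equals_paired_t(self):
        df = self._random_tidy(0, factors=(("fa", 2),))
        res = ana.rm_anova(df, "y", ["fa"])["fa"]
        wide = df.pivot(index="participant_id", columns="fa", values="y")
        t, p = st.ttest_rel(wide["fa0"], wide["fa1"])
        assert res.F == pytest.approx(t**2, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert (res.df1, res.df2) == (1, 11)

    def test_matches_statsmodels_three_way(self):
        df = self._random_tidy(1, factors=(("fa", 2), ("fb", 3), ("fc", 2)))
        mine = ana.rm_anova(df, "y", ["fa", "fb", "fc"])
        ref = AnovaRM(df, "y", "participant_id", within=["fa", "fb", "fc"]).fit()
        for effect in ref.anova_table.index:
            m = mine[effect]
            r = ref.anova_table.loc[effect]
            assert m.F == pytest.approx(r["F Value"], abs=1e-8)
            assert (m.df1, m.df2) == (r["Num DF"], r["Den DF"])
            assert m.p == pytest.approx(r["Pr > F"], abs=1e-10)

    def test_zero_between_condition_variance(self):
        df = self._random_tidy(2, factors=(("fa", 3),))
        df["y"] = df.groupby("participant_id")["y"].transform("mean")
        res = ana.rm_anova(df, "y", ["fa"])["fa"]
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.eta_p_sq == pytest.approx(0.0, abs=1e-20)

    def test_epsilon_bounds(self):
        for seed in range(100):
            df = self._random_tidy(seed, n=8, factors=(("fa", 4),))
            eps = ana.rm_anova(df, "y", ["fa"])["fa"].epsilon
            assert 1.0 / 3.0 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_missing_cell_rejected(self):
        df = self._random_tidy(3).iloc[1:]
        with pytest.raises(ValueError, match="unbalanced"):
            ana.rm_anova(df, "y", ["fa", "fb"])

    def test_type_I_error_calibrated(self):
        """Exchangeable data: the 2x3 interaction rejects at ~alpha."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            Y = rng.standard_normal((10, 6))
            res = ana._rm_anova_wide(Y, [("fa", 2), ("fb", 3)])
            hits += res["fa:fb"].p < 0.05
        assert abs(hits / n_rep - 0.05) < 0.02


class TestChanceTest:
    def test_all_at_chance(self):
        res = ana.chance_level_test([0.5, 0.5, 0.5, 0.5])
        assert (res.t, res.p, res.d) == (0.0, 0.5, 0.0)
        assert res.degenerate

    def test_zero_variance_flagged(self):
        res = ana.chance_level_test([0.6, 0.6, 0.6, 0.6])
        assert res.degenerate
        assert res.p == 0.0

    def test_one_tailed_against_chance(self):
        rng = np.random.default_rng(1)
        accs = 0.7 + 0.05 * rng.standard_normal(30)
        res = ana.chance_level_test(accs)
        t, p = st.ttest_1samp(accs, 0.5, alternative="greater")
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.d == pytest.approx((accs.mean() - 0.5) / accs.std(ddof=1))


def _cost_log(seed, n_participants=6, single=500.0, repeat=600.0, switch=640.0,
              jitter=0.0):
    """Deterministic (or jittered) exp3-like log with fixed cell RTs."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_participants):
        for b, seq in enumerate(["single"] * 2 + ["mixed"] * 2):
            for i in range(30):
                if seq == "single":
                    s_type = "single"
                else:
                    s_type = "repeat" if i % 2 == 0 else "switch"
                base = {"single": single, "repeat": repeat, "switch": switch}[s_type]
                rows.append(
                    make_trial(
                        participant_id=pid,
                        block_index=b,
                        trial_index=i,
                        csi_ms=200.0 if b % 2 == 0 else 800.0,
                        sequence_type=s_type,
                        congruent=(i % 4 < 2),
                        rt_ms=base + jitter * rng.standard_normal(),
                        response="right",
                        correct=True,
                    )
                )
    return pd.DataFrame(rows)


class TestCosts:
    def test_constructed_shifts_recovered_exactly(self):
        log = _cost_log(0)
        costs = ana.compute_costs(log)
        cells = costs.per_cell
        assert cells["rt_mixing_cost_ms"].to_numpy() == pytest.approx(100.0, abs=1e-9)
        assert cells["switch_cost_ms"].to_numpy() == pytest.approx(40.0, abs=1e-9)

    def test_identical_distributions_give_null_cost(self):
        log = _cost_log(1, single=600.0, repeat=600.0, switch=600.0, jitter=40.0)
        costs = ana.compute_costs(log)
        by_part = costs.per_participant_by_csi().groupby("participant_id")[
            "switch_cost_ms"
        ].mean()
        sem = by_part.std(ddof=1) / np.sqrt(len(by_part))
        assert abs(by_part.mean()) < 2.0 * sem + 1e-9

    def test_empty_cell_flagged(self):
        log = _cost_log(2)
        log = log[~((log["sequence_type"] == "switch") & (log["csi_ms"] == 800.0))]
        costs = ana.compute_costs(log)
        assert costs.missing_cells
        long_cells = costs.per_cell[costs.per_cell["csi_ms"] == 800.0]
        assert long_cells["switch_cost_ms"].isna().all()


class TestAsymmetry:
    def test_previous_congruency_bookkeeping(self, exp3_plan):
        t = dsg.attach_previous_congruency(exp3_plan.trials)
        for _, block in t.groupby("block_index"):
            expected = block["congruent"].shift(1)
            got = block["congruency_n_minus_1"]
            assert got.iloc[0] is pd.NA or pd.isna(got.iloc[0])
            pd.testing.assert_series_equal(
                got.iloc[1:].astype("boolean"),
                expected.iloc[1:].astype("boolean"),
                check_names=False,
            )

    def test_asymmetry_cells_and_anova(self, exp3_log_small):
        res = ana.asymmetry_analysis(exp3_log_small)
        assert set(res.costs["switch_direction"]) == {"to_motion", "to_color"}
        means = res.costs.groupby(["switch_direction", "prev_congruent"])[
            "switch_cost_ms"
        ].mean()
        # the inertia penalty loads only on to-motion after incongruent trials
        asym_motion = means["to_motion"][False] - means["to_motion"][True]
        asym_color = means["to_color"][False] - means["to_color"][True]
        assert asym_motion > asym_color
        assert res.rt_anova["switch_direction:prev_congruent"].p_gg < 0.05


def test_cost_significance_summary_shape(exp3_log_small):
    costs = ana.compute_costs(exp3_log_small)
    summary = ana.cost_significance_summary(costs)
    assert list(summary["cost"]) == list(ana.CostTable.COST_COLUMNS)
    assert {"p_short", "p_long", "p_preparatory_reduction"} <= set(summary.columns)


def test_bonferroni_pairwise_family_size():
    rng = np.random.default_rng(0)
    rows = [
        {"participant_id": s, "level": lv, "y": rng.normal() + d}
        for s in range(10)
        for lv, d in (("a", 0.0), ("b", 0.5), ("c", 1.0))
    ]
    table = ana.bonferroni_pairwise(pd.DataFrame(rows), "y", "level")
    assert len(table) == 3
    assert (table["p_bonferroni"] >= table["p"]).all()
    assert (table["p_bonferroni"] <= 1.0).all()
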