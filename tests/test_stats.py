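"""Repeated-measures ANOVA, contrasts, predictor coding and mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import helmert

import scrollclick as sc
from scrollclick.stats import (
    _gg_epsilon,
    build_hysteresis_predictors,
    consecutive_contrasts,
    fit_mixed_model,
    rm_anova_cube,
    rm_anova_gg,
)

from _oracles import (
    oracle_epsilon,
    oracle_two_way_rm_anova,
    paired_t,
    random_orthonormal_contrast,
)


def _long(Y, factors):
    n = Y.shape[0]
    rows = []
    for idx in np.ndindex(Y.shape):
        row = {"participant": idx[0], "y": Y[idx]}
        for f, j in zip(factors, idx[1:]):
            row[f] = f"l{j}"
        rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self):
        """F, SS and generalized eta squared agree with the definitional
        loop-based decomposition to 1e-8 on random balanced tables."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(4, 9)
            a = rng.integers(2, 5)
            b = rng.integers(2, 5)
            Y = (rng.normal(size=(n, a, b))
                 + rng.normal(size=(n, 1, 1)))  # participant heterogeneity
            mine = {e.effect: e for e in rm_anova_cube(Y, ["A", "B"])}
            oracle = oracle_two_way_rm_anova(Y)
            for name in ("A", "B", "A:B"):
                F, ss_e, ss_err, eta_g = oracle[name]
                assert mine[name].F == pytest.approx(F, abs=1e-8)
                assert mine[name].ss_effect == pytest.approx(ss_e, abs=1e-8)
                assert mine[name].ss_error == pytest.approx(ss_err, abs=1e-8)
                assert mine[name].eta_g == pytest.approx(eta_g, abs=1e-8)

    def test_matches_pingouin_two_way(self):
        """Cross-check against an independent implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(8, 3, 4)) + rng.normal(size=(8, 1, 1))
        df = _long(Y, ["A", "B"])
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"],
                          subject="participant", detailed=True)
        mine = {e.effect: e for e in rm_anova_cube(Y, ["A", "B"])}
        for src, name in (("A", "A"), ("B", "B"), ("A * B", "A:B")):
            row = ref[ref.Source == src].iloc[0]
            assert mine[name].F == pytest.approx(row["F"], rel=1e-9)
            assert mine[name].eta_g == pytest.approx(row["ng2"], rel=1e-9)
        # main-effect GG epsilons (pingouin's interaction epsilon uses a
        # different, self-flagged approximation)
        for src, name in (("A", "A"), ("B", "B")):
            row = ref[ref.Source == src].iloc[0]
            assert mine[name].epsilon == pytest.approx(row["eps"], rel=1e-9)
            assert mine[name].p == pytest.approx(row["p_GG_corr"], rel=1e-9)

    def test_epsilon_basis_invariance(self):
        """Epsilon from Helmert contrasts equals epsilon from a random
        orthonormal basis (including for the interaction)."""
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(10, 3, 4))
        for axes, k in (((1,), 3), ((2,), 4), (((1, 2)), 12)):
            eps = _gg_epsilon(Y, axes if isinstance(axes, tuple) else (axes,))
            if axes == (1,):
                cells = Y.mean(axis=2)
            elif axes == (2,):
                cells = Y.mean(axis=1)
            else:
                cells = Y.reshape(10, -1)
            if axes == (1, 2):
                C = np.kron(random_orthonormal_contrast(3, rng),
                            random_orthonormal_contrast(4, rng))
            else:
                C = random_orthonormal_contrast(cells.shape[1], rng)
            assert eps == pytest.approx(oracle_epsilon(cells, C), abs=1e-9)

    def test_two_level_factor_has_epsilon_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(6, 2, 3))
        effects = {e.effect: e for e in rm_anova_cube(Y, ["A", "B"])}
        assert effects["A"].epsilon == 1.0

    def test_constant_effect_gives_zero_F(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 1, 3))
        Y = np.repeat(base, 4, axis=1)  # no A effect within participants
        effects = {e.effect: e for e in rm_anova_cube(Y, ["A", "B"])}
        assert effects["A"].F == pytest.approx(0.0, abs=1e-18)

    def test_epsilon_bounds_on_random_tables(self):
        """1/(k-1) <= eps <= 1 over a large sample of random tables."""
        rng = np.random.default_rng(99)
        for _ in range(10_000):
            n = int(rng.integers(3, 8))
            k = int(rng.integers(3, 6))
            Y = rng.normal(size=(n, k))
            eps = _gg_epsilon(Y[:, :, None].reshape(n, k), (1,))
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_missing_cells_rejected_with_listing(self):
        rng = np.random.default_rng(5)
        df = _long(rng.normal(size=(4, 2, 2)), ["A", "B"])
        df = df[~((df.participant == 2) & (df.A == "l1") & (df.B == "l0"))]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gg(df, ["A", "B"], dv="y")

    def test_single_participant_rejected(self):
        df = _long(np.zeros((1, 2, 2)), ["A", "B"])
        with pytest.raises(ValueError, match="participant"):
            rm_anova_gg(df, ["A", "B"], dv="y")

    def test_three_way_decomposition_sums_to_total(self):
        """Full decomposition: all effect + subject SS add to total SS."""
        from scrollclick.stats import _effect_decomposition
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(5, 2, 3, 3))
        ss = _effect_decomposition(Y)
        total = float(((Y - Y.mean()) ** 2).sum())
        assert sum(ss.values()) == pytest.approx(total, rel=1e-10)


class TestConsecutiveContrasts:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(5, 3))
        df = _long(Y[:, :, None].reshape(5, 3, 1), ["A", "B"])
        res = consecutive_contrasts(df, "A", dv="y")
        assert len(res) == 2
        for r, (i, j) in zip(res, ((0, 1), (1, 2))):
            t, dof = paired_t(Y[:, i], Y[:, j])
            assert r.t == pytest.approx(t)
            assert r.df == dof
            assert r.d_z == pytest.approx(t / np.sqrt(5))

    def test_identical_levels_give_zero(self):
        Y = np.tile(np.arange(5.0)[:, None], (1, 3))
        df = _long(Y[:, :, None].reshape(5, 3, 1), ["A", "B"])
        res = consecutive_contrasts(df, "A", dv="y")
        assert all(r.t == 0.0 and r.d_z == 0.0 for r in res)

    def test_constant_difference_flagged_degenerate(self):
        Y = np.column_stack([np.arange(5.0), np.arange(5.0) + 1.0])
        df = _long(Y[:, :, None].reshape(5, 2, 1), ["A", "B"])
        res = consecutive_contrasts(df, "A", dv="y")
        assert res[0].degenerate

    def test_fewer_than_two_levels_rejected(self):
        df = _long(np.zeros((3, 1, 1)), ["A", "B"])
        with pytest.raises(ValueError):
            consecutive_contrasts(df, "A", dv="y")


class TestHysteresisPredictors:
    def _table(self, prev_y, d_current, sv=0.0):
        rows = [
            {"participant": 0, "block": 0, "trial_index": 0,
             "displacement": -0.4, "initial_click_y": prev_y,
             "trial_duration": 2.0, "start_vertical": 0.0},
            {"participant": 0, "block": 0, "trial_index": 1,
             "displacement": d_current, "initial_click_y": 0.6,
             "trial_duration": 2.0, "start_vertical": sv},
        ]
        return pd.DataFrame(rows)

    def test_worked_coding_examples(self):
        # previous click at the top of the screen
        t = build_hysteresis_predictors(self._table(1.0, -0.4), "exp1")
        assert t["prev_ecc_signed"].iloc[0] == pytest.approx(0.25)
        t = build_hysteresis_predictors(self._table(1.0, 0.4), "exp1")
        assert t["prev_ecc_signed"].iloc[0] == pytest.approx(-0.25)
        # previous click at the screen center, current downward
        t = build_hysteresis_predictors(self._table(0.5, -0.4), "exp1")
        assert t["prev_ecc_signed"].iloc[0] == pytest.approx(-0.25)

    def test_direction_and_start_coding(self):
        t = build_hysteresis_predictors(self._table(0.8, 0.6, sv=-0.4), "exp1")
        assert t["direction"].iloc[0] == 0.5
        assert t["start_position"].iloc[0] == -0.4
        t = build_hysteresis_predictors(self._table(0.8, -0.6), "exp1")
        assert t["direction"].iloc[0] == -0.5

    def test_first_trial_of_block_dropped(self, exp1_small_frame):
        t = build_hysteresis_predictors(exp1_small_frame, "exp1")
        n_blocks = exp1_small_frame.groupby(["participant", "block"]).ngroups
        assert len(t) == len(exp1_small_frame) - n_blocks

    def test_slow_trials_and_successors_dropped(self):
        df = self._table(1.0, -0.4)
        extra = df.iloc[[1]].assign(trial_index=2, displacement=0.4)
        df = pd.concat([df, extra], ignore_index=True)
        df.loc[1, "trial_duration"] = 11.0  # middle trial too slow
        t = build_hysteresis_predictors(df, "exp1")
        assert len(t) == 0  # trial 1 slow, trial 2's predecessor slow

    def test_unordered_input_rejected(self):
        df = self._table(1.0, -0.4).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="ordered"):
            build_hysteresis_predictors(df, "exp1")

    def test_exp2_inducer_coding(self):
        rows = []
        for i, (cond, _) in enumerate([("low", 1), ("low", 2)]):
            rows.append({"participant": 0, "block": 0, "subblock": 0,
                         "trial_index": i, "displacement": -0.28,
                         "initial_click_y": 0.7, "trial_duration": 2.0,
                         "eccentricity_condition": cond})
        t = build_hysteresis_predictors(pd.DataFrame(rows), "exp2")
        assert t["inducer_eccentricity"].iloc[0] == pytest.approx(0.14)


class TestMixedModel:
    def _simulate_linear(self, rng, n_p=10, n_t=40, betas=(0.1, -0.3, 0.2),
                         slope_sd=0.05, noise_sd=0.05):
        rows = []
        for p in range(n_p):
            b = np.asarray(betas) + rng.normal(0, slope_sd, len(betas))
            X = rng.normal(0, 1, (n_t, len(betas)))
            y = 0.5 + X @ b + rng.normal(0, noise_sd, n_t)
            for i in range(n_t):
                rows.append({"participant": p, "y": y[i],
                             **{f"x{j}": X[i, j] for j in range(len(betas))}})
        return pd.DataFrame(rows)

    def test_null_data_gives_null_weights(self):
        rng = np.random.default_rng(2)
        df = self._simulate_linear(rng, betas=(0.0, 0.0, 0.0), slope_sd=0.0)
        res = fit_mixed_model(df, dv="y", predictors=["x0", "x1", "x2"],
                              cov_struct="diagonal")
        for fe in res.fixed:
            assert abs(fe.beta_hat) < 4 * fe.se + 1e-3

    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(3)
        n = 64
        # QR with a leading constant column: the rest are centered and
        # mutually orthogonal
        A = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        X = np.linalg.qr(A)[0][:, 1:]
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["participant"] = np.repeat(np.arange(8), 8)
        df["y"] = rng.normal(size=n)
        res = fit_mixed_model(df, dv="y", predictors=["x0", "x1", "x2"],
                              cov_struct="diagonal")
        for fe in res.fixed:
            assert fe.vif == pytest.approx(1.0, abs=1e-6)

    def test_weight_recovery_within_two_se(self):
        """Known generating weights are inside beta_hat +- 2 SE in at least
        90 of 100 simulated datasets."""
        rng = np.random.default_rng(17)
        betas = (0.12, -0.25, 0.08)
        hits = np.zeros(len(betas))
        n_sim = 100
        for _ in range(n_sim):
            df = self._simulate_linear(rng, n_p=12, n_t=30, betas=betas)
            res = fit_mixed_model(df, dv="y", predictors=["x0", "x1", "x2"],
                                  cov_struct="diagonal")
            for j, fe in enumerate(res.fixed):
                hits[j] += abs(fe.beta_hat - betas[j]) <= 2 * fe.se
        assert (hits / n_sim >= 0.90).all()

    def test_r2_invariants(self):
        rng = np.random.default_rng(5)
        df = self._simulate_linear(rng)
        res = fit_mixed_model(df, dv="y", predictors=["x0", "x1", "x2"],
                              cov_struct="diagonal")
        assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(6)
        df = self._simulate_linear(rng, n_p=4, n_t=10)
        df["x_dup"] = df["x0"]
        with pytest.raises(ValueError, match="collinear"):
            fit_mixed_model(df, dv="y",
                            predictors=["x0", "x1", "x2", "x_dup"])

    def test_hysteresis_weight_grows_with_lambda(self):
        """Synthetic heuristic data: the previous-eccentricity weight is
        positive and increases with the generating hysteresis weight."""
        estimates = []
        for lam in (0.1, 0.5):
            params = sc.StrategyParams(hysteresis_weight=lam, noise_sd=0.07)
            design = sc.generate_exp1_design(6, seed=31)
            logs, _ = sc.generate_dataset(design, "heuristic", seed=32,
                                          params=params)
            frame = sc.summaries_to_frame([sc.reduce_trial(l) for l in logs])
            table = build_hysteresis_predictors(frame, "exp1")
            res = fit_mixed_model(table, cov_struct="diagonal")
            w = {fe.name: fe.beta_hat for fe in res.fixed}
            estimates.append(w["prev_ecc_signed"])
            assert w["prev_ecc_signed"] > 0
        assert estimates[1] > estimates[0]
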