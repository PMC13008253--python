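import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kineflux.eta_regression import (
    EtaModel,
    FitError,
    LogitLinearRegression,
    TrainingTable,
    build_training_table,
    enumerate_feature_sets,
    extract_regulator_candidates,
    fit_logit,
    group_folds,
    grouped_cv_adjusted_r2,
    load_eta_models,
    save_eta_models,
    screen_candidate_pool,
    select_model,
)


def logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestEnumeration:
    def test_two_substrates_four_candidates_give_fifteen_sets(self):
        sets = enumerate_feature_sets(["s1", "s2"], ["m1", "m2", "m3", "m4"])
        assert len(sets) == 15
        assert all(subs == ("s1", "s2") for subs, _ in sets)
        assert sets[0][1] == ()  # substrates-only candidate always present

    def test_empty_pool_gives_substrates_only(self):
        assert enumerate_feature_sets(["s1"], []) == [(("s1",), ())]

    def test_five_candidates_give_twenty_six_sets(self):
        assert len(enumerate_feature_sets(["s"], list("abcde"))) == 26  # 1+5+10+10

    @given(m=st.integers(min_value=0, max_value=10))
    @settings(deadline=None, max_examples=11)
    def test_count_matches_brute_force_subset_enumeration(self, m):
        pool = [f"x{i}" for i in range(m)]
        sets = enumerate_feature_sets(["s"], pool, max_extra=3)
        brute = [
            c for k in range(0, 4) for c in itertools.combinations(pool, k)
        ]
        assert len(sets) == len(brute)
        assert [e for _, e in sets] == brute  # deterministic lexicographic order

    def test_pool_overlapping_substrates_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            enumerate_feature_sets(["a"], ["a", "b"])


class TestFitLogit:
    def test_constant_half_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        alpha, beta = fit_logit(X, np.full(30, 0.5))
        np.testing.assert_allclose(alpha, 0.0, atol=1e-10)
        assert beta == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_recovery_to_machine_precision(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 2))
        y = logistic(0.3 * X[:, 0] - 0.2 * X[:, 1] + 0.1)
        alpha, beta = fit_logit(X, y)
        np.testing.assert_allclose(alpha, [0.3, -0.2], atol=1e-6)
        assert beta == pytest.approx(0.1, abs=1e-6)

    def test_boundary_response_clipped_to_finite_coefficients(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 1))
        y = logistic(2.0 * X[:, 0])
        y[0] = 1.0  # exact boundary
        alpha, beta = fit_logit(X, y)
        assert np.isfinite(alpha).all() and np.isfinite(beta)

    def test_rank_deficient_matrix_names_collinear_columns(self):
        X = np.ones((20, 2))
        X[:, 1] = 2.0  # both constant -> collinear with intercept
        with pytest.raises(FitError, match="collinear"):
            fit_logit(X, np.full(20, 0.4))

    def test_out_of_range_response_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            fit_logit(np.ones((5, 1)), np.array([0.5, 0.2, 1.2, 0.3, 0.4]))

    def test_noisy_recovery_rmse_within_ten_percent(self):
        """Logit-scale noise sd 0.05, n=50: coefficient RMSE stays below 10%."""
        rng = np.random.default_rng(3)
        true = np.array([0.1, 0.3, -0.2])  # beta, alpha1, alpha2
        errs = []
        for _ in range(100):
            X = rng.normal(size=(50, 2))
            z = true[0] + X @ true[1:] + rng.normal(0, 0.05, size=50)
            alpha, beta = fit_logit(X, logistic(z))
            errs.append(np.concatenate([[beta - true[0]], alpha - true[1:]]))
        rmse = np.sqrt(np.mean(np.square(errs), axis=0))
        assert np.all(rmse / np.abs(true) <= 0.10)

    def test_refined_fit_handles_saturated_normalized_response(self):
        """On a max-normalized response (one row exactly 1) the eta-scale NLS
        refinement is far more accurate than the clipped transform+OLS fit,
        whose clipped boundary row is a high-leverage logit outlier."""
        rng = np.random.default_rng(4)
        X = np.sort(rng.uniform(0.2, 8.0, size=(40, 1)), axis=0)
        y = logistic(6.0 - 1.5 * X[:, 0])
        y = y / y.max()
        plain = LogitLinearRegression(refine=False).fit(X, y)
        refined = LogitLinearRegression(refine=True).fit(X, y)
        err_plain = np.abs(y - plain.predict(X)).max()
        err_refined = np.abs(y - refined.predict(X)).max()
        assert err_refined < 0.01
        assert err_refined < err_plain / 10

    def test_predictions_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 1)) * 100
        est = LogitLinearRegression().fit(X, logistic(X[:, 0]))
        pred = est.predict(np.array([[1e6], [-1e6], [0.0]]))
        assert np.all((pred > 0) & (pred < 1))

    def test_sklearn_estimator_contract(self):
        est = LogitLinearRegression(epsilon=1e-5, refine=True)
        assert est.get_params() == {"epsilon": 1e-5, "refine": True}
        est.set_params(epsilon=1e-6)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 2))
        est.fit(X, logistic(X[:, 0]))
        assert est.coef_.shape == (2,)
        assert est.n_features_in_ == 2


class TestGroupedCV:
    def _grouped_data(self, n_groups=10, reps=2, p=2, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n_groups * reps, p))
        groups = np.repeat([f"g{i}" for i in range(n_groups)], reps)
        z = 0.2 + X @ np.array([0.5, -0.4])[:p] + rng.normal(0, noise, size=len(X))
        return X, logistic(z), groups

    def test_perfect_fit_scores_one(self):
        X, y, g = self._grouped_data()
        assert grouped_cv_adjusted_r2(X, y, g, seed=0) == pytest.approx(1.0, abs=1e-6)

    def test_adjustment_formula(self):
        # adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1): R^2=0.8, n=10, p=2
        assert 1 - (1 - 0.8) * 9 / 7 == pytest.approx(0.742857, abs=1e-6)

    def test_permuted_response_scores_nonpositive_on_average(self):
        X, y, g = self._grouped_data(n_groups=12)
        rng = np.random.default_rng(42)
        scores = []
        for seed in range(100):
            yp = rng.permutation(y)
            scores.append(grouped_cv_adjusted_r2(X, yp, g, seed=seed))
        assert np.mean(scores) < 0

    def test_folds_never_split_replicate_groups(self):
        groups = np.repeat([f"g{i}" for i in range(9)], 2)
        for seed in range(100):
            folds = group_folds(groups, k_folds=5, seed=seed)
            assert sorted(np.concatenate(folds)) == list(range(18))
            for fold in folds:
                held = set(groups[fold])
                outside = set(groups[np.setdiff1d(np.arange(18), fold)])
                assert not held & outside

    def test_fewer_groups_than_folds_is_an_error(self):
        with pytest.raises(ValueError, match="lower k_folds"):
            group_folds(["a", "a", "b", "b"], k_folds=5)

    def test_fold_assignment_deterministic_given_seed(self):
        groups = np.repeat(list("abcdefgh"), 2)
        f1 = group_folds(groups, seed=7)
        f2 = group_folds(groups, seed=7)
        assert all((a == b).all() for a, b in zip(f1, f2))


def make_training_table(seed=0, n_groups=12, extra_effect=0.0):
    """Synthetic per-reaction table: substrate phi plus 4 decoy metabolites."""
    rng = np.random.default_rng(seed)
    n = n_groups * 2
    phi = pd.DataFrame(
        rng.uniform(0.5, 5.0, size=(n, 5)), columns=["sub", "m1", "m2", "m3", "m4"]
    )
    phi.index = [f"c{i}" for i in range(n)]
    z = 2.0 - 0.9 * phi["sub"] + extra_effect * phi["m2"]
    groups = pd.Series(
        np.repeat([f"g{i}" for i in range(n_groups)], 2), index=phi.index
    )
    return TrainingTable(
        reaction_id="RX",
        phi=phi,
        eta=pd.Series(logistic(z), index=phi.index),
        groups=groups,
        substrates=("sub",),
    )


class TestSelectModel:
    def test_substrate_only_data_selects_no_extras(self):
        table = make_training_table(seed=1)
        model = select_model(table, candidate_pool=["m1", "m2", "m3", "m4"], seed=1)
        assert model.extra_metabolites == ()
        assert model.cv_adj_r2 == pytest.approx(1.0, abs=1e-4)

    def test_planted_effector_is_selected(self):
        table = make_training_table(seed=2, extra_effect=-0.6)
        model = select_model(table, candidate_pool=["m1", "m2", "m3", "m4"], seed=2)
        assert model.extra_metabolites == ("m2",)
        np.testing.assert_allclose(
            [model.alpha["sub"], model.alpha["m2"], model.beta],
            [-0.9, -0.6, 2.0],
            atol=1e-6,
        )

    def test_winner_at_least_as_good_as_substrates_only(self):
        table = make_training_table(seed=3, extra_effect=-0.4)
        model = select_model(table, candidate_pool=["m1", "m2", "m3", "m4"], seed=3)
        sub_score = grouped_cv_adjusted_r2(
            table.phi[["sub"]].to_numpy(), table.eta.to_numpy(),
            table.groups.to_numpy(), seed=3, refine=True,
        )
        assert model.cv_adj_r2 >= sub_score - 1e-6

    def test_selection_deterministic_across_repeated_runs(self):
        table = make_training_table(seed=4)
        m1 = select_model(table, candidate_pool=["m1", "m2"], seed=5)
        m2 = select_model(table, candidate_pool=["m1", "m2"], seed=5)
        assert m1.extra_metabolites == m2.extra_metabolites
        assert m1.cv_adj_r2 == m2.cv_adj_r2

    def test_screening_ranks_true_effector_into_pool(self):
        table = make_training_table(seed=6, extra_effect=-0.8)
        pool = screen_candidate_pool(table, pool_size=2)
        assert "m2" in pool


class TestBuildTrainingTable:
    def test_min_samples_threshold_excludes_sparse_reactions(self, bundle):
        from kineflux.kinetics import build_kinetic_table, compute_flux_sum_table

        table = build_kinetic_table(bundle.dataset)
        fluxsums = compute_flux_sum_table(bundle.model, bundle.dataset.flux)
        eta = table.eta.copy()
        eta.loc["ENZ01", eta.columns[9:]] = np.nan  # only 9 defined conditions
        tabs = build_training_table(
            eta, fluxsums, bundle.model, bundle.dataset.replicate_group, min_samples=10
        )
        assert "ENZ01" not in tabs
        assert "ENZ02" in tabs

    def test_substrates_read_from_negative_stoichiometry(self, bundle):
        from kineflux.kinetics import build_kinetic_table, compute_flux_sum_table

        table = build_kinetic_table(bundle.dataset)
        fluxsums = compute_flux_sum_table(bundle.model, bundle.dataset.flux)
        tabs = build_training_table(
            table.eta, fluxsums, bundle.model, bundle.dataset.replicate_group
        )
        assert tabs["ENZ03"].substrates == ("S03",)

    def test_retained_count_matches_brute_force(self, bundle):
        from kineflux.kinetics import build_kinetic_table, compute_flux_sum_table

        table = build_kinetic_table(bundle.dataset)
        fluxsums = compute_flux_sum_table(bundle.model, bundle.dataset.flux)
        tabs = build_training_table(
            table.eta, fluxsums, bundle.model, bundle.dataset.replicate_group
        )
        oracle = sum(
            1
            for rid in table.eta.index
            if table.eta.loc[rid].notna().sum() >= 10
            and bundle.model.substrates_of(rid)
        )
        assert len(tabs) == oracle


class TestRegulatorCandidates:
    def _model(self, extras):
        return EtaModel("RX", ("sub",), tuple(extras),
                        {m: -0.5 for m in ("sub",) + tuple(extras)}, 1.0, 0.9, 20)

    def test_no_extras_gives_empty_set(self):
        fluxsums = pd.DataFrame(np.random.default_rng(0).uniform(1, 2, (3, 8)),
                                index=["a", "b", "c"])
        assert extract_regulator_candidates(self._model([]), fluxsums) == set()

    def test_affine_copy_included_weak_correlate_excluded(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        fluxsums = pd.DataFrame(
            np.vstack([base, 2.0 * base + 3.0, rng.normal(size=12)]),
            index=["m_sel", "m_copy", "m_noise"],
        )
        out = extract_regulator_candidates(self._model(["m_sel"]), fluxsums)
        assert "m_copy" in out and "m_sel" in out and "m_noise" not in out

    def test_planted_correlation_thresholding(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        partner = 0.9 * base + np.sqrt(1 - 0.81) * rng.normal(size=200)  # r ~ 0.9
        distract = 0.5 * base + np.sqrt(0.75) * rng.normal(size=200)  # r ~ 0.5
        fluxsums = pd.DataFrame(
            np.vstack([base, partner, distract]), index=["sel", "pair", "far"]
        )
        out = extract_regulator_candidates(self._model(["sel"]), fluxsums, 0.8)
        assert out == {"sel", "pair"}

    def test_constant_profile_skipped(self):
        fluxsums = pd.DataFrame(
            np.vstack([np.ones(6), np.arange(6.0)]), index=["sel", "other"]
        )
        out = extract_regulator_candidates(self._model(["sel"]), fluxsums)
        assert out == {"sel"}


class TestSerialization:
    def test_round_trip(self, tmp_path):
        models = {
            "R1": EtaModel("R1", ("a",), ("b",), {"a": 0.5, "b": -0.2}, 1.5, 0.91, 20)
        }
        path = tmp_path / "models.json"
        save_eta_models(models, str(path))
        loaded = load_eta_models(str(path))
        assert loaded["R1"] == models["R1"]

    def test_prediction_after_round_trip(self, tmp_path):
        m = EtaModel("R1", ("a",), (), {"a": -0.3}, 2.0, 0.95, 18)
        save_eta_models({"R1": m}, str(tmp_path / "m.json"))
        m2 = load_eta_models(str(tmp_path / "m.json"))["R1"]
        phi = pd.Series({"a": 1.7})
        assert m2.predict(phi) == pytest.approx(m.predict(phi))
        assert 0 < m2.predict(phi) < 1
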