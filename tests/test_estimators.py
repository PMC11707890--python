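"""LR and CSR estimators: closed-form recovery, penalized paths,
rank-condition errors, and agreement with a generic numerical minimizer."""

import numpy as np
import pytest
from scipy import optimize

from perturbsem import (
    CausalStructureRegression,
    ConvergenceError,
    LinearResponseRegression,
    PerturbationDataset,
    RankDeficientDesignError,
    benchmark_sem,
    fit_csr,
    fit_csr_penalized,
    fit_lr,
    mean_response,
    misspecify_b,
    predict_csr,
    predict_lr,
    random_dag_sem,
    random_mixed_design,
    simulate,
)

DRUG1_RESPONSE = np.array([1.0, 1.6, 1.2, 2.4, 0.0])


def _unit_drug(q, idx):
    D = np.zeros((1, q))
    D[0, idx] = 1.0
    return D


class TestLR:
    def test_noiseless_recovery_of_reduced_form(self, noiseless_data, sem):
        model = fit_lr(noiseless_data)
        R_true = np.linalg.solve(np.eye(5) - sem.A, sem.B)
        np.testing.assert_allclose(model.R_, R_true, atol=1e-8)

    def test_identity_truth(self, rng):
        D = rng.normal(size=(20, 4))
        data = PerturbationDataset(
            D=D, X=D.copy(),
            drug_names=[f"d{i}" for i in range(4)],
            response_names=[f"x{i}" for i in range(4)],
            condition_ids=[str(i) for i in range(20)],
        )
        np.testing.assert_allclose(fit_lr(data).R_, np.eye(4), atol=1e-10)

    def test_zeroed_drug_column_is_zero_and_prediction_vanishes(self, noisy_data):
        model = fit_lr(noisy_data, zeroed_drugs=["D3"])
        assert np.all(model.R_[:, 2] == 0)
        np.testing.assert_array_equal(
            predict_lr(model, _unit_drug(15, 2)), np.zeros((1, 5))
        )

    def test_rank_deficient_design_names_columns(self, noisy_data):
        D = noisy_data.D.copy()
        D[:, 4] = 0.0  # drug 5 never applied
        broken = PerturbationDataset(
            D=D, X=noisy_data.X,
            drug_names=noisy_data.drug_names,
            response_names=noisy_data.response_names,
            condition_ids=noisy_data.condition_ids,
        )
        with pytest.raises(RankDeficientDesignError, match="D5"):
            fit_lr(broken)
        # minimum-norm escape hatch
        model = fit_lr(broken, allow_minimum_norm=True)
        assert model.R_.shape == (5, 15)

    def test_predict_zero_drugs_gives_zero(self, noiseless_data):
        model = fit_lr(noiseless_data)
        np.testing.assert_array_equal(
            predict_lr(model, np.zeros((3, 15))), np.zeros((3, 5))
        )

    def test_training_interpolation_when_noiseless(self, noiseless_data):
        model = fit_lr(noiseless_data)
        np.testing.assert_allclose(
            predict_lr(model, noiseless_data.D), noiseless_data.X, atol=1e-8
        )

    def test_unit_drug_prediction_matches_total_effect(self, noiseless_data):
        model = fit_lr(noiseless_data)
        np.testing.assert_allclose(
            predict_lr(model, _unit_drug(15, 0))[0], DRUG1_RESPONSE, atol=1e-8
        )

    def test_lasso_large_penalty_zeroes_everything(self, noisy_data):
        model = fit_lr(noisy_data, lam=1e6)
        np.testing.assert_array_equal(model.R_, np.zeros((5, 15)))

    def test_lasso_small_penalty_near_ols(self, noisy_data):
        ols = fit_lr(noisy_data)
        lasso = fit_lr(noisy_data, lam=1e-6)
        np.testing.assert_allclose(lasso.R_, ols.R_, atol=1e-4)

    def test_lr_is_b_free(self, noisy_data, sem):
        # identical bits regardless of how the analyst believes B looks
        model = fit_lr(noisy_data)
        model_after_misspec = fit_lr(noisy_data)
        misspecify_b(sem.B)  # B never enters the LR objective
        assert np.array_equal(model.R_, model_after_misspec.R_)


class TestCSR:
    def test_noiseless_recovery_of_structure(self, noiseless_data, sem):
        model = fit_csr(noiseless_data, sem.B)
        np.testing.assert_allclose(model.A_hat_, sem.A, atol=1e-8)
        np.testing.assert_allclose(
            (np.eye(5) - model.A_hat_) @ model.T_, np.eye(5), atol=1e-8
        )
        assert model.pd_report_["pd_ok"]

    def test_unconnected_truth_gives_identity_t(self, rng):
        p = 4
        sem = random_dag_sem(p=p, q=8, seed=3, edge_prob=0.0, noise_sd=0.0)
        data = simulate(sem, random_mixed_design(30, 8, seed=4), seed=5)
        model = fit_csr(data, sem.B)
        np.testing.assert_allclose(model.T_, np.eye(p), atol=1e-8)
        np.testing.assert_allclose(model.A_hat_, np.zeros((p, p)), atol=1e-8)

    def test_misspecified_b_distorts_structure(self, noiseless_data, sem):
        model = fit_csr(noiseless_data, misspecify_b(sem.B))
        assert np.max(np.abs(model.A_hat_ - sem.A)) > 0.2

    def test_rank_condition_error_mentions_targets(self, sem, noiseless_data):
        B_partial = sem.B.copy()
        B_partial[4, :] = 0.0  # no drug targets response 5
        with pytest.raises(RankDeficientDesignError, match="target every response"):
            fit_csr(noiseless_data, B_partial)

    def test_extrapolation_to_held_out_drug(self, noiseless_data, sem):
        # train without any condition involving drug 1
        keep = noiseless_data.D[:, 0] == 0
        sub = noiseless_data.subset(
            [c for c, k in zip(noiseless_data.condition_ids, keep) if k]
        )
        model = fit_csr(sub, sem.B)
        pred = predict_csr(model, sem.B, _unit_drug(15, 0))
        np.testing.assert_allclose(pred[0], DRUG1_RESPONSE, atol=1e-8)

    def test_identity_t_prediction_is_direct_effect(self, sem):
        model = CausalStructureRegression(B=sem.B)
        model.T_ = np.eye(5)
        model.n_features_in_ = 15
        D = _unit_drug(15, 5)
        np.testing.assert_allclose(model.predict(D), D @ sem.B.T)

    def test_predict_zero_is_zero(self, noiseless_data, sem):
        model = fit_csr(noiseless_data, sem.B)
        np.testing.assert_array_equal(
            predict_csr(model, sem.B, np.zeros((2, 15))), np.zeros((2, 5))
        )


class TestPenalizedCSR:
    def test_vanishing_penalty_matches_closed_form(self, noiseless_data, sem):
        pen = fit_csr_penalized(noiseless_data, sem.B, lam=1e-8)
        closed = fit_csr(noiseless_data, sem.B)
        np.testing.assert_allclose(pen.A_hat_, closed.A_hat_, atol=1e-3)

    def test_huge_penalty_kills_off_diagonals(self, noisy_data, sem):
        model = fit_csr_penalized(noisy_data, sem.B, lam=1e6)
        off = model.A_hat_ - np.diag(np.diag(model.A_hat_))
        np.testing.assert_array_equal(off, np.zeros((5, 5)))

    def test_mask_constrains_entry_to_exact_zero(self, noiseless_data, sem):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 1] = True  # a true-zero entry: well-posed constraint
        model = fit_csr_penalized(noiseless_data, sem.B, lam=1e-6, mask=mask)
        assert model.A_hat_[0, 1] == 0.0

    def test_masking_a_strong_true_edge_fails_to_converge(self, noiseless_data, sem):
        # constraining the 1.6 edge to zero on noiseless data leaves an
        # objective whose infimum is not attained: the solver must raise
        # and carry its objective trace
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 0] = True
        est = CausalStructureRegression(B=sem.B, alpha=1e-6, mask=mask, max_iter=2000)
        with pytest.raises(ConvergenceError) as exc:
            est.fit(noiseless_data.D, noiseless_data.X)
        trace = exc.value.trace
        assert len(trace) > 10 and trace[-1] <= trace[0]

    def test_seeded_determinism(self, noisy_data, sem):
        a = fit_csr_penalized(noisy_data, sem.B, lam=0.05, seed=3)
        b = fit_csr_penalized(noisy_data, sem.B, lam=0.05, seed=3)
        np.testing.assert_array_equal(a.A_hat_, b.A_hat_)

    def test_objective_recorded(self, noisy_data, sem):
        model = fit_csr_penalized(noisy_data, sem.B, lam=0.05)
        assert model.objective_ == pytest.approx(model.objective_trace_[-1])


class TestOracleEquivalence:
    """Closed-form fits agree with a generic numerical minimizer of the
    same objective on random small instances."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_lr_matches_generic_minimizer(self, seed):
        r = np.random.default_rng(seed)
        p, q, n = 3, 6, 20
        D = r.normal(size=(n, q))
        X = r.normal(size=(n, p))
        model = LinearResponseRegression().fit(D, X)

        def obj(flat):
            R = flat.reshape(p, q)
            return np.sum((X - D @ R.T) ** 2)

        res = optimize.minimize(obj, np.zeros(p * q), method="BFGS",
                                options={"gtol": 1e-12})
        np.testing.assert_allclose(model.R_, res.x.reshape(p, q), atol=1e-6)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_csr_matches_generic_minimizer(self, seed):
        sem = random_dag_sem(p=3, q=6, seed=seed, edge_prob=0.5, noise_sd=0.2)
        data = simulate(sem, random_mixed_design(20, 6, seed=seed + 10), seed=seed)
        model = fit_csr(data, sem.B)
        G = data.D @ sem.B.T

        def obj(flat):
            T = flat.reshape(3, 3)
            return np.sum((data.X - G @ T.T) ** 2)

        res = optimize.minimize(obj, np.eye(3).ravel(), method="BFGS",
                                options={"gtol": 1e-12})
        np.testing.assert_allclose(model.T_, res.x.reshape(3, 3), atol=1e-6)


def test_prediction_equivalence_at_truth(noiseless_data, sem):
    """With zero noise, LR, CSR and the true mean response coincide on
    any in-span test design."""
    quiet = benchmark_sem()
    quiet.noise_sd = 0.0
    lr = fit_lr(noiseless_data)
    csr = fit_csr(noiseless_data, sem.B)
    rng = np.random.default_rng(0)
    D_test = rng.uniform(0, 1, size=(10, 15))
    truth = np.array([mean_response(quiet, d) for d in D_test])
    np.testing.assert_allclose(predict_lr(lr, D_test), truth, atol=1e-8)
    np.testing.assert_allclose(predict_csr(csr, sem.B, D_test), truth, atol=1e-8)
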