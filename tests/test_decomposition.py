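"""Decomposition tests: prox oracles, ALM feasibility, optimality, recovery."""

import numpy as np
import pytest
from scipy import linalg
from scipy.optimize import minimize

from neurokda import decomposition as dc
from neurokda.features import FeatureMatrix
from neurokda.synth import SynthSpec, generate_cohort


def planted_objective(cohort, params):
    """Objective of the planted feasible triple (class, optimal confound split,
    remainder as sparse error)."""
    conf = cohort.truth_confound_component
    U, s, Vt = linalg.svd(conf, full_matrices=False)
    s = np.where(s > 1e-10, s, 0.0)
    p = params.resolve(*cohort.features.X.shape)
    Bp, bp = dc._split_product(U, s, Vt, p.mu, p.gamma, int(p.n_atoms))
    Ep = cohort.features.X - cohort.truth_class_component - conf
    return dc.objective_value(cohort.truth_class_component, Bp, bp, Ep, p)


def slsqp_test_code_optimum(y, A, B, gamma, tau):
    """Independent convex oracle for the test-coding program: split each
    L1 variable into positive/negative parts and solve the smooth
    equality-constrained QP with SLSQP."""
    M, N = A.shape
    d = B.shape[1]
    n = 2 * N + d + 2 * M

    def obj(z):
        be = z[2 * N:2 * N + d]
        return z[:2 * N].sum() + gamma * be @ be + tau * z[2 * N + d:].sum()

    def grad(z):
        g = np.ones(n)
        g[2 * N:2 * N + d] = 2 * gamma * z[2 * N:2 * N + d]
        g[2 * N + d:] = tau
        return g

    Aeq = np.hstack([A, -A, B, np.eye(M), -np.eye(M)])
    cons = [{"type": "eq", "fun": lambda z: Aeq @ z - y, "jac": lambda z: Aeq}]
    bounds = [(0, None)] * (2 * N) + [(None, None)] * d + [(0, None)] * (2 * M)
    res = minimize(obj, np.zeros(n), jac=grad, bounds=bounds, constraints=cons,
                   method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14})
    assert res.success
    return res.fun


class TestProxOperators:
    @pytest.mark.parametrize("x,t,expected", [(1.5, 1.0, 0.5), (-0.3, 1.0, 0.0),
                                              (-2.0, 0.5, -1.5)])
    def test_soft_threshold_scalars(self, x, t, expected):
        assert dc.soft_threshold(x, t) == pytest.approx(expected)

    def test_soft_threshold_matches_elementwise_formula(self, rng):
        for _ in range(200):
            x = rng.normal(size=(5, 4)) * rng.uniform(0.1, 10)
            t = rng.uniform(0, 3)
            expected = np.sign(x) * np.maximum(np.abs(x) - t, 0)
            assert np.abs(dc.soft_threshold(x, t) - expected).max() <= 1e-8

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            dc.soft_threshold(1.0, -0.1)
        with pytest.raises(ValueError):
            dc.svt(np.eye(2), -0.1)

    def test_svt_diagonal(self):
        out = dc.svt(np.diag([3.0, 1.0]), 2.0)
        np.testing.assert_allclose(out, np.diag([1.0, 0.0]), atol=1e-12)

    def test_svt_zero_matrix(self):
        assert np.all(dc.svt(np.zeros((3, 5)), 1.0) == 0)

    def test_svt_matches_full_svd_oracle(self, rng):
        for _ in range(200):
            Mx = rng.normal(size=(5, 4)) * rng.uniform(0.1, 5)
            t = rng.uniform(0, 2)
            U, s, Vt = np.linalg.svd(Mx, full_matrices=False)
            expected = (U * np.maximum(s - t, 0)) @ Vt
            out = dc.svt(Mx, t)
            assert np.abs(out - expected).max() <= 1e-8
            np.testing.assert_allclose(np.linalg.svd(out, compute_uv=False),
                                       np.maximum(s - t, 0), atol=1e-8)

    def test_svt_rejects_non_finite(self):
        with pytest.raises(ValueError):
            dc.svt(np.array([[np.nan, 0.0], [0.0, 1.0]]), 0.5)


class TestParams:
    @pytest.mark.parametrize("bad", [dict(mu=0), dict(gamma=-1), dict(tau=0),
                                     dict(rho_scale=1.0), dict(tol=0), dict(max_iter=0)])
    def test_invalid_params_raise(self, bad):
        with pytest.raises(ValueError):
            dc.DecompParams(**bad)

    def test_shape_dependent_defaults(self):
        p = dc.DecompParams().resolve(100, 20)
        assert p.tau == pytest.approx(1 / np.sqrt(100))
        assert p.n_atoms == 20


class TestTrainDecompose:
    def test_zero_input_gives_zero_model(self):
        m = dc.train_decompose(np.zeros((10, 4)))
        assert m.converged
        for part in (m.A, m.B, m.beta_train, m.E):
            assert np.all(part == 0)
        assert m.history["objective"][-1] == 0.0

    def test_feasibility_and_objective_dominance(self, small_cohort):
        m = dc.train_decompose(small_cohort.features)
        assert m.converged
        X = small_cohort.features.X
        resid = np.linalg.norm(X - m.A - m.B @ m.beta_train - m.E) / np.linalg.norm(X)
        assert resid <= m.params.tol
        assert m.history["objective"][-1] <= planted_objective(small_cohort, dc.DecompParams())

    def test_rank_of_A_not_above_rank_of_X(self, small_cohort):
        m = dc.train_decompose(small_cohort.features)
        X = small_cohort.features.X

        def numerical_rank(mat):
            s = np.linalg.svd(mat, compute_uv=False)
            return int((s > 1e-6 * s[0]).sum()) if s.size and s[0] > 0 else 0

        assert numerical_rank(m.A) <= numerical_rank(X)

    def test_labels_attached_to_atoms(self, small_cohort):
        m = dc.train_decompose(small_cohort.features)
        np.testing.assert_array_equal(m.labels, small_cohort.features.labels)
        assert m.A.shape[1] == m.labels.size

    def test_nan_input_rejected(self):
        X = np.ones((5, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            dc.train_decompose(X)

    def test_deterministic(self, small_cohort):
        m1 = dc.train_decompose(small_cohort.features)
        m2 = dc.train_decompose(small_cohort.features)
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.E, m2.E)

    def test_scale_equivariance(self):
        # scaling data by c with gamma scaled by c scales all parts by c
        spec = SynthSpec(n_per_class=(8, 8), dim=40, rank_class=2, rank_confound=2,
                         sparsity=0.05, effect=3.0, seed=2)
        X = generate_cohort(spec).features.X
        c = 7.0
        m1 = dc.train_decompose(X, dc.DecompParams())
        m2 = dc.train_decompose(c * X, dc.DecompParams(gamma=c))
        scale = np.abs(c * X).max()
        assert np.abs(m2.A - c * m1.A).max() / scale <= 1e-5
        assert np.abs(m2.B @ m2.beta_train - c * m1.B @ m1.beta_train).max() / scale <= 1e-5
        assert np.abs(m2.E - c * m1.E).max() / scale <= 1e-5

    def test_sparse_support_recovery_with_large_outliers(self):
        # planted corruption >= 5x signal scale: E's largest entries find it
        for seed in range(3):
            spec = SynthSpec(n_per_class=(10, 10), dim=60, rank_class=2,
                             rank_confound=3, sparsity=0.05, effect=3.0,
                             noise_sd=0.0, seed=seed, sparse_amplitude=(5.0, 8.0))
            co = generate_cohort(spec)
            m = dc.train_decompose(co.features)
            true_support = co.truth_sparse.ravel() != 0
            k = int(true_support.sum())
            top = np.argsort(np.abs(m.E).ravel())[::-1][:k]
            overlap = true_support[top].mean()
            assert overlap >= 0.9


class TestTestDecompose:
    def test_zero_vector(self, small_cohort):
        m = dc.train_decompose(small_cohort.features)
        code = dc.test_decompose(np.zeros(m.n_features), m)
        assert code.objective == 0.0
        assert np.all(code.alpha == 0)

    def test_training_column_feasibility_bound(self, small_cohort):
        # y = column j of A: alpha = e_j is feasible with objective 1
        m = dc.train_decompose(small_cohort.features)
        code = dc.test_decompose(m.A[:, 3], m)
        assert code.converged
        assert code.objective <= 1.0 + 1e-6

    def test_residual_invariant(self, small_cohort, rng):
        m = dc.train_decompose(small_cohort.features)
        y = rng.normal(size=m.n_features)
        code = dc.test_decompose(y, m, tol=1e-8)
        resid = np.linalg.norm(y - m.A @ code.alpha - m.B @ code.beta - code.eps)
        assert resid / max(np.linalg.norm(y), 1.0) <= 1e-8

    def test_objective_matches_convex_solver_on_small_instances(self):
        # independent oracle: SLSQP on the split-variable formulation
        for seed in range(5):
            spec = SynthSpec(n_per_class=(3, 3), dim=15, rank_class=1,
                             rank_confound=2, sparsity=0.05, effect=3.0, seed=seed)
            co = generate_cohort(spec)
            m = dc.train_decompose(co.features)
            y = co.truth_class_component[:, 0] + \
                0.5 * np.random.default_rng(seed).normal(size=15)
            code = dc.test_decompose(y, m, tol=1e-9, max_iter=20000)
            opt = slsqp_test_code_optimum(y, m.A, m.B, m.params.gamma, m.params.tau)
            assert abs(code.objective - opt) / max(abs(opt), 1e-12) <= 1e-3

    def test_objective_non_increasing_after_warmup(self, small_cohort, rng):
        m = dc.train_decompose(small_cohort.features)
        y = rng.normal(size=m.n_features)
        code = dc.test_decompose(y, m, tol=1e-10, max_iter=3000)
        obj = np.asarray(code.history["objective"])
        res = np.asarray(code.history["residual"])
        warm = int(np.argmax(res < 1e-6))  # first near-feasible iterate
        diffs = np.diff(obj[warm:])
        assert diffs.max() <= 1e-7 * max(obj[-1], 1.0)

    def test_dimension_mismatch_rejected(self, small_cohort):
        m = dc.train_decompose(small_cohort.features)
        with pytest.raises(ValueError):
            dc.test_decompose(np.zeros(m.n_features + 1), m)


class TestClassComponent:
    def test_zero_and_unit_codes(self, small_cohort):
        m = dc.train_decompose(small_cohort.features)
        zero = dc.TestCode(np.zeros(m.n_train), np.zeros(m.B.shape[1]),
                           np.zeros(m.n_features), 0.0, 0.0, True)
        assert np.all(dc.class_component(zero, m) == 0)
        ej = dc.TestCode(np.eye(m.n_train)[4], np.zeros(m.B.shape[1]),
                         np.zeros(m.n_features), 0.0, 0.0, True)
        np.testing.assert_allclose(dc.class_component(ej, m), m.A[:, 4])

    def test_component_tracks_planted_class_signal(self):
        # Pearson correlation of the coded class component against the
        # planted class signal beats its correlation against the confound;
        # the balance parameter is calibrated as the pipeline would
        from neurokda.pipeline import calibrate_decomp_params

        spec = SynthSpec(n_per_class=(10, 10), dim=60, rank_class=2,
                         rank_confound=3, sparsity=0.02, effect=5.0,
                         noise_sd=0.1, confound_strength=0.5, seed=5)
        co = generate_cohort(spec)
        params = calibrate_decomp_params(co.features.X, co.features.labels)
        m = dc.train_decompose(co.features, params)
        j = 0
        code = dc.test_decompose(co.features.X[:, j], m)
        comp = dc.class_component(code, m)
        r_class = np.corrcoef(comp, co.truth_class_component[:, j])[0, 1]
        r_conf = np.corrcoef(comp, co.truth_confound_component[:, j])[0, 1]
        assert r_class > abs(r_conf)


def test_model_serialization_roundtrip(tmp_path, small_cohort):
    m = dc.train_decompose(small_cohort.features)
    path = tmp_path / "model.npz"
    dc.save_model(m, path)
    back = dc.load_model(path)
    np.testing.assert_array_equal(back.A, m.A)
    np.testing.assert_array_equal(back.labels, m.labels)
    assert back.params == m.params
    assert back.converged == m.converged
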