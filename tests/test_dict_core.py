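"""Single-layer operations against independent oracles.

Oracles used here: a dense angular grid for the one-atom dictionary update,
a vectorized Kronecker-product linear solve for the inner code update,
plain gradient descent for the per-sample last-layer objective and for the
SVM, and hand evaluation for the objective examples.
"""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from tsmdl import dict_core
from tsmdl.dict_core import (
    ClassifierParams,
    Dictionary,
    InitConfig,
    LayerHyperParams,
    fit_linear_svm,
    ksvd_init,
    total_objective,
    update_codes_inner,
    update_codes_last,
    update_dictionary,
)
from tsmdl.graphs import LabelVector, build_laplacian_pair, build_pair_weights


def _graphs_for(labels):
    return build_laplacian_pair(build_pair_weights(labels))


def _random_dictionary(rng, d, k):
    D = rng.standard_normal((d, k))
    return Dictionary(atoms=D / np.linalg.norm(D, axis=0))


class TestKSVDInit:
    def test_recovers_scaled_unit_vectors(self):
        """Data whose columns are exact multiples of K distinct unit vectors
        must yield those vectors (up to sign/permutation) as atoms."""
        rng = np.random.default_rng(0)
        d, K, n = 12, 6, 90
        basis = np.linalg.qr(rng.standard_normal((d, K)))[0]
        idx = np.tile(np.arange(K), n // K)
        X = basis[:, idx] * rng.uniform(0.5, 2.0, size=n)
        labels = LabelVector(["A"] * n)
        D = ksvd_init(X, labels, K, InitConfig(ksvd_sparsity=1, ksvd_iters=15, seed=0))
        corr = np.abs(basis.T @ D.atoms)
        r, c = linear_sum_assignment(-corr)
        assert corr[r, c].min() >= 0.99

    def test_unit_norm_and_determinism(self, rng):
        X = rng.standard_normal((10, 40))
        labels = LabelVector(["A"] * 20 + ["B"] * 20)
        cfg = InitConfig(seed=7)
        D1 = ksvd_init(X, labels, 8, cfg)
        D2 = ksvd_init(X, labels, 8, cfg)
        np.testing.assert_allclose(np.linalg.norm(D1.atoms, axis=0), 1, atol=1e-8)
        np.testing.assert_array_equal(D1.atoms, D2.atoms)

    def test_remainder_atoms_go_to_largest_class(self, rng):
        X = rng.standard_normal((10, 30))
        labels = LabelVector(["A"] * 10 + ["B"] * 20)
        D = ksvd_init(X, labels, 5, InitConfig(seed=0))  # 2 + 2 + 1 extra for B
        assert D.n_atoms == 5

    def test_overcomplete_rejected(self, rng):
        X = rng.standard_normal((10, 6))
        with pytest.raises(ValueError, match="overcomplete beyond sample count"):
            ksvd_init(X, LabelVector(["A"] * 6), 8, InitConfig(seed=0))


class TestDictionaryUpdate:
    def test_single_atom_matches_angular_grid_oracle(self):
        """K=1 has the closed form D = input z^T / ||input z^T||; compare to
        brute-force minimization over the unit circle (2-D input)."""
        rng = np.random.default_rng(1)
        inp = rng.standard_normal((2, 15))
        z = rng.standard_normal((1, 15))
        D0 = Dictionary(atoms=np.array([[1.0], [0.0]]))
        D = update_dictionary(inp, z, D0)

        thetas = np.linspace(0, 2 * np.pi, 200_000, endpoint=False)
        cand = np.stack([np.cos(thetas), np.sin(thetas)])  # (2, n_grid)
        errs = (
            np.linalg.norm(inp) ** 2
            - 2 * (cand.T @ inp @ z.ravel())
            + np.linalg.norm(z) ** 2
        )
        best = cand[:, np.argmin(errs)]
        assert np.linalg.norm(D.atoms.ravel() - best) < 1e-4
        closed = (inp @ z.T) / np.linalg.norm(inp @ z.T)
        np.testing.assert_allclose(D.atoms, closed, atol=1e-6)

    def test_exact_factorization_reaches_zero_error(self, rng):
        Dtrue = _random_dictionary(rng, 8, 5)
        Z = rng.standard_normal((5, 30))
        inp = Dtrue.atoms @ Z
        D0 = _random_dictionary(rng, 8, 5)
        D = update_dictionary(inp, Z, D0, max_sweeps=200, rel_tol=1e-14)
        assert np.linalg.norm(inp - D.atoms @ Z) ** 2 <= 1e-8

    @pytest.mark.parametrize("seed", range(50))
    def test_reconstruction_error_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        d, k, n = 6, 4, 12
        inp = rng.standard_normal((d, n))
        Z = rng.standard_normal((k, n))
        D0 = _random_dictionary(rng, d, k)
        before = np.linalg.norm(inp - D0.atoms @ Z) ** 2
        D = update_dictionary(inp, Z, D0)
        after = np.linalg.norm(inp - D.atoms @ Z) ** 2
        assert after <= before + 1e-10
        np.testing.assert_allclose(np.linalg.norm(D.atoms, axis=0), 1, atol=1e-8)

    def test_zero_code_row_keeps_previous_atom(self, rng):
        inp = rng.standard_normal((5, 10))
        Z = rng.standard_normal((3, 10))
        Z[1, :] = 0.0
        D0 = _random_dictionary(rng, 5, 3)
        D = update_dictionary(inp, Z, D0)
        np.testing.assert_array_equal(D.atoms[:, 1], D0.atoms[:, 1])


def _kron_oracle(D, prev, next_contrib, P, hp):
    """Minimize the layer objective by solving the vectorized normal
    equations (I kron A + M^T kron I) vec(Z) = vec(B)."""
    Dm = D.atoms
    K, n = Dm.shape[1], prev.shape[1]
    A = Dm.T @ Dm
    B = Dm.T @ prev
    if next_contrib is not None:
        A = A + np.eye(K)
        B = B + next_contrib
    M = hp.alpha * P.P_same - hp.beta * P.P_diff + hp.lam * np.eye(n)
    # column-major vec: vec(AZ) = (I kron A) vec(Z), vec(ZM) = (M^T kron I) vec(Z)
    big = np.kron(np.eye(n), A) + np.kron(M.T, np.eye(K))
    z = np.linalg.solve(big, B.T.ravel())
    return z.reshape(n, K).T


class TestInnerCodeUpdate:
    def test_orthonormal_unregularized_is_projection(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        D = Dictionary(atoms=q)
        X = rng.standard_normal((6, 9))
        P = _graphs_for(LabelVector(["A"] * 9))
        hp = LayerHyperParams(alpha=0, beta=0, lam=0)
        # lam = 0 with orthonormal D: system is A = I, still PD
        Z = update_codes_inner(D, X, None, P, hp)
        np.testing.assert_allclose(Z, q.T @ X, atol=1e-10)

    def test_next_layer_contribution_halves_projection(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        D = Dictionary(atoms=q)
        X = rng.standard_normal((5, 7))
        P = _graphs_for(LabelVector(["A"] * 7))
        hp = LayerHyperParams(alpha=0, beta=0, lam=0)
        Z = update_codes_inner(D, X, np.zeros((5, 7)), P, hp)
        np.testing.assert_allclose(Z, 0.5 * q.T @ X, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("with_next", [False, True])
    def test_matches_kronecker_oracle(self, seed, with_next):
        rng = np.random.default_rng(seed)
        d, K, n = 8, 6, 10
        D = _random_dictionary(rng, d, K)
        prev = rng.standard_normal((d, n))
        nxt = rng.standard_normal((K, n)) if with_next else None
        labels = LabelVector([f"c{i % 3}" for i in range(n)])
        P = _graphs_for(labels)
        hp = LayerHyperParams(alpha=0.5, beta=0.2, lam=0.3)
        Z = update_codes_inner(D, prev, nxt, P, hp)
        Z_oracle = _kron_oracle(D, prev, nxt, P, hp)
        rel = np.linalg.norm(Z - Z_oracle) / np.linalg.norm(Z_oracle)
        assert rel <= 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_lam_zero_beta_never_ill_posed(self, seed):
        """With beta = 0 and lam > 0 the system is provably PD."""
        rng = np.random.default_rng(seed)
        D = _random_dictionary(rng, 4, 6)  # overcomplete, A singular
        prev = rng.standard_normal((4, 8))
        P = _graphs_for(LabelVector(random_labels_local(rng, 8)))
        hp = LayerHyperParams(alpha=float(rng.uniform(0, 2)), beta=0.0, lam=float(rng.uniform(0.01, 2)))
        update_codes_inner(D, prev, None, P, hp)  # must not raise

    def test_ill_posed_hyperparameters_rejected(self, rng):
        D = _random_dictionary(rng, 4, 6)
        prev = rng.standard_normal((4, 8))
        P = _graphs_for(LabelVector(["A"] * 4 + ["B"] * 4))
        hp = LayerHyperParams(alpha=0.0, beta=50.0, lam=0.0)
        with pytest.raises(ValueError, match="ill-posed"):
            update_codes_inner(D, prev, None, P, hp)


def random_labels_local(rng, n):
    return [f"c{int(rng.integers(3))}" for _ in range(n)]


def _last_layer_objective(Z, D, prev, P, clf, labels, hp):
    bd = total_objective(
        prev, [D], [Z], P, clf, [hp], labels=labels, loss="squared_hinge", include_clf_reg=False
    )
    return bd.total


class TestLastLayerCodeUpdate:
    def _setup(self, seed, n=8, lam_clf=0.4):
        rng = np.random.default_rng(seed)
        d, K = 6, 5
        D = _random_dictionary(rng, d, K)
        prev = rng.standard_normal((d, n))
        labels = LabelVector(["a"] * (n // 2) + ["b"] * (n - n // 2))
        P = _graphs_for(labels)
        hp = LayerHyperParams(alpha=0.3, beta=0.1, lam=0.5)
        clf = ClassifierParams(
            weights=rng.standard_normal((K, 2)),
            biases=rng.standard_normal(2),
            classes=("a", "b"),
            clf_weight=lam_clf,
        )
        return D, prev, labels, P, hp, clf

    def test_zero_coupling_equals_inner_update(self):
        D, prev, labels, P, hp, clf = self._setup(0, lam_clf=0.0)
        Z_last = update_codes_last(D, prev, P, clf, labels, hp)
        Z_inner = update_codes_inner(D, prev, None, P, hp)
        np.testing.assert_allclose(Z_last, Z_inner, atol=1e-10)

    def test_single_sample_matches_gradient_descent_oracle(self):
        """One sample, alpha = beta = 0: the guarded active-set solve must
        agree with a plain gradient-descent minimizer of the per-sample
        squared-hinge surrogate."""
        rng = np.random.default_rng(3)
        d, K = 6, 4
        D = _random_dictionary(rng, d, K)
        prev = rng.standard_normal((d, 1))
        labels = LabelVector(["a"])
        P = _graphs_for(labels)
        hp = LayerHyperParams(alpha=0.0, beta=0.0, lam=0.7)
        clf = ClassifierParams(
            weights=rng.standard_normal((K, 2)),
            biases=rng.standard_normal(2),
            classes=("a", "b"),
            clf_weight=0.8,
        )
        Z = update_codes_last(D, prev, P, clf, labels, hp)

        def obj(z):
            r = prev.ravel() - D.atoms @ z
            val = r @ r + hp.lam * (z @ z)
            for k, c in enumerate(clf.classes):
                y = 1.0 if c == "a" else -1.0
                m = y * (clf.weights[:, k] @ z + clf.biases[k])
                val += clf.clf_weight * max(0.0, 1.0 - m) ** 2
            return val

        def grad(z, eps=1e-6):
            g = np.zeros_like(z)
            for i in range(z.size):
                e = np.zeros_like(z)
                e[i] = eps
                g[i] = (obj(z + e) - obj(z - e)) / (2 * eps)
            return g

        z = np.zeros(K)
        for _ in range(20000):
            g = grad(z)
            z -= 0.01 * g
        assert np.linalg.norm(Z.ravel() - z) / max(np.linalg.norm(z), 1.0) <= 1e-4
        assert obj(Z.ravel()) <= obj(z) + 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_surrogate_objective_never_increases(self, seed):
        D, prev, labels, P, hp, clf = self._setup(seed)
        Z0 = update_codes_inner(D, prev, None, P, hp)
        before = _last_layer_objective(Z0, D, prev, P, clf, labels, hp)
        Z = update_codes_last(D, prev, P, clf, labels, hp, Z_init=Z0)
        after = _last_layer_objective(Z, D, prev, P, clf, labels, hp)
        assert after <= before + 1e-10


class TestLinearSVM:
    def test_separable_clouds_classified_perfectly(self, rng):
        Z = np.hstack([rng.normal(-3, 0.3, (2, 20)), rng.normal(3, 0.3, (2, 20))])
        labels = LabelVector(["neg"] * 20 + ["pos"] * 20)
        clf = fit_linear_svm(Z, labels, cost=10.0)
        pred_idx = np.argmax(clf.scores(Z), axis=0)
        pred = [clf.classes[i] for i in pred_idx]
        assert pred == list(labels.labels)

    def test_symmetric_data_has_zero_bias(self, rng):
        Zh = rng.standard_normal((3, 15)) + np.array([[2.0], [0.0], [0.0]])
        Z = np.hstack([Zh, -Zh])
        labels = LabelVector(["pos"] * 15 + ["neg"] * 15)
        clf = fit_linear_svm(Z, labels, cost=1.0)
        assert np.all(np.abs(clf.biases) <= 1e-6)

    def test_matches_gradient_descent_oracle(self):
        """Per-class squared-hinge SVM objective at the fitted parameters
        matches a plain (sub)gradient-descent minimizer to 1e-3 relative."""
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((3, 10))
        labels = LabelVector(["a", "b"] * 5)
        cost = 1.0
        clf = fit_linear_svm(Z, labels, cost=cost)

        def class_obj(w, b, y):
            r = np.maximum(0.0, 1.0 - y * (Z.T @ w + b))
            return w @ w / (2 * cost) + r @ r

        for k, c in enumerate(clf.classes):
            y = np.where(np.array(labels.labels, dtype=object) == c, 1.0, -1.0)
            x = np.zeros(4)
            for _ in range(50000):
                w, b = x[:3], x[3]
                r = 1.0 - y * (Z.T @ w + b)
                act = r > 0
                gw = w / cost - 2 * Z[:, act] @ (y[act] * r[act])
                gb = -2 * float((y[act] * r[act]).sum())
                x = x - 2e-3 * np.concatenate([gw, [gb]])
            oracle = class_obj(x[:3], x[3], y)
            fitted = class_obj(clf.weights[:, k], clf.biases[k], y)
            assert fitted <= oracle * (1 + 1e-3)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate class"):
            fit_linear_svm(rng.standard_normal((2, 5)), LabelVector(["a"] * 5))

    def test_missing_requested_class_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate class"):
            fit_linear_svm(
                rng.standard_normal((2, 6)),
                LabelVector(["a", "b"] * 3),
                classes=("a", "b", "c"),
            )


class TestTotalObjective:
    def test_all_zero_parameters_hand_value(self, rng):
        """Z = 0, w = 0, b = 0: every term vanishes except ||X||_F^2 and one
        unit margin violation per class per sample."""
        d, K, n, C = 5, 3, 7, 2
        X = rng.standard_normal((d, n))
        D = _random_dictionary(rng, d, K)
        labels = LabelVector(["a", "b"] * 3 + ["a"])
        P = _graphs_for(labels)
        clf = ClassifierParams(
            weights=np.zeros((K, C)), biases=np.zeros(C), classes=("a", "b"), clf_weight=0.3
        )
        hp = LayerHyperParams(alpha=0.4, beta=0.2, lam=0.9)
        for loss in ("hinge", "squared_hinge"):
            bd = total_objective(
                X, [D], [np.zeros((K, n))], P, clf, [hp], labels=labels, loss=loss
            )
            expected = np.linalg.norm(X) ** 2 + 0.3 * n * C
            assert bd.total == pytest.approx(expected, rel=1e-12)

    def test_exact_factorization_zero_objective(self, rng):
        D1 = _random_dictionary(rng, 8, 6)
        D2 = _random_dictionary(rng, 6, 4)
        Z2 = rng.standard_normal((4, 10))
        Z1 = D2.atoms @ Z2
        X = D1.atoms @ Z1
        labels = LabelVector(["a", "b"] * 5)
        P = _graphs_for(labels)
        hp = LayerHyperParams(alpha=0, beta=0, lam=0)
        bd = total_objective(X, [D1, D2], [Z1, Z2], P, None, [hp, hp], labels=labels)
        assert bd.total == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_form_equals_pairwise_form(self, seed):
        """The graph part of the objective equals half the pairwise double
        sum (the trace form is canonical; factor 2 relates the two)."""
        from tsmdl.graphs import build_pair_weights, pairwise_penalty

        rng = np.random.default_rng(seed)
        n = 6
        labels = LabelVector(random_labels_local(rng, n))
        Q = build_pair_weights(labels)
        P = _graphs_for(labels)
        Z = rng.standard_normal((4, n))
        hp = LayerHyperParams(alpha=0.7, beta=0.2, lam=0.0)
        D = _random_dictionary(rng, 5, 4)
        X = rng.standard_normal((5, n))
        bd = total_objective(X, [D], [Z], P, None, [hp], labels=labels)
        pairwise = 0.5 * (
            hp.alpha * pairwise_penalty(Z, Q.Q_same) - hp.beta * pairwise_penalty(Z, Q.Q_diff)
        )
        assert bd.graph[0] == pytest.approx(pairwise, abs=1e-10)
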