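"""Single-layer building blocks of the multi-layer dictionary model.

Each layer l factorizes its input (the previous layer's codes, or the data
matrix X at layer 1) as ``Z_{l-1} approx D_l Z_l`` with unit-norm dictionary
columns.  Codes are regularized by a ridge penalty and by class-aware graph
Laplacians; the last layer's codes are additionally coupled to a linear
max-margin classifier.  This module provides:

* K-SVD per-class dictionary initialization,
* the dictionary update (column-wise block coordinate descent),
* the inner-layer code update (an exact Sylvester-type solve),
* the last-layer code update (guarded per-column active-set solves with a
  squared-hinge classification surrogate),
* a one-vs-rest linear SVM fit, and
* evaluation of the full objective with a per-term breakdown.

The graph penalty is used throughout in its trace form ``Tr(Z M Z^T)`` with
``M = alpha P_same - beta P_diff + lambda I``; the pairwise double-sum form
equals twice the trace form and is only used as a test oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from sklearn.linear_model import orthogonal_mp

from .graphs import LabelVector, LaplacianPair

logger = logging.getLogger(__name__)

__all__ = [
    "Dictionary",
    "LayerHyperParams",
    "ClassifierParams",
    "InitConfig",
    "ksvd_init",
    "update_dictionary",
    "update_codes_inner",
    "update_codes_last",
    "fit_linear_svm",
    "svm_objective",
    "total_objective",
    "ObjectiveBreakdown",
]

_UNIT_NORM_TOL = 1e-8


@dataclass
class Dictionary:
    """A layer dictionary: unit-norm atoms as columns of ``atoms``."""

    atoms: np.ndarray
    layer_index: int = 0

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix (input_dim x K)")
        if not np.all(np.isfinite(self.atoms)):
            raise ValueError("atoms must be finite")
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("every dictionary column must have unit norm")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def input_dim(self) -> int:
        return self.atoms.shape[0]


@dataclass(frozen=True)
class LayerHyperParams:
    """Per-layer weights: alpha (same-class pull), beta (different-class
    push), lam (ridge), dict_size (number of atoms K_l)."""

    alpha: float = 0.1
    beta: float = 0.01
    lam: float = 0.1
    dict_size: int = 8

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.lam < 0:
            raise ValueError("alpha, beta, lam must be nonnegative")
        if self.dict_size < 1:
            raise ValueError("dict_size must be positive")


@dataclass
class ClassifierParams:
    """One-vs-rest linear classifier: one weight column and bias per class."""

    weights: np.ndarray  # (K_L, C)
    biases: np.ndarray  # (C,)
    classes: tuple
    cost: float = 1.0
    clf_weight: float = 0.1

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]

    def scores(self, Z: np.ndarray) -> np.ndarray:
        """Class scores w_c^T z + b_c, shape (C, N)."""
        return self.weights.T @ Z + self.biases[:, None]


@dataclass(frozen=True)
class InitConfig:
    """K-SVD initialization settings: sparsity target T, iterations, seed."""

    ksvd_sparsity: int = 3
    ksvd_iters: int = 10
    seed: int = 0


def _normalize_columns(D: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    D = D.copy()
    norms = np.linalg.norm(D, axis=0)
    for j in np.flatnonzero(norms < 1e-12):
        if rng is None:
            v = np.zeros(D.shape[0])
            v[j % D.shape[0]] = 1.0
        else:
            v = rng.standard_normal(D.shape[0])
        D[:, j] = v
    norms = np.linalg.norm(D, axis=0)
    return D / norms


def _fix_signs(D: np.ndarray) -> np.ndarray:
    """Resolve the sign ambiguity of atoms deterministically: the entry of
    largest magnitude in each column is made positive."""
    idx = np.argmax(np.abs(D), axis=0)
    signs = np.sign(D[idx, np.arange(D.shape[1])])
    signs[signs == 0] = 1.0
    return D * signs


def _ksvd(X: np.ndarray, K: int, sparsity: int, iters: int, rng: np.random.Generator) -> np.ndarray:
    """Plain K-SVD: alternate OMP sparse coding and rank-1 atom updates.

    Dead atoms (no users) are replaced by the currently worst-represented
    sample, which keeps the algorithm deterministic given the rng state.
    """
    d, n = X.shape
    cols = rng.choice(n, size=K, replace=False)
    D = _normalize_columns(X[:, cols], rng)
    T = min(sparsity, K, d)
    for _ in range(iters):
        with warnings.catch_warnings():
            # linear dependence among a class's few atoms is expected early on
            warnings.simplefilter("ignore", RuntimeWarning)
            Z = orthogonal_mp(D, X, n_nonzero_coefs=T)
        if Z.ndim == 1:
            Z = Z[:, None]
        for j in range(K):
            users = np.flatnonzero(Z[j, :] != 0.0)
            if users.size == 0:
                resid = np.linalg.norm(X - D @ Z, axis=0)
                worst = int(np.argmax(resid))
                atom = X[:, worst]
                nrm = np.linalg.norm(atom)
                if nrm < 1e-12:
                    atom = rng.standard_normal(d)
                    nrm = np.linalg.norm(atom)
                D[:, j] = atom / nrm
                continue
            E = X[:, users] - D @ Z[:, users] + np.outer(D[:, j], Z[j, users])
            # rank-1 SVD of E
            U, s, Vt = np.linalg.svd(E, full_matrices=False)
            D[:, j] = U[:, 0]
            Z[j, users] = s[0] * Vt[0]
    return _fix_signs(D)


def ksvd_init(X: np.ndarray, labels: LabelVector, K: int, cfg: InitConfig) -> Dictionary:
    """Initialize a layer dictionary by running K-SVD separately per class.

    Each class receives ``K // C`` atoms (remainder atoms go to the largest
    class); per-class dictionaries are concatenated and column-normalized.
    Deterministic given ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    if K > n:
        raise ValueError("overcomplete beyond sample count at init")
    classes = labels.classes
    C = len(classes)
    if K < C:
        raise ValueError(f"need at least one atom per class (K={K} < {C} classes)")
    y = np.asarray(labels.labels, dtype=object)
    counts = {c: int(np.sum(y == c)) for c in classes}
    base = K // C
    alloc = {c: base for c in classes}
    largest = max(classes, key=lambda c: (counts[c], str(c)))
    alloc[largest] += K - base * C
    rng = np.random.default_rng(cfg.seed)
    blocks = []
    for c in classes:
        kc = alloc[c]
        if kc == 0:
            continue
        Xc = X[:, y == c]
        if kc > Xc.shape[1]:
            raise ValueError("overcomplete beyond sample count at init")
        blocks.append(_ksvd(Xc, kc, cfg.ksvd_sparsity, cfg.ksvd_iters, rng))
    D = _normalize_columns(np.hstack(blocks), rng)
    return Dictionary(atoms=D)


def update_dictionary(
    inp: np.ndarray,
    codes: np.ndarray,
    D_prev: Dictionary,
    max_sweeps: int = 10,
    rel_tol: float = 1e-6,
) -> Dictionary:
    """Minimize ``||inp - D codes||_F^2`` over unit-norm-column D, codes fixed.

    Column-wise block coordinate descent: each atom's exact constrained
    minimizer given the others is ``E_j z_j^T`` normalized, where ``E_j`` is
    the residual excluding atom j.  The reconstruction error never increases.
    Atoms whose code row is all zero are kept from ``D_prev`` (logged).
    """
    inp = np.asarray(inp, dtype=float)
    codes = np.asarray(codes, dtype=float)
    D = D_prev.atoms.copy()
    K = D.shape[1]
    if codes.shape[0] != K or inp.shape[1] != codes.shape[1] or inp.shape[0] != D.shape[0]:
        raise ValueError("inconsistent shapes in dictionary update")
    R = inp - D @ codes
    prev_err = float(np.linalg.norm(R) ** 2)
    for _ in range(max_sweeps):
        for j in range(K):
            zj = codes[j, :]
            if not np.any(zj):
                logger.debug("atom %d has an all-zero code row; kept from previous dictionary", j)
                continue
            Rj = R + np.outer(D[:, j], zj)
            v = Rj @ zj
            nrm = np.linalg.norm(v)
            if nrm < 1e-14:
                continue
            d_new = v / nrm
            D[:, j] = d_new
            R = Rj - np.outer(d_new, zj)
        err = float(np.linalg.norm(R) ** 2)
        if prev_err - err <= rel_tol * max(prev_err, 1e-30):
            break
        prev_err = err
    return Dictionary(atoms=D, layer_index=D_prev.layer_index)


def _graph_matrix(P: LaplacianPair, hp: LayerHyperParams) -> np.ndarray:
    n = P.n
    return hp.alpha * P.P_same - hp.beta * P.P_diff + hp.lam * np.eye(n)


def _solve_sylvester_sym(A: np.ndarray, M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A Z + Z M = B for symmetric A, M via eigendecomposition.

    Requires min eig(A) + min eig(M) > 0 (joint positive definiteness of the
    quadratic form), otherwise the layer subproblem is unbounded below.
    """
    wA, UA = eigh(A)
    wM, VM = eigh(M)
    if wA[0] + wM[0] <= 1e-10:
        raise ValueError("ill-posed hyperparameters: increase lambda_l or decrease beta_l")
    Bt = UA.T @ B @ VM
    Z = Bt / (wA[:, None] + wM[None, :])
    return UA @ Z @ VM.T


def update_codes_inner(
    D_l: Dictionary,
    prev: np.ndarray,
    next_contrib: Optional[np.ndarray],
    P: LaplacianPair,
    hp: LayerHyperParams,
) -> np.ndarray:
    """Exact minimizer of the inner-layer code objective.

    Minimizes ``||prev - D Z||_F^2 + ||Z - next_contrib||_F^2 (if a next
    layer exists) + Tr(Z M Z^T)`` with ``M = alpha P_same - beta P_diff +
    lam I``.  The stationarity condition is the two-sided linear equation
    ``(D^T D + delta I) Z + Z M = D^T prev + next_contrib`` (delta = 1 iff a
    next layer exists), solved exactly through eigendecompositions.
    """
    prev = np.asarray(prev, dtype=float)
    Dm = D_l.atoms
    K = Dm.shape[1]
    A = Dm.T @ Dm
    B = Dm.T @ prev
    if next_contrib is not None:
        A = A + np.eye(K)
        B = B + np.asarray(next_contrib, dtype=float)
    M = _graph_matrix(P, hp)
    return _solve_sylvester_sym(A, M, B)


def _active_set(clf: ClassifierParams, y_signs: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Classes whose margin is violated at z: y_c (w_c^T z + b_c) < 1."""
    margins = y_signs * (clf.weights.T @ z + clf.biases)
    return np.flatnonzero(margins < 1.0)


def _col_objective(
    z: np.ndarray,
    i: int,
    DtD: np.ndarray,
    Dt_prev_i: np.ndarray,
    prev_i_sq: float,
    M: np.ndarray,
    Z: np.ndarray,
    clf: ClassifierParams,
    y_signs_i: np.ndarray,
    lam_clf: float,
) -> float:
    """Exact per-column value of the last-layer surrogate objective (terms
    involving column i only; cross terms with other, fixed columns included)."""
    recon = prev_i_sq - 2.0 * float(Dt_prev_i @ z) + float(z @ DtD @ z)
    cross = Z @ M[:, i] - M[i, i] * Z[:, i]
    graph = M[i, i] * float(z @ z) + 2.0 * float(z @ cross)
    margins = y_signs_i * (clf.weights.T @ z + clf.biases)
    viol = np.maximum(0.0, 1.0 - margins)
    return recon + graph + lam_clf * float(viol @ viol)


def update_codes_last(
    D_L: Dictionary,
    prev: np.ndarray,
    P: LaplacianPair,
    clf: ClassifierParams,
    labels: LabelVector,
    hp: LayerHyperParams,
    max_sweeps: int = 5,
    Z_init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Last-layer code update with the classifier coupling.

    Minimizes ``||prev - D Z||_F^2 + Tr(Z M Z^T) + lam_clf * sum_c
    squared-hinge`` by per-column block coordinate descent.  The non-smooth
    classification term is handled with an active-set squared-hinge
    surrogate: classes currently violating the margin enter a per-column
    linear system; each candidate column is accepted only if it lowers the
    exact per-column objective, so the update never increases the surrogate
    objective.  Sweeps stop when the active sets stabilize (max 5 sweeps).
    """
    prev = np.asarray(prev, dtype=float)
    Dm = D_L.atoms
    K = Dm.shape[1]
    lam_clf = clf.clf_weight
    M = _graph_matrix(P, hp)
    if lam_clf == 0.0:
        return update_codes_inner(D_L, prev, None, P, hp)
    DtD = Dm.T @ Dm
    # joint convexity check, as in the inner update
    wA = np.linalg.eigvalsh(DtD)
    wM = np.linalg.eigvalsh(M)
    if wA[0] + wM[0] <= 1e-10:
        raise ValueError("ill-posed hyperparameters: increase lambda_l or decrease beta_l")
    Z = np.asarray(Z_init, dtype=float).copy() if Z_init is not None else _solve_sylvester_sym(DtD, M, Dm.T @ prev)
    n = prev.shape[1]
    y_int = labels.as_int()
    classes = labels.classes
    class_idx = {c: k for k, c in enumerate(clf.classes)}
    # y_signs[c, i] = +1 if sample i belongs to class c else -1
    y_signs = -np.ones((clf.n_classes, n))
    for i in range(n):
        y_signs[class_idx[classes[y_int[i]]], i] = 1.0
    Dt_prev = Dm.T @ prev
    prev_sq = np.sum(prev * prev, axis=0)
    prev_active = None
    for _ in range(max_sweeps):
        active_sets = []
        for i in range(n):
            z_old = Z[:, i].copy()
            act = _active_set(clf, y_signs[:, i], z_old)
            active_sets.append(tuple(act))
            cross = Z @ M[:, i] - M[i, i] * z_old
            H = DtD + M[i, i] * np.eye(K)
            rhs = Dt_prev[:, i] - cross
            if act.size:
                W = clf.weights[:, act]
                H = H + lam_clf * (W @ W.T)
                rhs = rhs + lam_clf * (W @ (y_signs[act, i] * (1.0 - y_signs[act, i] * clf.biases[act])))
            try:
                z_new = np.linalg.solve(H, rhs)
            except np.linalg.LinAlgError:
                continue
            f_old = _col_objective(z_old, i, DtD, Dt_prev[:, i], prev_sq[i], M, Z, clf, y_signs[:, i], lam_clf)
            f_new = _col_objective(z_new, i, DtD, Dt_prev[:, i], prev_sq[i], M, Z, clf, y_signs[:, i], lam_clf)
            if f_new < f_old:
                Z[:, i] = z_new
        if prev_active is not None and active_sets == prev_active:
            break
        prev_active = active_sets
    return Z


def _svm_loss_grad(x: np.ndarray, Z: np.ndarray, y: np.ndarray, cost: float):
    w, b = x[:-1], x[-1]
    margins = y * (Z.T @ w + b)
    r = 1.0 - margins
    act = r > 0
    f = float(w @ w) / (2.0 * cost) + float(r[act] @ r[act])
    coef = np.zeros_like(r)
    coef[act] = -2.0 * y[act] * r[act]
    grad_w = w / cost + Z @ coef
    grad_b = float(coef.sum())
    return f, np.concatenate([grad_w, [grad_b]])


def fit_linear_svm(
    Z_L: np.ndarray,
    labels: LabelVector,
    cost: float = 1.0,
    clf_weight: float = 0.1,
    warm: Optional[ClassifierParams] = None,
    classes: Optional[Sequence] = None,
) -> ClassifierParams:
    """Fit one-vs-rest linear max-margin classifiers on last-layer codes.

    Per class c, with y in {+1, -1}, minimizes the smooth squared-hinge SVM
    objective ``||w||^2 / (2 cost) + sum_i max(0, 1 - y_i (w^T z_i + b))^2``
    by L-BFGS (warm-started when a previous classifier is supplied, so a
    refit never increases this objective).  Deterministic given the data.
    """
    Z_L = np.asarray(Z_L, dtype=float)
    present = labels.classes
    if classes is None:
        classes = present
    classes = tuple(classes)
    if len(classes) < 2:
        raise ValueError("degenerate class: need at least two classes")
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"degenerate class: {missing[0]!r} absent from training labels")
    if cost <= 0:
        raise ValueError("cost must be positive")
    K, n = Z_L.shape
    y_int = labels.as_int()
    lbls = np.asarray(labels.labels, dtype=object)
    W = np.zeros((K, len(classes)))
    b = np.zeros(len(classes))
    for k, c in enumerate(classes):
        y = np.where(lbls == c, 1.0, -1.0)
        x0 = np.zeros(K + 1)
        if warm is not None and c in warm.classes:
            kw = warm.classes.index(c)
            x0[:-1] = warm.weights[:, kw]
            x0[-1] = warm.biases[kw]
        res = minimize(
            _svm_loss_grad,
            x0,
            args=(Z_L, y, cost),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "gtol": 1e-10, "ftol": 1e-14},
        )
        # L-BFGS line search satisfies Wolfe conditions, so res.fun <= f(x0);
        # guard anyway against pathological termination.
        f0, _ = _svm_loss_grad(x0, Z_L, y, cost)
        if res.fun <= f0:
            W[:, k], b[k] = res.x[:-1], res.x[-1]
        else:
            W[:, k], b[k] = x0[:-1], x0[-1]
    return ClassifierParams(weights=W, biases=b, classes=classes, cost=cost, clf_weight=clf_weight)


def svm_objective(clf: ClassifierParams, Z: np.ndarray, labels: LabelVector, include_reg: bool = True) -> float:
    """Sum over classes of the squared-hinge SVM objective evaluated on Z."""
    lbls = np.asarray(labels.labels, dtype=object)
    total = 0.0
    for k, c in enumerate(clf.classes):
        y = np.where(lbls == c, 1.0, -1.0)
        margins = y * (Z.T @ clf.weights[:, k] + clf.biases[k])
        r = np.maximum(0.0, 1.0 - margins)
        total += float(r @ r)
        if include_reg:
            total += float(clf.weights[:, k] @ clf.weights[:, k]) / (2.0 * clf.cost)
    return total


@dataclass
class ObjectiveBreakdown:
    """Per-term values of the objective, for logging and convergence checks."""

    reconstruction: list = field(default_factory=list)  # per layer
    graph: list = field(default_factory=list)  # per layer, Tr(Z M Z^T)
    classification: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(self.reconstruction) + sum(self.graph) + self.classification)


def total_objective(
    X: np.ndarray,
    dicts: Sequence[Dictionary],
    codes: Sequence[np.ndarray],
    P: LaplacianPair,
    clf: Optional[ClassifierParams],
    hps: Sequence[LayerHyperParams],
    labels: Optional[LabelVector] = None,
    loss: str = "hinge",
    include_clf_reg: bool = False,
) -> ObjectiveBreakdown:
    """Evaluate the full multi-layer objective with a per-term breakdown.

    ``sum_l ||Z_{l-1} - D_l Z_l||_F^2 + sum_l Tr(Z_l M_l Z_l^T) + lam_clf *
    sum_c f(Z_L, y_c, w_c, b_c)`` with ``Z_0 = X``.  ``loss`` selects the
    classification term: ``"hinge"`` (the max-margin loss the model states)
    or ``"squared_hinge"`` (the optimization surrogate); with
    ``include_clf_reg`` the classifiers' ridge terms ``||w_c||^2/(2 cost)``
    are added inside the lam_clf factor, giving the exact quantity that the
    alternating solver decreases.
    """
    out = ObjectiveBreakdown()
    Z_prev = np.asarray(X, dtype=float)
    for D, Z, hp in zip(dicts, codes, hps):
        R = Z_prev - D.atoms @ Z
        out.reconstruction.append(float(np.linalg.norm(R) ** 2))
        M = _graph_matrix(P, hp)
        out.graph.append(float(np.trace(Z @ M @ Z.T)))
        Z_prev = Z
    if clf is not None and clf.clf_weight > 0.0:
        if labels is None:
            raise ValueError("labels required to evaluate the classification term")
        Z_L = codes[-1]
        lbls = np.asarray(labels.labels, dtype=object)
        total = 0.0
        for k, c in enumerate(clf.classes):
            y = np.where(lbls == c, 1.0, -1.0)
            margins = y * (Z_L.T @ clf.weights[:, k] + clf.biases[k])
            r = np.maximum(0.0, 1.0 - margins)
            if loss == "hinge":
                total += float(r.sum())
            elif loss == "squared_hinge":
                total += float(r @ r)
            else:
                raise ValueError(f"unknown loss {loss!r}")
            if include_clf_reg:
                total += float(clf.weights[:, k] @ clf.weights[:, k]) / (2.0 * clf.cost)
        out.classification = clf.clf_weight * total
    return out
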