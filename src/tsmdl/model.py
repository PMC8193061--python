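"""The full transfer-learning estimator.

Fits a stack of dictionaries shared between a labeled source domain and a
(sparsely labeled) target domain by alternating optimization: dictionary
updates, graph-regularized code updates layer by layer, a classifier-coupled
last-layer code update, and a one-vs-rest linear SVM refit.  At test time a
stack of ridge encoders maps a new sample through the dictionaries and the
classifier scores decide the label.

Typical use::

    cfg = TSMDLConfig(n_layers=2, dict_sizes=(16, 8), seed=0)
    model = fit(X_s, y_s, X_t, y_t, cfg)
    y_hat = predict(model, X_test)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedShuffleSplit

from . import dict_core, graphs
from .dict_core import ClassifierParams, Dictionary, InitConfig, LayerHyperParams
from .graphs import LabelVector, LaplacianPair

logger = logging.getLogger(__name__)

__all__ = [
    "TSMDLConfig",
    "TSMDLModel",
    "fit",
    "build_encoder",
    "encode",
    "predict",
    "evaluate",
    "split_target",
    "run_experiment",
]

#: Dictionary sizes used for layers 1..5 when none are given.
DEFAULT_DICT_SIZES = (500, 450, 400, 350, 300)


@dataclass(frozen=True)
class TSMDLConfig:
    """Hyperparameters of the full model.

    ``dict_sizes`` defaults to (500, 450, 400, 350, 300) truncated to
    ``n_layers``.  ``layer_params`` may be a single LayerHyperParams applied
    to every layer or one per layer.  ``clf_weight`` is the coupling weight
    between the last-layer codes and the classifier; ``svm_cost`` the SVM
    trade-off.
    """

    n_layers: int = 3
    dict_sizes: Optional[tuple] = None
    alpha: float = 0.1
    beta: float = 0.01
    lam: float = 0.1
    clf_weight: float = 0.1
    svm_cost: float = 1.0
    max_outer_iters: int = 30
    rel_tol: float = 1e-5
    ksvd_sparsity: int = 3
    ksvd_iters: int = 10
    recompute_graphs: bool = False
    seed: int = 0
    layer_params: Optional[tuple] = None

    def __post_init__(self):
        if not 1 <= self.n_layers <= 5:
            raise ValueError("n_layers must be in 1..5")
        sizes = self.dict_sizes
        if sizes is None:
            sizes = DEFAULT_DICT_SIZES[: self.n_layers]
        sizes = tuple(int(k) for k in sizes)
        if len(sizes) != self.n_layers:
            raise ValueError("len(dict_sizes) must equal n_layers")
        if any(k < 2 for k in sizes):
            raise ValueError("every dictionary size must be >= 2")
        object.__setattr__(self, "dict_sizes", sizes)
        if self.layer_params is not None and len(self.layer_params) != self.n_layers:
            raise ValueError("layer_params must have one entry per layer")

    def hyper_params(self) -> tuple:
        """Resolved per-layer hyperparameters."""
        if self.layer_params is not None:
            return tuple(
                replace(hp, dict_size=k) for hp, k in zip(self.layer_params, self.dict_sizes)
            )
        return tuple(
            LayerHyperParams(alpha=self.alpha, beta=self.beta, lam=self.lam, dict_size=k)
            for k in self.dict_sizes
        )

    def to_dict(self) -> dict:
        hps = self.hyper_params()
        return {
            "n_layers": self.n_layers,
            "dict_sizes": list(self.dict_sizes),
            "layer_params": [
                {"alpha": h.alpha, "beta": h.beta, "lam": h.lam, "dict_size": h.dict_size}
                for h in hps
            ],
            "clf_weight": self.clf_weight,
            "svm_cost": self.svm_cost,
            "max_outer_iters": self.max_outer_iters,
            "rel_tol": self.rel_tol,
            "ksvd_sparsity": self.ksvd_sparsity,
            "ksvd_iters": self.ksvd_iters,
            "recompute_graphs": self.recompute_graphs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TSMDLConfig":
        d = dict(d)
        lp = d.pop("layer_params", None)
        if lp is not None:
            d["layer_params"] = tuple(LayerHyperParams(**h) for h in lp)
        return cls(**d)


@dataclass
class TSMDLModel:
    """A fitted model: dictionaries, ridge encoders, classifier, and log."""

    dicts: list  # of Dictionary
    thetas: list  # encoder matrices, thetas[l] has shape (K_l, K_{l-1})
    classifier: ClassifierParams
    config: TSMDLConfig
    training_log: list = field(default_factory=list)
    objective_breakdown: list = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.dicts[0].input_dim

    @property
    def classes(self) -> tuple:
        return self.classifier.classes


def _build_joined_laplacians(labels: LabelVector) -> LaplacianPair:
    """Per-domain supervised graphs, block-joined (source block first)."""
    parts = []
    for dom in (graphs.SOURCE, graphs.TARGET):
        idx = labels.domain_indices(dom)
        if idx.size == 0:
            parts.append(None)
            continue
        sub = labels.subset(idx)
        parts.append(graphs.build_laplacian_pair(graphs.build_pair_weights(sub)))
    return graphs.block_join(parts[0], parts[1])


def _ridge_encoder(D: Dictionary, lam: float) -> np.ndarray:
    """Theta = (D^T D + lam I)^{-1} D^T; errors if the system is singular."""
    Dm = D.atoms
    G = Dm.T @ Dm + lam * np.eye(Dm.shape[1])
    w = np.linalg.eigvalsh(G)
    if w[0] <= 1e-12:
        raise ValueError(
            "singular encoder system (rank-deficient dictionary with lambda_l = 0); "
            "set lambda_l > 0"
        )
    return np.linalg.solve(G, Dm.T)


def _surrogate_objective(X, dicts, codes, P, clf, hps, labels) -> dict_core.ObjectiveBreakdown:
    return dict_core.total_objective(
        X, dicts, codes, P, clf, hps, labels=labels, loss="squared_hinge", include_clf_reg=True
    )


def fit(
    X_s: np.ndarray,
    y_s: Optional[Sequence],
    X_t: np.ndarray,
    y_t: Sequence,
    cfg: TSMDLConfig,
) -> TSMDLModel:
    """Fit the model on labeled source and target samples.

    Columns are samples.  ``X_s`` may be empty (shape (d, 0)), in which case
    the model degenerates to single-domain supervised dictionary learning on
    the target — used as the no-transfer baseline.

    The outer loop follows the alternating scheme: update every dictionary,
    update inner-layer codes (exact Sylvester solves), update last-layer
    codes (classifier-coupled), refit the SVM, and record the surrogate
    objective.  Stops when the relative objective change drops below
    ``cfg.rel_tol`` or after ``cfg.max_outer_iters`` iterations.
    """
    X_s = np.asarray(X_s, dtype=float)
    X_t = np.asarray(X_t, dtype=float)
    if X_s.size == 0 and X_s.ndim != 2:
        X_s = X_s.reshape(X_t.shape[0], 0)
    if X_s.shape[1] > 0 and X_s.shape[0] != X_t.shape[0]:
        raise ValueError(
            f"feature dimension mismatch between domains: source has {X_s.shape[0]}, "
            f"target has {X_t.shape[0]}"
        )
    y_s = list(y_s) if y_s is not None else []
    y_t = list(y_t)
    if len(y_s) != X_s.shape[1] or len(y_t) != X_t.shape[1]:
        raise ValueError("label count must match sample count in each domain")
    labels = LabelVector(y_s + y_t, [graphs.SOURCE] * len(y_s) + [graphs.TARGET] * len(y_t))
    if len(labels.classes) < 2:
        raise ValueError("degenerate class: need at least two classes in the training data")
    X = np.hstack([X_s, X_t])

    hps = cfg.hyper_params()
    L = cfg.n_layers
    P = _build_joined_laplacians(labels)

    # --- initialization: per-class K-SVD dictionaries, ridge-encoded codes
    init_cfg = InitConfig(ksvd_sparsity=cfg.ksvd_sparsity, ksvd_iters=cfg.ksvd_iters, seed=cfg.seed)
    dicts: list = []
    codes: list = []
    Z_prev = X
    for l in range(L):
        D = dict_core.ksvd_init(Z_prev, labels, cfg.dict_sizes[l], init_cfg)
        D.layer_index = l
        lam_enc = max(hps[l].lam, 1e-8)
        Z = _ridge_encoder(D, lam_enc) @ Z_prev
        dicts.append(D)
        codes.append(Z)
        Z_prev = Z
    clf = dict_core.fit_linear_svm(
        codes[-1], labels, cost=cfg.svm_cost, clf_weight=cfg.clf_weight
    )

    bd = _surrogate_objective(X, dicts, codes, P, clf, hps, labels)
    log = [bd.total]
    breakdowns = [bd]
    logger.info("iter 0 (init): objective %.6g", bd.total)

    for it in range(1, cfg.max_outer_iters + 1):
        inputs = [X] + codes[:-1]
        for l in range(L):
            dicts[l] = dict_core.update_dictionary(inputs[l], codes[l], dicts[l])
        if cfg.recompute_graphs:
            # labels never change, so this is the identity; kept for fidelity
            P = _build_joined_laplacians(labels)
        for l in range(L - 1):
            inp = X if l == 0 else codes[l - 1]
            next_contrib = dicts[l + 1].atoms @ codes[l + 1]
            codes[l] = dict_core.update_codes_inner(dicts[l], inp, next_contrib, P, hps[l])
        inp_last = X if L == 1 else codes[L - 2]
        codes[L - 1] = dict_core.update_codes_last(
            dicts[L - 1], inp_last, P, clf, labels, hps[L - 1], Z_init=codes[L - 1]
        )
        clf = dict_core.fit_linear_svm(
            codes[-1], labels, cost=cfg.svm_cost, clf_weight=cfg.clf_weight, warm=clf
        )
        bd = _surrogate_objective(X, dicts, codes, P, clf, hps, labels)
        breakdowns.append(bd)
        log.append(bd.total)
        logger.info(
            "iter %d: objective %.6g (recon %.4g, graph %.4g, clf %.4g)",
            it,
            bd.total,
            sum(bd.reconstruction),
            sum(bd.graph),
            bd.classification,
        )
        if abs(log[-2] - log[-1]) < cfg.rel_tol * max(abs(log[-2]), 1e-30):
            break

    thetas = [_ridge_encoder(D, hp.lam if hp.lam > 0 else 1e-8) for D, hp in zip(dicts, hps)]
    return TSMDLModel(
        dicts=dicts,
        thetas=thetas,
        classifier=clf,
        config=cfg,
        training_log=log,
        objective_breakdown=breakdowns,
    )


def build_encoder(model: TSMDLModel) -> list:
    """Recompute the per-layer ridge encoders Theta_l = (D^T D + lam I)^-1 D^T.

    The graph regularizers do not enter the test-time encoder: they couple
    training samples to each other and cannot apply to a single unseen
    sample, so the encoder is the model's inductive (ridge) approximation.
    """
    hps = model.config.hyper_params()
    return [_ridge_encoder(D, hp.lam if hp.lam > 0 else 1e-8) for D, hp in zip(model.dicts, hps)]


def encode(model: TSMDLModel, x_new: np.ndarray) -> np.ndarray:
    """Map input vectors (or a (d, n) matrix) to last-layer codes.

    Applies the encoder stack layer by layer, z <- Theta_l z for
    l = 1..L (the only shape-valid composition).
    """
    x = np.asarray(x_new, dtype=float)
    vector_in = x.ndim == 1
    if vector_in:
        x = x[:, None]
    if x.shape[0] != model.input_dim:
        raise ValueError(f"expected input of length {model.input_dim}, got {x.shape[0]}")
    z = x
    for theta in model.thetas:
        z = theta @ z
    return z[:, 0] if vector_in else z


def predict(model: TSMDLModel, X_new: np.ndarray) -> list:
    """Predicted class labels: argmax over class scores w_c^T z + b_c.

    Ties are broken toward the lowest class index (classes are stored in
    sorted order), so prediction is deterministic.
    """
    Z = encode(model, X_new)
    if Z.ndim == 1:
        Z = Z[:, None]
    scores = model.classifier.scores(Z)
    idx = np.argmax(scores, axis=0)
    return [model.classes[i] for i in idx]


def evaluate(y_true: Sequence, y_pred: Sequence, pos_label=None) -> dict:
    """Accuracy, precision, recall, F1.

    For binary tasks the positive class is ``pos_label`` when given, the
    label ``"tumor"`` when present, otherwise the lexicographically last
    class; multiclass tasks are macro-averaged.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    classes = sorted(set(y_true) | set(y_pred))
    acc = accuracy_score(y_true, y_pred)
    if len(classes) == 2:
        if pos_label is None:
            pos_label = "tumor" if "tumor" in classes else classes[-1]
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", pos_label=pos_label, zero_division=0
        )
    else:
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0
        )
    return {
        "accuracy": float(acc),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f),
    }


def split_target(
    X_t: np.ndarray, y_t: Sequence, train_fraction: float = 0.1, seed: int = 0
) -> tuple:
    """Stratified split of the target domain into a small labeled training
    part (default 10%) and a held-out test part.

    Returns ``(X_train, y_train, X_test, y_test)``; columns are samples.
    """
    y_t = np.asarray(list(y_t), dtype=object)
    n = len(y_t)
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=train_fraction, random_state=seed)
    (train_idx, test_idx), = splitter.split(np.zeros(n), y_t)
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    return (
        X_t[:, train_idx],
        list(y_t[train_idx]),
        X_t[:, test_idx],
        list(y_t[test_idx]),
    )


def run_experiment(
    X_s: np.ndarray,
    y_s: Sequence,
    X_t: np.ndarray,
    y_t: Sequence,
    cfg: TSMDLConfig,
    n_repeats: int = 10,
    target_train_fraction: float = 0.1,
    use_source: bool = True,
) -> dict:
    """Repeated-split evaluation protocol.

    For each of ``n_repeats`` repeats (distinct seeds derived from
    ``cfg.seed``): train on the full source plus a stratified
    ``target_train_fraction`` of the target, test on the remaining target
    samples; report the mean and standard deviation of accuracy, precision,
    recall, and F1.  With ``use_source=False`` the source is dropped — the
    no-transfer baseline.
    """
    per_metric: dict = {}
    runs = []
    for r in range(n_repeats):
        seed_r = int(cfg.seed) + 1000 * (r + 1)
        Xtr_t, ytr_t, Xte_t, yte_t = split_target(
            X_t, y_t, train_fraction=target_train_fraction, seed=seed_r
        )
        cfg_r = replace(cfg, seed=seed_r)
        if use_source:
            m = fit(X_s, y_s, Xtr_t, ytr_t, cfg_r)
        else:
            empty = np.zeros((X_t.shape[0], 0))
            m = fit(empty, [], Xtr_t, ytr_t, cfg_r)
        metrics = evaluate(yte_t, predict(m, Xte_t))
        runs.append(metrics)
    out = {}
    for key in ("accuracy", "precision", "recall", "f1"):
        vals = np.asarray([r[key] for r in runs])
        out[f"{key}_mean"] = float(vals.mean())
        out[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out["n_repeats"] = n_repeats
    out["runs"] = runs
    return out
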