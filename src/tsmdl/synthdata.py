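"""Synthetic two-domain transfer tasks with known ground truth.

Data are generated from the model's own assumption: a shared stack of
unit-norm-column dictionaries ``X = D_1 (D_2 (... (D_L z_L)))`` with
class-clustered deepest-layer codes.  Domain shift is realized as a
perturbation of the *dictionaries* used for the target domain (not a mean
shift): the model's premise is a shared dictionary, and this is the knob
that violates that premise smoothly — magnitude 0 gives ideal transfer,
large magnitudes a negative-transfer regime for stress tests.

A second generator produces the classic identifiable dictionary-learning
setting (sparse codes on class-specific supports) for atom-recovery tests,
where dense isotropic codes would leave the dictionary determined only up
to rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dict_core import Dictionary
from .graphs import SOURCE, TARGET, LabelVector

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "generate_ground_truth_model",
    "generate_transfer_task",
    "generate_sparse_recovery_task",
    "generate_blob_image",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    class_separation scales the distance between class prototype codes in
    units of the within-class code standard deviation (which is 1);
    domain_shift is the magnitude of the random perturbation applied to the
    target-domain dictionaries; noise_sd the observation noise.
    """

    input_dim: int = 32
    layer_sizes: tuple = (16, 8)
    n_classes: int = 2
    n_source: int = 120
    n_target: int = 120
    class_separation: float = 2.0
    domain_shift: float = 0.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1 or self.n_classes < 1:
            raise ValueError("input_dim and n_classes must be positive")
        if self.n_source < 0 or self.n_target < 1:
            raise ValueError("sample counts must be positive (n_source may be 0)")
        if len(self.layer_sizes) < 1 or any(k < 1 for k in self.layer_sizes):
            raise ValueError("layer_sizes must be positive")
        if self.layer_sizes[-1] < self.n_classes:
            raise ValueError("deepest layer must have at least one atom per class")
        if self.class_separation < 0 or self.domain_shift < 0 or self.noise_sd < 0:
            raise ValueError("separation, shift and noise must be nonnegative")
        for n, what in ((self.n_source, "n_source"), (self.n_target, "n_target")):
            if n and n % self.n_classes:
                raise ValueError(f"{what}={n} not divisible by n_classes={self.n_classes}")


@dataclass
class SynthDataset:
    """Generated data plus the ground truth that produced it."""

    X_s: np.ndarray
    X_t: np.ndarray
    y_s: list
    y_t: list
    true_dicts: list  # source-domain Dictionary per layer
    true_dicts_target: list  # target-domain (shifted) Dictionary per layer
    true_codes_s: np.ndarray  # deepest-layer codes, source
    true_codes_t: np.ndarray
    prototypes: np.ndarray  # (K_L, n_classes)
    config: SynthConfig = None

    @property
    def labels(self) -> LabelVector:
        return LabelVector(self.y_s + self.y_t, [SOURCE] * len(self.y_s) + [TARGET] * len(self.y_t))


def _random_unit_dict(rng: np.random.Generator, d: int, k: int) -> np.ndarray:
    D = rng.standard_normal((d, k))
    return D / np.linalg.norm(D, axis=0)


def generate_ground_truth_model(cfg: SynthConfig) -> tuple:
    """Random unit-norm dictionaries D_1..D_L plus class prototype codes.

    Prototypes are mutually orthogonal directions in deepest-layer code
    space, scaled so every pair is ``class_separation`` apart (within-class
    code sd is 1); class_separation = 0 collapses all prototypes to zero.
    """
    rng = np.random.default_rng(cfg.seed)
    dims = (cfg.input_dim,) + tuple(cfg.layer_sizes)
    dicts = [
        Dictionary(atoms=_random_unit_dict(rng, dims[l], dims[l + 1]), layer_index=l)
        for l in range(len(cfg.layer_sizes))
    ]
    K_L = cfg.layer_sizes[-1]
    G = rng.standard_normal((K_L, cfg.n_classes))
    ortho, _ = np.linalg.qr(G)
    # orthonormal columns at distance sqrt(2); rescale so pairwise distance
    # equals class_separation
    prototypes = ortho * (cfg.class_separation / np.sqrt(2.0))
    return dicts, prototypes


def _class_names(n_classes: int) -> list:
    if n_classes == 2:
        return ["normal", "tumor"]
    return [f"class{c}" for c in range(n_classes)]


def _sample_domain(
    rng: np.random.Generator,
    dicts: list,
    prototypes: np.ndarray,
    n: int,
    n_classes: int,
    noise_sd: float,
) -> tuple:
    per = n // n_classes
    names = _class_names(n_classes)
    y = [names[c] for c in range(n_classes) for _ in range(per)]
    K_L = prototypes.shape[0]
    Z = np.empty((K_L, n))
    for c in range(n_classes):
        sl = slice(c * per, (c + 1) * per)
        Z[:, sl] = prototypes[:, [c]] + rng.standard_normal((K_L, per))
    X = Z
    for D in reversed(dicts):
        X = D.atoms @ X
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)
    return X, y, Z


def _shift_dicts(rng: np.random.Generator, dicts: list, magnitude: float) -> list:
    if magnitude == 0.0:
        return [Dictionary(atoms=D.atoms.copy(), layer_index=D.layer_index) for D in dicts]
    out = []
    for D in dicts:
        G = _random_unit_dict(rng, *D.atoms.shape)
        pert = D.atoms + magnitude * G
        pert /= np.linalg.norm(pert, axis=0)
        out.append(Dictionary(atoms=pert, layer_index=D.layer_index))
    return out


def generate_transfer_task(cfg: SynthConfig = SynthConfig()) -> SynthDataset:
    """Generate a labeled two-domain task from a shared ground-truth model.

    Deepest-layer codes are class prototypes plus isotropic unit-variance
    noise; observations are the multi-layer reconstruction plus Gaussian
    noise of sd ``noise_sd``.  Target samples use dictionaries perturbed by
    ``domain_shift`` (perturbed columns renormalized to unit norm).  Classes
    are exactly balanced within each domain.
    """
    dicts, prototypes = generate_ground_truth_model(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    dicts_t = _shift_dicts(rng, dicts, cfg.domain_shift)
    if cfg.n_source:
        X_s, y_s, Z_s = _sample_domain(rng, dicts, prototypes, cfg.n_source, cfg.n_classes, cfg.noise_sd)
    else:
        X_s = np.zeros((cfg.input_dim, 0))
        y_s, Z_s = [], np.zeros((cfg.layer_sizes[-1], 0))
    X_t, y_t, Z_t = _sample_domain(rng, dicts_t, prototypes, cfg.n_target, cfg.n_classes, cfg.noise_sd)
    return SynthDataset(
        X_s=X_s,
        X_t=X_t,
        y_s=y_s,
        y_t=y_t,
        true_dicts=dicts,
        true_dicts_target=dicts_t,
        true_codes_s=Z_s,
        true_codes_t=Z_t,
        prototypes=prototypes,
        config=cfg,
    )


def generate_sparse_recovery_task(
    input_dim: int = 16,
    n_atoms: int = 8,
    n_samples: int = 400,
    n_classes: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SynthDataset:
    """Single-layer task with sparse class-supported codes, for atom recovery.

    Atoms are split evenly across classes; each sample activates exactly one
    atom from its class's support with a coefficient drawn uniformly from
    [1, 2] (sign random).  In this regime the dictionary is identifiable, so
    a learner's atoms can be compared to the truth by best-assignment cosine
    similarity.
    """
    if n_atoms % n_classes:
        raise ValueError("n_atoms must be divisible by n_classes")
    if n_samples % n_classes:
        raise ValueError(f"n_samples={n_samples} not divisible by n_classes={n_classes}")
    rng = np.random.default_rng(seed)
    D = Dictionary(atoms=_random_unit_dict(rng, input_dim, n_atoms), layer_index=0)
    per = n_samples // n_classes
    per_class_atoms = n_atoms // n_classes
    names = _class_names(n_classes)
    y = [names[c] for c in range(n_classes) for _ in range(per)]
    Z = np.zeros((n_atoms, n_samples))
    for c in range(n_classes):
        support = np.arange(c * per_class_atoms, (c + 1) * per_class_atoms)
        for i in range(per):
            j = support[i % per_class_atoms]
            coef = rng.uniform(1.0, 2.0) * rng.choice([-1.0, 1.0])
            Z[j, c * per + i] = coef
    X = D.atoms @ Z
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)
    return SynthDataset(
        X_s=X,
        X_t=np.zeros((input_dim, 0)),
        y_s=y,
        y_t=[],
        true_dicts=[D],
        true_dicts_target=[D],
        true_codes_s=Z,
        true_codes_t=np.zeros((n_atoms, 0)),
        prototypes=np.zeros((n_atoms, n_classes)),
        config=None,
    )


def generate_blob_image(
    size: int = 64, n_blobs: int = 3, noise_sd: float = 0.05, seed: int = 0
) -> np.ndarray:
    """A synthetic grayscale test image: Gaussian blobs on noise, in [0, 1].

    Used for end-to-end feature-extraction tests; it emulates nothing about
    real MRI beyond being a nonnegative single-channel raster.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
        s = rng.uniform(0.05 * size, 0.15 * size)
        a = rng.uniform(0.5, 1.0)
        img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    img += noise_sd * rng.standard_normal(img.shape)
    img -= img.min()
    if img.max() > 0:
        img /= img.max()
    return img
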