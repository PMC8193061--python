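"""Supervised pair-weight graphs and their Laplacians.

The model regularizes each layer's coding matrix with two graphs built from
class labels: a *same-class* graph pulling codes of equally labeled samples
together and a *different-class* graph pushing codes of differently labeled
samples apart.  Graphs are built per domain (source, target) and then joined
block-diagonally, so there is never a cross-domain edge.

Pair weights are normalized by the number of qualifying ordered pairs, so the
nonzero entries of each weight matrix sum to one and the two penalty terms are
scale-comparable regardless of sample count or class balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LabelVector",
    "PairWeights",
    "LaplacianPair",
    "build_pair_weights",
    "build_laplacian_pair",
    "block_join",
    "pairwise_penalty",
]

SOURCE = "source"
TARGET = "target"


@dataclass(frozen=True)
class LabelVector:
    """Class labels plus source/target domain tags for N samples.

    Domain tags must form a contiguous source block followed by a contiguous
    target block (either block may be empty), matching the column layout of
    the concatenated feature matrix ``X = [X_s, X_t]``.
    """

    labels: tuple
    domains: tuple

    def __init__(self, labels: Sequence, domains: Optional[Sequence] = None):
        labels = tuple(labels)
        if domains is None:
            domains = (SOURCE,) * len(labels)
        domains = tuple(domains)
        if len(domains) != len(labels):
            raise ValueError("labels and domains must have equal length")
        bad = set(domains) - {SOURCE, TARGET}
        if bad:
            raise ValueError(f"unknown domain tag(s): {sorted(bad)!r}")
        # contiguity: once we see 'target' we must never see 'source' again
        seen_target = False
        for d in domains:
            if d == TARGET:
                seen_target = True
            elif seen_target:
                raise ValueError("domain tags must be a source block followed by a target block")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "domains", domains)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> tuple:
        return tuple(sorted(set(self.labels)))

    def domain_indices(self, domain: str) -> np.ndarray:
        return np.asarray([i for i, d in enumerate(self.domains) if d == domain], dtype=int)

    def subset(self, idx: Sequence[int]) -> "LabelVector":
        idx = list(idx)
        return LabelVector([self.labels[i] for i in idx], [self.domains[i] for i in idx])

    def concat(self, other: "LabelVector") -> "LabelVector":
        return LabelVector(self.labels + other.labels, self.domains + other.domains)

    def as_int(self) -> np.ndarray:
        """Labels as integer codes in sorted-class order (deterministic)."""
        lut = {c: k for k, c in enumerate(self.classes)}
        return np.asarray([lut[c] for c in self.labels], dtype=int)


@dataclass(frozen=True)
class PairWeights:
    """Same-class / different-class adjacency over N samples."""

    Q_same: np.ndarray
    Q_diff: np.ndarray

    def __post_init__(self):
        for name, Q in (("Q_same", self.Q_same), ("Q_diff", self.Q_diff)):
            if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(Q, Q.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")

    @property
    def n(self) -> int:
        return self.Q_same.shape[0]


@dataclass(frozen=True)
class LaplacianPair:
    """Graph Laplacians P = degree(Q) - Q for the same/different-class graphs."""

    P_same: np.ndarray
    P_diff: np.ndarray

    @property
    def n(self) -> int:
        return self.P_same.shape[0]


def build_pair_weights(labels: LabelVector, restrict_to_domain: Optional[str] = None) -> PairWeights:
    """Build the same-class and different-class pair-weight matrices.

    Entry (i, j), i != j, of ``Q_same`` is 1/|C| when samples i and j share a
    class, where |C| counts all ordered same-class pairs; ``Q_diff`` likewise
    with 1/|M| over ordered different-class pairs.  With
    ``restrict_to_domain`` only pairs within that domain are connected (the
    matrices keep the full N x N shape, rows of other-domain samples are
    zero), which is how per-domain graphs are built before block joining.
    """
    n = len(labels)
    if n == 0:
        raise ValueError("no samples")
    y = labels.as_int()
    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)
    diff = y[:, None] != y[None, :]
    if restrict_to_domain is not None:
        in_dom = np.asarray([d == restrict_to_domain for d in labels.domains])
        mask = in_dom[:, None] & in_dom[None, :]
        same &= mask
        diff &= mask
    n_same = int(same.sum())
    n_diff = int(diff.sum())
    Q_same = same.astype(float) / n_same if n_same else np.zeros((n, n))
    Q_diff = diff.astype(float) / n_diff if n_diff else np.zeros((n, n))
    return PairWeights(Q_same=Q_same, Q_diff=Q_diff)


def _laplacian(Q: np.ndarray) -> np.ndarray:
    if not np.allclose(Q, Q.T, atol=1e-12):
        raise ValueError("pair-weight matrix must be symmetric")
    return np.diag(Q.sum(axis=1)) - Q


def build_laplacian_pair(Q: PairWeights) -> LaplacianPair:
    """Laplacians P = Q~ - Q, with Q~ the diagonal degree matrix of Q."""
    return LaplacianPair(P_same=_laplacian(Q.Q_same), P_diff=_laplacian(Q.Q_diff))


def block_join(P_source: Optional[LaplacianPair], P_target: Optional[LaplacianPair]) -> LaplacianPair:
    """Join per-domain Laplacians block-diagonally (source block first).

    An empty (``None`` or size-0) domain is the identity case: the other
    domain's Laplacians are returned unchanged.  No cross-domain coupling is
    ever introduced.
    """

    def _empty(P: Optional[LaplacianPair]) -> bool:
        return P is None or P.n == 0

    if _empty(P_source) and _empty(P_target):
        raise ValueError("no samples")
    if _empty(P_target):
        return P_source  # type: ignore[return-value]
    if _empty(P_source):
        return P_target  # type: ignore[return-value]
    from scipy.linalg import block_diag

    return LaplacianPair(
        P_same=block_diag(P_source.P_same, P_target.P_same),
        P_diff=block_diag(P_source.P_diff, P_target.P_diff),
    )


def pairwise_penalty(Z: np.ndarray, Q: np.ndarray) -> float:
    """Sum_ij Q_ij ||z_i - z_j||^2 by explicit double loop.

    Brute-force pairwise form of the graph penalty; equal to 2 Tr(Z P Z^T)
    with P the Laplacian of Q.  Used as an independent oracle in tests and
    for objective reporting in the pairwise convention.
    """
    n = Z.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if Q[i, j] != 0.0:
                d = Z[:, i] - Z[:, j]
                total += Q[i, j] * float(d @ d)
    return total
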