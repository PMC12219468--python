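"""Activation pooling, principal-component bases, and subspace reconstruction.

The analysis treats each network layer as a set of latent dimensions obtained
by PCA: spatial structure is first removed by global max pooling, a PC basis is
fit on the large fit-set activations (centered on fit-set channel means,
retaining all components up to the numerical matrix rank), and the evaluation
set is projected into that basis.  Activations can also be reconstructed from a
subset of components, which is how a network is reduced to its most universal
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "ActivationSet",
    "PCBasis",
    "PCScores",
    "global_max_pool",
    "pool_activation_set",
    "fit_pc_basis",
    "project",
    "reconstruct_topk",
]

_EPS = np.finfo(np.float64).eps


@dataclass
class ActivationSet:
    """One network's layerwise activations over a named stimulus split.

    ``layers`` maps layer id to a ``stimuli x channels x spatial`` tensor (raw)
    or a ``stimuli x channels`` matrix (pooled); every layer must cover the same
    stimuli in the same order.
    """

    network_id: str
    layers: dict[str, np.ndarray]
    split: str = "all"

    def __post_init__(self) -> None:
        counts = {k: np.asarray(v).shape[0] for k, v in self.layers.items()}
        if len(set(counts.values())) > 1:
            raise ValueError(f"layers disagree on stimulus count: {counts}")

    @property
    def n_stimuli(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    def take(self, rows: slice | np.ndarray, split: str) -> "ActivationSet":
        """Row-subset every layer (e.g. restrict to the fit or eval split)."""
        return ActivationSet(
            network_id=self.network_id,
            layers={k: np.asarray(v)[rows] for k, v in self.layers.items()},
            split=split,
        )


def global_max_pool(raw: np.ndarray) -> np.ndarray:
    """Max over spatial positions per channel; identity on pooled input."""
    raw = np.asarray(raw)
    if raw.ndim == 2:
        return raw.copy()
    if raw.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D activations, got shape {raw.shape}")
    if raw.shape[2] < 1:
        raise ValueError("spatial axis must have length >= 1")
    return raw.max(axis=2)


def pool_activation_set(actset: ActivationSet) -> ActivationSet:
    """Apply global max pooling to every layer of an activation set."""
    return ActivationSet(
        network_id=actset.network_id,
        layers={k: global_max_pool(v) for k, v in actset.layers.items()},
        split=actset.split,
    )


@dataclass(frozen=True)
class PCBasis:
    """Principal-component basis of one layer's fit-set activations.

    ``loadings`` (channels x r) has orthonormal columns; ``variances`` are the
    corresponding eigenvalues of the fit-set covariance, in descending order.
    """

    layer_id: str
    channel_means: np.ndarray
    loadings: np.ndarray
    variances: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        L = self.loadings
        if L.shape[1] != self.rank or self.variances.shape != (self.rank,):
            raise ValueError("basis rank inconsistent with loadings/variances")
        if self.rank:
            if not np.allclose(L.T @ L, np.eye(self.rank), atol=1e-8):
                raise ValueError("loadings are not orthonormal")
            if np.any(np.diff(self.variances) > 1e-12) or self.variances[-1] < -1e-12:
                raise ValueError("variances must be non-increasing and nonnegative")


@dataclass(frozen=True)
class PCScores:
    """Projected coordinates of a stimulus set in a layer's PC basis."""

    layer_id: str
    scores: np.ndarray       # stimuli x r
    pc_rank: np.ndarray      # 1-based variance-order index per column

    def __post_init__(self) -> None:
        if self.scores.shape[1] != self.pc_rank.size:
            raise ValueError("pc_rank length must match score columns")
        expected = np.arange(1, self.pc_rank.size + 1)
        if not np.array_equal(self.pc_rank, expected):
            raise ValueError("pc_rank must be strictly increasing 1..r")


def fit_pc_basis(X_fit: np.ndarray, layer_id: str = "") -> PCBasis:
    """PCA of the column-mean-centered fit-set activations, kept to matrix rank.

    The retained component count is the numerical rank of the centered matrix
    under the conventional tolerance ``max(shape) * eps * s_max``.  All-constant
    input yields an empty (rank-0) basis rather than an error.
    """
    X_fit = np.asarray(X_fit, dtype=np.float64)
    if X_fit.ndim != 2 or X_fit.shape[0] < 2:
        raise ValueError("X_fit must be 2-D with at least 2 stimuli")
    means = X_fit.mean(axis=0)
    Xc = X_fit - means
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * _EPS * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    variances = s[:r] ** 2 / (X_fit.shape[0] - 1)
    return PCBasis(
        layer_id=layer_id,
        channel_means=means,
        loadings=Vt[:r].T.copy(),
        variances=variances,
        rank=r,
    )


def project(basis: PCBasis, X: np.ndarray) -> PCScores:
    """Project activations into a fitted basis: ``(X - fit means) . loadings``.

    No re-centering on X's own means — the fit-set channel means are the only
    statistic carried over, so evaluation-set projections never peek.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != basis.channel_means.size:
        raise ValueError(
            f"channel mismatch: X has {X.shape[1]}, basis expects "
            f"{basis.channel_means.size}"
        )
    scores = (X - basis.channel_means) @ basis.loadings
    return PCScores(
        layer_id=basis.layer_id,
        scores=scores,
        pc_rank=np.arange(1, basis.rank + 1),
    )


def reconstruct_topk(
    basis: PCBasis, scores: PCScores, keep: Iterable[int]
) -> np.ndarray:
    """Reconstruct activations from a subset of components (1-based PC ranks)."""
    keep = np.asarray(sorted(set(int(k) for k in keep)), dtype=np.intp)
    if keep.size and (keep.min() < 1 or keep.max() > basis.rank):
        raise IndexError(f"keep indices must lie in 1..{basis.rank}")
    idx = keep - 1
    n = scores.scores.shape[0]
    if idx.size == 0:
        return np.tile(basis.channel_means, (n, 1))
    return scores.scores[:, idx] @ basis.loadings[:, idx].T + basis.channel_means
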