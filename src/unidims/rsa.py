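"""Representational similarity analysis with universal-subspace reduction.

A network layer and a brain subject are compared by the Spearman correlation
between their representational dissimilarity matrices (RDMs; pairwise Pearson
correlation distances between stimulus response patterns).  Evaluation stimuli
are split into disjoint train/test halves: the layer with the best subject-
averaged train-set similarity is selected, and the reported similarity is
computed on the held-out test half.  The reduction analysis then reconstructs
the selected layer's test-set activations from only its top-k most universal
dimensions and recomputes the similarity, asking how much of the conventional
RSA outcome those few dimensions carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .activations import ActivationSet, PCBasis, PCScores, project, reconstruct_topk
from .inference import spearman

__all__ = [
    "RDM",
    "RSAResult",
    "split_train_test",
    "compute_rdm",
    "rdm_similarity",
    "run_rsa",
]


@dataclass(frozen=True)
class RDM:
    """Pearson-distance representational dissimilarity matrix."""

    labels: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        D = self.D
        n = self.labels.size
        if D.shape != (n, n):
            raise ValueError("D must be square and match labels")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if D.min() < -1e-10 or D.max() > 2 + 1e-10:
            raise ValueError("Pearson distances must lie in [0, 2]")


@dataclass
class RSAResult:
    """Layer selection and full/reduced test-set representational similarity."""

    per_layer_train_similarity: dict[str, float]
    selected_layer: str
    test_similarity_full: float
    test_similarity_reduced: dict[int, float]
    per_subject_full: np.ndarray
    per_subject_reduced: dict[int, np.ndarray]


def split_train_test(
    eval_stimuli: int | Sequence[int], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split evaluation stimuli into disjoint train/test halves.

    With an odd count the extra stimulus goes to the training half.
    """
    ids = (
        np.arange(eval_stimuli)
        if np.isscalar(eval_stimuli)
        else np.asarray(eval_stimuli)
    )
    if ids.size < 8:
        raise ValueError("need at least 8 stimuli to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    n_train = (ids.size + 1) // 2
    return np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])


def compute_rdm(X: np.ndarray, labels: np.ndarray | None = None) -> RDM:
    """RDM of a conditions x features matrix: D(i,j) = 1 - Pearson(row i, row j).

    Rows with zero variance have undefined correlations; their distance to
    every other condition is set to 1 (chance level) with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 features")
    labels = np.arange(X.shape[0]) if labels is None else np.asarray(labels)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance condition rows; "
            "their distances are set to 1"
        )
    safe = np.where(degenerate, 1.0, norms)
    C = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    D = 1.0 - np.clip(C, -1.0, 1.0)
    D[degenerate, :] = 1.0
    D[:, degenerate] = 1.0
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return RDM(labels=labels, D=D)


def rdm_similarity(a: RDM, b: RDM) -> float:
    """Spearman correlation of two RDMs over their strictly-lower triangles."""
    if not np.array_equal(a.labels, b.labels):
        raise ValueError("RDMs must share labels and label order")
    idx = np.tril_indices_from(a.D, k=-1)
    return spearman(a.D[idx], b.D[idx])


def run_rsa(
    bases: Mapping[str, PCBasis],
    scores_eval: Mapping[str, PCScores],
    universality: Mapping[str, np.ndarray],
    subjects: Sequence[np.ndarray],
    split: tuple[np.ndarray, np.ndarray],
    ks: Sequence[int] = (10, 5),
) -> RSAResult:
    """Train/test RSA of one network against brain subjects, full and reduced.

    ``bases``/``scores_eval`` give each layer's PC basis and evaluation-set
    projection (ordered shallow to deep); ``universality`` maps each layer to
    the universality score of its dimensions in PC-rank order.  ``subjects``
    are evaluation-set voxel matrices row-aligned with the projections.

    The best layer is chosen by subject-averaged train-half RDM similarity
    (ties broken toward the shallower layer); the full and top-k-reduced test
    similarities are computed on the held-out half.  The reduction keeps the k
    most universal dimensions *within the selected layer*; a k exceeding the
    layer rank is clamped with a warning.
    """
    train_ids, test_ids = split
    subj_train_rdms = [compute_rdm(np.asarray(V)[train_ids]) for V in subjects]
    subj_test_rdms = [compute_rdm(np.asarray(V)[test_ids]) for V in subjects]

    def layer_activations(layer_id: str) -> np.ndarray:
        basis, ps = bases[layer_id], scores_eval[layer_id]
        return reconstruct_topk(basis, ps, range(1, basis.rank + 1))

    per_layer: dict[str, float] = {}
    for lid in bases:
        rdm = compute_rdm(layer_activations(lid)[train_ids])
        per_layer[lid] = float(
            np.mean([rdm_similarity(rdm, s) for s in subj_train_rdms])
        )
    selected = max(per_layer, key=lambda lid: per_layer[lid])  # first max wins

    full_test = compute_rdm(layer_activations(selected)[test_ids])
    per_subject_full = np.array(
        [rdm_similarity(full_test, s) for s in subj_test_rdms]
    )

    basis, ps = bases[selected], scores_eval[selected]
    u = np.asarray(universality[selected], dtype=np.float64)
    if u.size != basis.rank:
        raise ValueError("universality vector must cover the layer's dimensions")
    reduced: dict[int, float] = {}
    per_subject_reduced: dict[int, np.ndarray] = {}
    for k in ks:
        kk = int(k)
        if kk > basis.rank:
            warnings.warn(f"k={kk} exceeds layer rank {basis.rank}; clamping")
            kk = basis.rank
        # Most-universal first; stable order on ties.
        top = np.argsort(-u, kind="mergesort")[:kk] + 1
        recon = reconstruct_topk(basis, ps, top)
        rdm = compute_rdm(recon[test_ids])
        per_subj = np.array([rdm_similarity(rdm, s) for s in subj_test_rdms])
        reduced[int(k)] = float(per_subj.mean())
        per_subject_reduced[int(k)] = per_subj

    return RSAResult(
        per_layer_train_similarity=per_layer,
        selected_layer=selected,
        test_similarity_full=float(per_subject_full.mean()),
        test_similarity_reduced=reduced,
        per_subject_full=per_subject_full,
        per_subject_reduced=per_subject_reduced,
    )
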