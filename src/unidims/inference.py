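"""Rank-correlation inference between universality and brain similarity.

The headline statistic is the Spearman correlation between the two dimension
metrics across all dimensions of a model set, with a partial variant that
controls for PC rank (high-variance components are expected to be more
universal, and the partialed statistic asks whether the relationship survives
beyond that).  Significance comes from a label-permutation test: evaluation
stimuli are shuffled before recomputing universality — with a single shared
permutation per target network, so dependencies among a network's dimensions
are preserved — and the observed correlation is compared with the resulting
null distribution under the add-one convention, so p is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .mapping import pearson_columns
from .metrics import DimensionScoringEngine

__all__ = [
    "InferenceResult",
    "spearman",
    "partial_spearman",
    "permutation_test",
    "run_inference",
]


@dataclass(frozen=True)
class InferenceResult:
    """Observed rank correlations and their permutation-based significance."""

    rho: float
    rho_partial: float
    p_value: float
    n_permutations: int
    seed: int
    null_rhos: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Ties receive average ranks.  If either side has zero rank variance the
    correlation is undefined and reported as 0 with a warning.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("zero rank variance; Spearman correlation set to 0")
        return 0.0
    return float(pearson_columns(rx, ry)[0])


def partial_spearman(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """Spearman correlation of x and y after partialing out a control variable.

    All three vectors are midrank-transformed; the ranked x and y are each
    residualized on the ranked control by least squares (with intercept) and
    the Pearson correlation of the residuals is returned.  A constant control
    degenerates to the plain Spearman correlation, with a warning.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    control = np.asarray(control, dtype=np.float64).ravel()
    if not (x.size == y.size == control.size) or x.size < 4:
        raise ValueError("need three equal-length vectors of length >= 4")
    if np.ptp(control) == 0:
        warnings.warn("constant control; returning plain Spearman correlation")
        return spearman(x, y)
    rx, ry, rc = rankdata(x), rankdata(y), rankdata(control)
    A = np.column_stack([np.ones_like(rc), rc])
    R = np.column_stack([rx, ry])
    coef, *_ = np.linalg.lstsq(A, R, rcond=None)
    resid = R - A @ coef
    # A variable fully explained by the control leaves only numerical residue.
    scale = np.linalg.norm(R - R.mean(axis=0), axis=0)
    resid_norm = np.linalg.norm(resid, axis=0)
    if np.any(resid_norm <= 1e-8 * np.where(scale > 0, scale, 1.0)):
        warnings.warn("zero residual variance; partial Spearman set to 0")
        return 0.0
    return float(pearson_columns(resid[:, 0], resid[:, 1])[0])


def permutation_test(
    engine: DimensionScoringEngine,
    targets: dict[str, np.ndarray],
    brain_similarity: np.ndarray,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """One-sided stimulus-label permutation test of the universality coupling.

    Each iteration draws one permutation of evaluation-stimulus indices per
    target network and applies it to *all* of that network's dimension series
    (preserving within-network dependence), recomputes every universality
    score against the unchanged predictors, and correlates the permuted
    universality vector with the observed (unpermuted) brain similarity.  The
    p-value is ``(1 + #{null rho >= observed rho}) / (n_perm + 1)``.

    Returns ``(p_value, null_rhos, observed_rho)``.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 (p floor would exceed 0.05)")
    order = list(targets)
    observed_u = engine.universality(targets)
    observed = np.concatenate([observed_u[nid] for nid in order])
    brain_similarity = np.asarray(brain_similarity, dtype=np.float64).ravel()
    if brain_similarity.size != observed.size:
        raise ValueError("brain_similarity length must match total dimensions")
    rho_obs = spearman(observed, brain_similarity)
    rng = np.random.default_rng(seed)
    n_stim = engine.plan.n_stimuli
    null_rhos = np.empty(n_perm)
    for it in range(n_perm):
        shuffled = {
            nid: targets[nid][rng.permutation(n_stim)] for nid in order
        }
        u_perm = engine.universality(shuffled)
        u_vec = np.concatenate([u_perm[nid] for nid in order])
        null_rhos[it] = spearman(u_vec, brain_similarity)
    p = (1.0 + np.sum(null_rhos >= rho_obs)) / (n_perm + 1.0)
    return float(p), null_rhos, float(rho_obs)


def run_inference(
    engine: DimensionScoringEngine,
    targets: dict[str, np.ndarray],
    universality: np.ndarray,
    brain_similarity: np.ndarray,
    pc_rank: np.ndarray,
    n_perm: int = 199,
    seed: int = 0,
) -> InferenceResult:
    """Observed Spearman, partial Spearman given PC rank, and permutation p."""
    rho = spearman(universality, brain_similarity)
    rho_partial = partial_spearman(universality, brain_similarity, pc_rank)
    p, null_rhos, _ = permutation_test(
        engine, targets, brain_similarity, n_perm=n_perm, seed=seed
    )
    return InferenceResult(
        rho=rho,
        rho_partial=rho_partial,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        null_rhos=null_rhos,
    )
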