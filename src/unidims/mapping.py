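"""Cross-validated linear mapping between feature spaces.

Implements the prediction backbone used by the universality and brain-similarity
metrics: nested cross-validated ridge regression (outer 5-fold evaluation, inner
leave-one-out penalty selection), plus two simpler mapping variants (ordinary
least squares, one-to-one column matching).

All fits handle the intercept by centering predictors and targets on training
means; the ridge penalty applies to slopes only.  Leave-one-out (LOO) residuals
are computed in closed form from the SVD of the centered training matrix via the
hat-matrix identity ``e_loo = e / (1 - h)``; for an unregularized fit that
exactly interpolates the training data (more columns than rows) the identity is
replaced by its analytic zero-penalty limit ``e_loo_i = [Kc^+ yc]_i / [Kc^+]_ii``
on the centered Gram matrix, which equals the minimum-norm refit.  Both forms
agree with explicit refitting to floating-point precision.

Degenerate correlations (a prediction or target with zero variance) are defined
as 0 rather than NaN so that fold averages stay well formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PenaltyGrid",
    "FoldPlan",
    "MappingScore",
    "FoldedRidgeDesign",
    "make_fold_plan",
    "ridge_fit_predict",
    "loo_select_penalty",
    "nested_cv_score",
    "ols_score",
    "one_to_one_score",
    "concat_predictor_layers",
    "pearson_columns",
]

_EPS = np.finfo(np.float64).eps


def pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation between paired columns of ``a`` and ``b``.

    Columns with zero variance on either side yield r = 0 (degenerate-case
    convention).  Accepts 1-D inputs, in which case a scalar array is returned.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64).T).T
    b = np.atleast_2d(np.asarray(b, dtype=np.float64).T).T
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = np.einsum("ij,ij->j", ac, bc)
    denom = np.linalg.norm(ac, axis=0) * np.linalg.norm(bc, axis=0)
    safe = denom > 0
    r = np.zeros(a.shape[1])
    r[safe] = num[safe] / denom[safe]
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class PenaltyGrid:
    """Ordered ridge-penalty candidates: zero plus log-spaced positive values.

    The default grid is {0} union {10^-3, 10^-2, ..., 10^4}: eight positive
    values with equal logarithmic spacing between the stated bounds.
    """

    values: tuple[float, ...] = field(
        default_factory=lambda: (0.0,) + tuple(10.0 ** np.arange(-3, 5))
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.size == 0 or np.any(v < 0):
            raise ValueError("penalty grid must be nonempty and nonnegative")
        pos = v[v > 0]
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positive penalties must be strictly increasing")
        object.__setattr__(self, "values", tuple(float(x) for x in v))


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of evaluation stimuli to outer cross-validation folds."""

    n_folds: int
    assignment: np.ndarray  # stimulus index -> fold label in [0, n_folds)
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.intp)
        object.__setattr__(self, "assignment", a)
        counts = np.bincount(a, minlength=self.n_folds)
        if len(counts) != self.n_folds or counts.min() == 0:
            raise ValueError("every fold must receive at least one stimulus")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def n_stimuli(self) -> int:
        return self.assignment.size


def make_fold_plan(n_stimuli: int, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Randomly partition ``n_stimuli`` into ``n_folds`` near-equal folds."""
    if n_stimuli < n_folds:
        raise ValueError(
            f"need at least {n_folds} stimuli for {n_folds} folds, got {n_stimuli}"
        )
    rng = np.random.default_rng(seed)
    labels = np.arange(n_stimuli) % n_folds
    assignment = labels[rng.permutation(n_stimuli)]
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=seed)


@dataclass(frozen=True)
class MappingScore:
    """Cross-validated prediction accuracy of one target dimension."""

    per_fold_r: np.ndarray
    mean_r: float
    chosen_penalty: np.ndarray
    method: Literal["ridge", "ols", "one_to_one"]


# ---------------------------------------------------------------------------
# SVD machinery shared by the standalone functions and the folded design cache
# ---------------------------------------------------------------------------


class _TrainStats:
    """SVD summary of one centered training matrix."""

    __slots__ = ("x_mean", "U", "s", "Vt", "U2", "cperp", "r0", "n")

    def __init__(self, X_train: np.ndarray):
        X_train = np.asarray(X_train, dtype=np.float64)
        self.n = X_train.shape[0]
        self.x_mean = X_train.mean(axis=0)
        Xc = X_train - self.x_mean
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # Truncate at the numerical rank: below-tolerance singular directions
        # are arbitrary completions whose left vectors can overlap span{1} and
        # corrupt the hat diagonal.
        tol = max(Xc.shape) * _EPS * (s[0] if s.size else 0.0)
        keep = s > tol
        self.U, self.s, self.Vt = U[:, keep], s[keep], Vt[keep]
        self.r0 = int(self.s.size)
        self.U2 = self.U**2
        self.cperp = np.clip(1.0 - 1.0 / self.n - self.U2.sum(axis=1), 0.0, None)

    def coef_factor(self, lam: float) -> np.ndarray:
        """Diagonal factor f(s) such that weights = V diag(f) U' yc."""
        if lam > 0:
            return self.s / (self.s**2 + lam)
        return 1.0 / self.s


def _loo_predictions(
    stats: _TrainStats,
    Y_train: np.ndarray,
    UtY: np.ndarray,
    lam: float,
    R_perp: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out predictions for every target column at penalty ``lam``.

    ``UtY`` is U' (Y_train - mean), precomputed once per training set;
    ``R_perp`` is the centered-target component outside col(U), hoisted by
    callers that sweep the penalty grid.
    """
    if R_perp is None:
        yc = Y_train - Y_train.mean(axis=0)
        R_perp = yc - stats.U @ UtY
    if lam > 0:
        alpha = lam / (stats.s**2 + lam)
        resid = stats.U @ (alpha[:, None] * UtY) + R_perp
        denom = stats.cperp + stats.U2 @ alpha
        return Y_train - resid / denom[:, None]
    # Unregularized least squares.
    resid = R_perp
    denom = stats.cperp
    if denom.min() > 1e-8:
        return Y_train - resid / denom[:, None]
    if denom.max() < 1e-8:
        # Exact interpolation (centered column space fills the centered row
        # space): zero-penalty limit of the ridge LOO identity, equivalently
        # the kernel form on the centered Gram matrix; equals the minimum-norm
        # refit.
        inv_s2 = 1.0 / stats.s**2
        resid = stats.U @ (inv_s2[:, None] * UtY)
        denom = stats.U2 @ inv_s2
        return Y_train - resid / denom[:, None]
    # Mixed near-singular case: explicit refits for the offending rows.
    safe = np.where(denom > 1e-8, denom, 1.0)
    preds = Y_train - resid / safe[:, None]
    X_rot = stats.U * stats.s  # rotated copy of centered X; identical fits
    for i in np.flatnonzero(denom <= 1e-8):
        mask = np.ones(stats.n, dtype=bool)
        mask[i] = False
        preds[i] = ridge_fit_predict(X_rot[mask], Y_train[mask], X_rot[i : i + 1], lam)[0]
    return preds


def _loo_criterion(
    stats: _TrainStats,
    Y_train: np.ndarray,
    UtY: np.ndarray,
    grid: PenaltyGrid,
    criterion: str,
) -> np.ndarray:
    """Score every (penalty, target) pair by LOO performance; higher is better."""
    if criterion not in ("pearson", "mse"):
        raise ValueError(f"unknown inner-loop criterion {criterion!r}")
    vals = np.asarray(grid.values)
    n, T = Y_train.shape
    out = np.empty((vals.size, T))
    yc = Y_train - Y_train.mean(axis=0)
    R_perp = yc - stats.U @ UtY
    # Batch all positive penalties into one GEMM: the per-penalty residual is
    # U (alpha_k * UtY) + R_perp, so stack the scaled UtY blocks column-wise.
    pos = np.flatnonzero(vals > 0)
    loo_by_lam: dict[int, np.ndarray] = {}
    if pos.size:
        A = vals[pos, None] / (stats.s[None, :] ** 2 + vals[pos, None])  # K x r
        stacked = (A[:, :, None] * UtY[None]).transpose(1, 0, 2).reshape(
            stats.s.size, pos.size * T
        )
        E = (stats.U @ stacked).reshape(n, pos.size, T)
        denoms = stats.cperp[:, None] + stats.U2 @ A.T  # n x K
        for j, k in enumerate(pos):
            loo_by_lam[k] = Y_train - (E[:, j, :] + R_perp) / denoms[:, j, None]
    for k in np.flatnonzero(vals == 0):
        loo_by_lam[k] = _loo_predictions(stats, Y_train, UtY, 0.0, R_perp=R_perp)
    for k in range(vals.size):
        loo = loo_by_lam[k]
        if criterion == "pearson":
            out[k] = pearson_columns(loo, Y_train)
        else:
            out[k] = -np.mean((loo - Y_train) ** 2, axis=0)
    return out


def ridge_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    penalty: float,
) -> np.ndarray:
    """Fit ridge regression (intercept via centering) and predict on ``X_test``.

    ``penalty=0`` reduces to least squares, minimum-norm when rank deficient.
    ``y_train`` may be a vector or a (stimuli x targets) matrix.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    y_train = np.asarray(y_train, dtype=np.float64)
    squeeze = y_train.ndim == 1
    Y = y_train[:, None] if squeeze else y_train
    stats = _TrainStats(X_train)
    y_mean = Y.mean(axis=0)
    UtY = stats.U.T @ (Y - y_mean)
    f = stats.coef_factor(penalty)
    G = (np.asarray(X_test, dtype=np.float64) - stats.x_mean) @ stats.Vt.T
    pred = G @ (f[:, None] * UtY) + y_mean
    return pred[:, 0] if squeeze else pred


def loo_select_penalty(
    X: np.ndarray,
    y: np.ndarray,
    grid: PenaltyGrid | None = None,
    criterion: str = "pearson",
) -> float:
    """Pick the penalty whose leave-one-out predictions best match ``y``.

    The default criterion maximizes the Pearson correlation between the LOO
    predicted series and the target, matching the outer evaluation metric;
    ``criterion="mse"`` minimizes the LOO squared error instead.  A target with
    zero variance is flagged and assigned the smallest grid value.
    """
    grid = grid or PenaltyGrid()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for leave-one-out selection")
    if np.ptp(y) == 0:
        warnings.warn("zero-variance target; returning smallest penalty")
        return min(grid.values)
    stats = _TrainStats(X)
    Y = y[:, None]
    UtY = stats.U.T @ (Y - Y.mean(axis=0))
    scores = _loo_criterion(stats, Y, UtY, grid, criterion)[:, 0]
    order = np.argsort(grid.values)  # ties resolved toward the smaller penalty
    best = order[np.argmax(scores[order])]
    return grid.values[best]


class FoldedRidgeDesign:
    """Per-fold SVD cache for scoring many targets against one predictor matrix.

    Building the design factors the centered training matrix of every outer
    fold once; scoring a block of target columns then costs only matrix
    products.  This is what makes permutation tests (which rescore permuted
    targets thousands of times against unchanged predictors) tractable.
    """

    def __init__(
        self,
        X: np.ndarray,
        plan: FoldPlan,
        grid: PenaltyGrid | None = None,
        criterion: str = "pearson",
        fixed_penalty: float | None = None,
    ):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("predictor matrix must be 2-D (stimuli x features)")
        if X.shape[0] != plan.n_stimuli:
            raise ValueError("predictor rows must align with the fold plan")
        self.plan = plan
        self.grid = grid or PenaltyGrid()
        self.criterion = criterion
        self.fixed_penalty = fixed_penalty
        self._folds = []
        for f in range(plan.n_folds):
            te = plan.assignment == f
            tr = ~te
            stats = _TrainStats(X[tr])
            G_test = (X[te] - stats.x_mean) @ stats.Vt.T
            self._folds.append((tr, te, stats, G_test))

    def _fold_predictions(self, Y: np.ndarray, fold) -> tuple[np.ndarray, np.ndarray]:
        """Held-out predictions and chosen penalties for one outer fold."""
        tr, te, stats, G_test = fold
        Ytr = Y[tr]
        y_mean = Ytr.mean(axis=0)
        UtY = stats.U.T @ (Ytr - y_mean)
        grid_vals = np.asarray(self.grid.values)
        if self.fixed_penalty is not None:
            lam_of_target = np.full(Y.shape[1], self.fixed_penalty)
        else:
            crit = _loo_criterion(stats, Ytr, UtY, self.grid, self.criterion)
            order = np.argsort(grid_vals)
            best = order[np.argmax(crit[order], axis=0)]
            lam_of_target = grid_vals[best]
            degenerate = np.ptp(Ytr, axis=0) == 0
            lam_of_target[degenerate] = grid_vals.min()
        preds = np.empty((int(te.sum()), Y.shape[1]))
        for lam in np.unique(lam_of_target):
            cols = lam_of_target == lam
            f_diag = stats.coef_factor(float(lam))
            preds[:, cols] = G_test @ (f_diag[:, None] * UtY[:, cols]) + y_mean[cols]
        return preds, lam_of_target

    def score(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Score every target column.

        Returns ``(mean_r, per_fold_r, chosen_penalty)`` with shapes
        ``(T,)``, ``(n_folds, T)`` and ``(n_folds, T)``.
        """
        Y = np.atleast_2d(np.asarray(Y, dtype=np.float64).T).T
        if Y.shape[0] != self.plan.n_stimuli:
            raise ValueError("target rows must align with the fold plan")
        per_fold = np.empty((self.plan.n_folds, Y.shape[1]))
        chosen = np.empty_like(per_fold)
        for k, fold in enumerate(self._folds):
            preds, lam = self._fold_predictions(Y, fold)
            per_fold[k] = pearson_columns(preds, Y[fold[1]])
            chosen[k] = lam
        return per_fold.mean(axis=0), per_fold, chosen

    def predict(self, Y: np.ndarray) -> np.ndarray:
        """Assembled cross-validated predicted series, row-aligned with ``Y``."""
        Y = np.atleast_2d(np.asarray(Y, dtype=np.float64).T).T
        out = np.empty_like(Y)
        for fold in self._folds:
            preds, _ = self._fold_predictions(Y, fold)
            out[fold[1]] = preds
        return out


def nested_cv_score(
    X: np.ndarray,
    y: np.ndarray,
    plan: FoldPlan,
    grid: PenaltyGrid | None = None,
    criterion: str = "pearson",
) -> MappingScore:
    """Nested cross-validated ridge score of one target dimension.

    Outer loop: the plan's folds, each held out once.  Inner loop: leave-one-out
    penalty selection on the remaining folds.  Performance is the Pearson
    correlation between held-out predictions and the target, averaged over
    folds.
    """
    design = FoldedRidgeDesign(X, plan, grid, criterion)
    mean_r, per_fold, chosen = design.score(y)
    return MappingScore(
        per_fold_r=per_fold[:, 0],
        mean_r=float(mean_r[0]),
        chosen_penalty=chosen[:, 0],
        method="ridge",
    )


def ols_score(X: np.ndarray, y: np.ndarray, plan: FoldPlan) -> MappingScore:
    """Cross-validated ordinary least squares (no regularization, no inner loop)."""
    design = FoldedRidgeDesign(X, plan, fixed_penalty=0.0)
    mean_r, per_fold, chosen = design.score(y)
    return MappingScore(
        per_fold_r=per_fold[:, 0],
        mean_r=float(mean_r[0]),
        chosen_penalty=chosen[:, 0],
        method="ols",
    )


def one_to_one_mean_r(
    X: np.ndarray, Y: np.ndarray, plan: FoldPlan
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-to-one mapping score for every target column.

    Per fold the predictor column with the highest (signed) training Pearson
    correlation with the target is selected; the fold score is the test-fold
    correlation between that column and the target.  Constant training columns
    are excluded; if none remain the fold scores 0.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64).T).T
    per_fold = np.zeros((plan.n_folds, Y.shape[1]))
    for f in range(plan.n_folds):
        te = plan.assignment == f
        tr = ~te
        Xtr, Ytr = X[tr], Y[tr]
        xc = Xtr - Xtr.mean(axis=0)
        yc = Ytr - Ytr.mean(axis=0)
        xn = np.linalg.norm(xc, axis=0)
        yn = np.linalg.norm(yc, axis=0)
        valid = xn > 0
        if not valid.any():
            continue
        corr = np.full((X.shape[1], Y.shape[1]), -np.inf)
        denom = np.outer(np.where(valid, xn, 1.0), np.where(yn > 0, yn, 1.0))
        corr[valid] = ((xc.T @ yc) / denom)[valid]
        best = np.argmax(corr, axis=0)
        per_fold[f] = pearson_columns(X[np.ix_(te, best)], Y[te])
    return per_fold.mean(axis=0), per_fold


def one_to_one_score(X: np.ndarray, y: np.ndarray, plan: FoldPlan) -> MappingScore:
    """One-to-one mapping score of a single target dimension."""
    if X.shape[1] < 1:
        raise ValueError("predictor matrix needs at least one column")
    mean_r, per_fold = one_to_one_mean_r(X, y, plan)
    return MappingScore(
        per_fold_r=per_fold[:, 0],
        mean_r=float(mean_r[0]),
        chosen_penalty=np.full(plan.n_folds, np.nan),
        method="one_to_one",
    )


def concat_predictor_layers(network) -> np.ndarray:
    """Concatenate a network's pooled layers column-wise, in layer order."""
    blocks = []
    for layer_id, arr in network.layers.items():
        if np.asarray(arr).ndim != 2:
            raise ValueError(
                f"layer {layer_id!r} is not pooled; apply global_max_pool first"
            )
        blocks.append(np.asarray(arr, dtype=np.float64))
    if not blocks:
        raise ValueError("network has no layers")
    return np.hstack(blocks)
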