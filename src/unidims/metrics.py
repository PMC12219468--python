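"""Dimension-level summary metrics: universality and brain similarity.

For each latent dimension d of a target network (one PC of one layer,
evaluated on the shared evaluation stimuli):

* ``universality(d) = median(r_d1, ..., r_dm)`` — the median cross-validated
  predictability of d from the concatenated layer activations of each of the m
  other networks in the set.  The median keeps the summary from being driven by
  a few predictor networks with extreme scores.
* ``brain_similarity(d) = mean(r_d1, ..., r_dn)`` — the mean cross-validated
  predictability of d from each of the n subjects' voxel responses.

Both r's come from the nested cross-validated ridge in :mod:`unidims.mapping`
(or the OLS / one-to-one variants).  A between-subject reliability of each
dimension — the mean pairwise correlation of subjects' cross-validated
predicted series — upper-bounds attainable brain similarity and supports an
attenuation-style adjustment.  Quantile binning summarizes the joint
distribution of the two metrics the way the scatter summaries do.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .activations import ActivationSet, PCScores
from .mapping import (
    FoldPlan,
    FoldedRidgeDesign,
    PenaltyGrid,
    concat_predictor_layers,
    one_to_one_mean_r,
    pearson_columns,
)

__all__ = [
    "DimensionRecord",
    "ScoreTable",
    "DimensionScoringEngine",
    "universality_score",
    "brain_similarity_score",
    "between_subject_reliability",
    "reliability_adjust",
    "quantile_bin_means",
]


@dataclass
class DimensionRecord:
    """Scores of one latent dimension (network, layer, 1-based PC rank)."""

    network_id: str
    layer_id: str
    pc_rank: int
    per_predictor_r: np.ndarray
    universality: float
    per_subject_r: np.ndarray
    brain_similarity: float
    reliability: float | None = None
    adjusted_brain_similarity: float | None = None

    def __post_init__(self) -> None:
        self.per_predictor_r = np.asarray(self.per_predictor_r, dtype=np.float64)
        self.per_subject_r = np.asarray(self.per_subject_r, dtype=np.float64)
        if self.per_predictor_r.size and not np.isclose(
            self.universality, float(np.median(self.per_predictor_r))
        ):
            raise ValueError("universality must equal median(per_predictor_r)")
        if self.per_subject_r.size and not np.isclose(
            self.brain_similarity, float(np.mean(self.per_subject_r))
        ):
            raise ValueError("brain_similarity must equal mean(per_subject_r)")


@dataclass
class ScoreTable:
    """All dimension records of one model set, keyed by (network, layer, rank)."""

    records: list[DimensionRecord]
    model_set: str = "custom"

    def __post_init__(self) -> None:
        keys = [(r.network_id, r.layer_id, r.pc_rank) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("(network_id, layer_id, pc_rank) must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame; per-predictor/subject r lists become columns."""
        rows = []
        for r in self.records:
            row = {
                "network_id": r.network_id,
                "layer_id": r.layer_id,
                "pc_rank": r.pc_rank,
                "universality": r.universality,
                "brain_similarity": r.brain_similarity,
                "reliability": np.nan if r.reliability is None else r.reliability,
                "adjusted_brain_similarity": (
                    np.nan
                    if r.adjusted_brain_similarity is None
                    else r.adjusted_brain_similarity
                ),
            }
            row.update(
                {f"r_pred_{i}": v for i, v in enumerate(r.per_predictor_r)}
            )
            row.update({f"r_subj_{i}": v for i, v in enumerate(r.per_subject_r)})
            rows.append(row)
        return pd.DataFrame(rows)


def universality_score(
    target: np.ndarray,
    predictors: Sequence[ActivationSet],
    plan: FoldPlan,
    grid: PenaltyGrid | None = None,
) -> tuple[np.ndarray, float]:
    """Universality of one dimension: median nested-CV r over predictor networks.

    ``target`` is the dimension's evaluation-set score series; ``predictors``
    are the pooled activation sets of every *other* network (the target network
    must not appear among them).
    """
    if not predictors:
        raise ValueError("need at least one predictor network")
    rs = []
    for net in predictors:
        design = FoldedRidgeDesign(concat_predictor_layers(net), plan, grid)
        mean_r, _, _ = design.score(target)
        rs.append(float(mean_r[0]))
    per_predictor = np.asarray(rs)
    return per_predictor, float(np.median(per_predictor))


def brain_similarity_score(
    target: np.ndarray,
    subjects: Sequence[np.ndarray],
    plan: FoldPlan,
    grid: PenaltyGrid | None = None,
) -> tuple[np.ndarray, float]:
    """Brain similarity of one dimension: mean nested-CV r over subjects."""
    if not subjects:
        raise ValueError("need at least one subject")
    rs = []
    for V in subjects:
        design = FoldedRidgeDesign(np.asarray(V), plan, grid)
        mean_r, _, _ = design.score(target)
        rs.append(float(mean_r[0]))
    per_subject = np.asarray(rs)
    return per_subject, float(np.mean(per_subject))


def between_subject_reliability(
    target: np.ndarray,
    subjects: Sequence[np.ndarray],
    plan: FoldPlan,
    grid: PenaltyGrid | None = None,
) -> float | None:
    """Consistency of a dimension's prediction across subjects.

    Each subject yields a cross-validated predicted series for the target; the
    reliability is the mean pairwise Pearson correlation between those series,
    clamped to [0, 1].  It upper-bounds how brain-predictable the dimension can
    be given subject-level noise.  Undefined (None) with fewer than 2 subjects.
    """
    if len(subjects) < 2:
        return None
    preds = [
        FoldedRidgeDesign(np.asarray(V), plan, grid).predict(target)[:, 0]
        for V in subjects
    ]
    pair_rs = [
        float(pearson_columns(preds[i], preds[j])[0])
        for i, j in combinations(range(len(preds)), 2)
    ]
    return float(np.clip(np.mean(pair_rs), 0.0, 1.0))


def reliability_adjust(
    record: DimensionRecord,
    floor: float = 0.1,
    mode: Literal["sqrt", "linear"] = "sqrt",
) -> float | None:
    """Attenuation-corrected brain similarity: divide by sqrt(reliability).

    Records with missing reliability, or reliability at or below ``floor``, are
    excluded (None) rather than divided by a noisy small number.  ``mode=
    "linear"`` divides by the reliability itself instead of its square root.
    """
    rel = record.reliability
    if rel is None or rel <= floor:
        return None
    denom = np.sqrt(rel) if mode == "sqrt" else rel
    return float(record.brain_similarity / denom)


def quantile_bin_means(
    table: ScoreTable | pd.DataFrame, bin_size: int = 100
) -> list[tuple[float, float]]:
    """Mean (universality, brain similarity) in consecutive universality bins.

    Records are sorted by universality ascending and grouped into bins of
    exactly ``bin_size``; a final partial bin is dropped so every bin is an
    equally sized quantile.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    frame = table.to_frame() if isinstance(table, ScoreTable) else table
    if frame.empty:
        raise ValueError("score table is empty")
    df = frame.sort_values("universality", kind="mergesort").reset_index(drop=True)
    n_bins = len(df) // bin_size
    out = []
    for b in range(n_bins):
        chunk = df.iloc[b * bin_size : (b + 1) * bin_size]
        out.append(
            (float(chunk["universality"].mean()), float(chunk["brain_similarity"].mean()))
        )
    return out


class DimensionScoringEngine:
    """Scores every dimension of every network against cached predictor designs.

    Folding each predictor network's concatenated layers (and each subject's
    voxel matrix) into a :class:`FoldedRidgeDesign` once makes repeated scoring
    — in particular the label-permutation null, which rescores shuffled targets
    hundreds of times — cheap.
    """

    def __init__(
        self,
        networks: dict[str, ActivationSet],
        subjects: Sequence[np.ndarray],
        plan: FoldPlan,
        grid: PenaltyGrid | None = None,
    ):
        self.plan = plan
        self.grid = grid or PenaltyGrid()
        self.network_ids = list(networks)
        self._net_designs = {
            nid: FoldedRidgeDesign(concat_predictor_layers(net), plan, self.grid)
            for nid, net in networks.items()
        }
        self._subj_designs = [
            FoldedRidgeDesign(np.asarray(V), plan, self.grid) for V in subjects
        ]
        self._net_X = {
            nid: concat_predictor_layers(net) for nid, net in networks.items()
        }

    def universality(
        self, targets: dict[str, np.ndarray], method: str = "ridge"
    ) -> dict[str, np.ndarray]:
        """Universality of every target column, per network.

        ``targets`` maps network id to its (eval stimuli x dimensions) PC-score
        matrix.  ``method`` selects the mapping: nested-CV ridge (default),
        plain cross-validated OLS, or one-to-one column matching.
        """
        out = {}
        for nid, Y in targets.items():
            rs = []
            for pid in self.network_ids:
                if pid == nid:
                    continue
                if method == "ridge":
                    mean_r, _, _ = self._net_designs[pid].score(Y)
                elif method == "ols":
                    design = FoldedRidgeDesign(
                        self._net_X[pid], self.plan, fixed_penalty=0.0
                    )
                    mean_r, _, _ = design.score(Y)
                elif method == "one_to_one":
                    mean_r, _ = one_to_one_mean_r(self._net_X[pid], Y, self.plan)
                else:
                    raise ValueError(f"unknown mapping method {method!r}")
                rs.append(mean_r)
            out[nid] = np.median(np.vstack(rs), axis=0)
        return out

    def per_predictor_r(self, nid: str, Y: np.ndarray) -> np.ndarray:
        """(m predictors x dimensions) ridge scores for one target network."""
        rs = [
            self._net_designs[pid].score(Y)[0]
            for pid in self.network_ids
            if pid != nid
        ]
        return np.vstack(rs)

    def per_subject_r(self, Y: np.ndarray) -> np.ndarray:
        """(n subjects x dimensions) ridge scores from each subject's voxels."""
        if not self._subj_designs:
            raise ValueError("engine was built without subjects")
        return np.vstack([d.score(Y)[0] for d in self._subj_designs])

    def subject_predictions(self, Y: np.ndarray) -> list[np.ndarray]:
        """Per subject, the cross-validated predicted series of every target."""
        return [d.predict(Y) for d in self._subj_designs]

    def score_table(
        self,
        targets: dict[str, PCScoresByLayer],
        model_set: str = "custom",
        with_reliability: bool = False,
        reliability_floor: float = 0.1,
    ) -> ScoreTable:
        """Build the full dimension-by-dimension score table.

        ``targets`` maps network id to an ordered ``{layer_id: PCScores}`` of
        evaluation-set projections.
        """
        records: list[DimensionRecord] = []
        for nid, layers in targets.items():
            Y = np.hstack([ps.scores for ps in layers.values()])
            meta = [
                (lid, int(rank))
                for lid, ps in layers.items()
                for rank in ps.pc_rank
            ]
            pred_r = self.per_predictor_r(nid, Y)
            subj_r = self.per_subject_r(Y)
            rel = np.full(Y.shape[1], np.nan)
            if with_reliability and len(self._subj_designs) >= 2:
                preds = self.subject_predictions(Y)
                pair_sum = np.zeros(Y.shape[1])
                n_pairs = 0
                for i, j in combinations(range(len(preds)), 2):
                    pair_sum += pearson_columns(preds[i], preds[j])
                    n_pairs += 1
                rel = np.clip(pair_sum / n_pairs, 0.0, 1.0)
            for d, (lid, rank) in enumerate(meta):
                rec = DimensionRecord(
                    network_id=nid,
                    layer_id=lid,
                    pc_rank=rank,
                    per_predictor_r=pred_r[:, d],
                    universality=float(np.median(pred_r[:, d])),
                    per_subject_r=subj_r[:, d],
                    brain_similarity=float(np.mean(subj_r[:, d])),
                    reliability=None if np.isnan(rel[d]) else float(rel[d]),
                )
                rec.adjusted_brain_similarity = reliability_adjust(
                    rec, floor=reliability_floor
                )
                records.append(rec)
        return ScoreTable(records=records, model_set=model_set)


# Ordered mapping layer_id -> PCScores for one network's evaluation projections.
PCScoresByLayer = dict[str, PCScores]
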