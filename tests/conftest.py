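"""Shared fixtures: pre-assembled simulated worlds at two scales.

The session-scoped ``aligned`` fixture runs the expensive front half of the
analysis once on the standard aligned world (6 networks x 3 layers x 60
channels, 600 fit / 200 eval stimuli, 4 subjects) and exposes the scored
quantities every downstream test needs.  Smaller worlds are built per-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from unidims import WorldConfig
from unidims.pipeline import build_analysis
from unidims.world import population_shared_fraction


@dataclass
class AlignedWorldScores:
    state: object
    universality: np.ndarray          # ridge, concatenated in target order
    universality_by_net: dict
    brain_similarity: np.ndarray
    pc_rank: np.ndarray
    shared_fraction: np.ndarray       # population ground truth per dimension


@pytest.fixture(scope="session")
def aligned() -> AlignedWorldScores:
    """Scored aligned world at the standard scale (seed 0, fold seed 0)."""
    cfg = WorldConfig(seed=0)
    state = build_analysis(cfg, fold_seed=0)
    u_by_net = state.engine.universality(state.targets)
    u = np.concatenate([u_by_net[nid] for nid in state.targets])
    bsim = np.concatenate(
        [state.engine.per_subject_r(state.targets[nid]).mean(axis=0)
         for nid in state.targets]
    )
    pc_rank = np.concatenate(
        [
            np.arange(1, state.bases[nid][lid].rank + 1)
            for nid in state.targets
            for lid in state.bases[nid]
        ]
    ).astype(float)
    frac = np.concatenate(
        [
            population_shared_fraction(
                state.world, i, l, state.bases[f"net{i}"][f"layer{l}"].loadings
            )
            for i in range(cfg.n_networks)
            for l in range(cfg.n_layers)
        ]
    )
    return AlignedWorldScores(
        state=state,
        universality=u,
        universality_by_net=u_by_net,
        brain_similarity=bsim,
        pc_rank=pc_rank,
        shared_fraction=frac,
    )


@pytest.fixture(scope="session")
def tiny_aligned():
    """Small aligned world for fast integration tests (3 nets x 2 layers)."""
    cfg = WorldConfig(
        n_stim_fit=150, n_stim_eval=60, n_networks=3, n_layers=2,
        n_channels=15, n_universal=3, n_idio=4, n_subjects=2, n_voxels=40,
        seed=0,
    )
    return build_analysis(cfg, fold_seed=0)
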