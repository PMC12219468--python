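"""Rank correlations and the stimulus-label permutation test."""

import numpy as np
import pytest

from unidims import WorldConfig
from unidims.inference import partial_spearman, permutation_test, spearman
from unidims.mapping import FoldedRidgeDesign, concat_predictor_layers
from unidims.pipeline import build_analysis


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------


def midranks(x):
    """Average ranks with ties, by explicit sorting (oracle helper)."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def pearson_formula(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    num = n * (a * b).sum() - a.sum() * b.sum()
    den = np.sqrt(n * (a**2).sum() - a.sum() ** 2) * np.sqrt(
        n * (b**2).sum() - b.sum() ** 2
    )
    return num / den


# --------------------------------------------------------------------------
# Spearman
# --------------------------------------------------------------------------


def test_spearman_rank_invariance_and_reversal():
    x = np.array([0.1, 1.2, 2.0, 3.5, 7.0])
    assert spearman(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)


def test_spearman_ties_match_midrank_oracle():
    x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
    y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0])
    want = pearson_formula(midranks(x), midranks(y))
    assert spearman(x, y) == pytest.approx(want, abs=1e-12)


def test_spearman_degenerate_input():
    with pytest.warns(UserWarning):
        assert spearman(np.ones(5), np.arange(5.0)) == 0.0
    with pytest.raises(ValueError):
        spearman([1, 2], [3, 4])


# --------------------------------------------------------------------------
# partial Spearman
# --------------------------------------------------------------------------


def test_partial_spearman_perfect_residualization():
    rng = np.random.default_rng(0)
    control = rng.standard_normal(50)
    x = control + 0.5 * rng.standard_normal(50)
    # y carries only control information -> partial correlation ~0
    with pytest.warns(UserWarning, match="zero residual"):
        assert abs(partial_spearman(x, control, control)) < 1e-8


def test_partial_spearman_closed_form_oracle():
    """Fixed 12-point triple: residual method equals the closed form
    (rxy - rxz*ryz) / sqrt((1-rxz^2)(1-ryz^2)) applied to midranks."""
    rng = np.random.default_rng(1)
    z = rng.standard_normal(12)
    x = 0.8 * z + rng.standard_normal(12)
    y = 0.5 * z + rng.standard_normal(12)
    rx, ry, rz = midranks(x), midranks(y), midranks(z)
    rxy = pearson_formula(rx, ry)
    rxz = pearson_formula(rx, rz)
    ryz = pearson_formula(ry, rz)
    want = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    assert partial_spearman(x, y, z) == pytest.approx(want, abs=1e-10)


def test_partial_spearman_independent_control_changes_little():
    """Control independent of both variables: partial ~ plain (100 seeds)."""
    deltas = []
    for s in range(100):
        rng = np.random.default_rng(40_000 + s)
        x = rng.standard_normal(300)
        y = 0.5 * x + rng.standard_normal(300)
        z = rng.standard_normal(300)
        deltas.append(abs(partial_spearman(x, y, z) - spearman(x, y)))
    assert np.mean(deltas) < 0.02 and max(deltas) < 0.05


def test_partial_spearman_constant_control_degenerates():
    x = np.arange(10.0)
    y = x**2
    with pytest.warns(UserWarning, match="constant control"):
        assert partial_spearman(x, y, np.ones(10)) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# permutation test
# --------------------------------------------------------------------------


def _tiny_state():
    cfg = WorldConfig(
        n_stim_fit=100, n_stim_eval=40, n_networks=3, n_layers=1,
        n_channels=8, n_universal=2, n_idio=2, n_subjects=2, n_voxels=20,
        seed=4,
    )
    return build_analysis(cfg)


def test_permutation_p_floor_and_bounds():
    st = _tiny_state()
    bsim = np.concatenate(
        [st.engine.per_subject_r(st.targets[k]).mean(axis=0) for k in st.targets]
    )
    p, null, rho = permutation_test(st.engine, st.targets, bsim, n_perm=19, seed=0)
    assert 1 / 20 <= p <= 1.0
    assert null.size == 19
    if rho > null.max():  # strong aligned coupling: observed tops every draw
        assert p == pytest.approx(1 / 20)
    with pytest.raises(ValueError):
        permutation_test(st.engine, st.targets, bsim, n_perm=10, seed=0)


def test_permutation_matches_reference_implementation():
    """Fixed tiny world: the engine-cached test equals a naive reference that
    rebuilds the predictor designs and applies one shared permutation per
    network each iteration."""
    st = _tiny_state()
    bsim = np.concatenate(
        [st.engine.per_subject_r(st.targets[k]).mean(axis=0) for k in st.targets]
    )
    n_perm, seed = 99, 5
    p_got, null_got, rho_got = permutation_test(
        st.engine, st.targets, bsim, n_perm=n_perm, seed=seed
    )

    designs = {
        nid: FoldedRidgeDesign(
            concat_predictor_layers(st.pooled_eval[nid]), st.plan
        )
        for nid in st.targets
    }

    def reference_universality(targets):
        out = []
        for nid in targets:
            rs = [
                designs[pid].score(targets[nid])[0]
                for pid in targets
                if pid != nid
            ]
            out.append(np.median(np.vstack(rs), axis=0))
        return np.concatenate(out)

    rho_obs = spearman(reference_universality(st.targets), bsim)
    rng = np.random.default_rng(seed)
    n = st.plan.n_stimuli
    null_ref = np.empty(n_perm)
    for it in range(n_perm):
        shuffled = {
            nid: st.targets[nid][rng.permutation(n)] for nid in st.targets
        }
        null_ref[it] = spearman(reference_universality(shuffled), bsim)
    p_ref = (1 + np.sum(null_ref >= rho_obs)) / (n_perm + 1)

    assert rho_got == pytest.approx(rho_obs, abs=1e-12)
    assert np.allclose(null_got, null_ref, atol=1e-12)
    assert p_got == pytest.approx(p_ref, abs=1e-12)


def test_aligned_world_coupling_is_significant(tiny_aligned):
    """Aligned world: positive rank coupling with small permutation p."""
    st = tiny_aligned
    bsim = np.concatenate(
        [st.engine.per_subject_r(st.targets[k]).mean(axis=0) for k in st.targets]
    )
    u = np.concatenate(list(st.engine.universality(st.targets).values()))
    rho = spearman(u, bsim)
    assert rho > 0.4
    p, _, _ = permutation_test(st.engine, st.targets, bsim, n_perm=99, seed=0)
    assert p <= 0.05
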