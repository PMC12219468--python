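"""Latent-factor simulation of networks and brain subjects.

The generator builds a world in which several "networks" observe the same
stimuli through noisy nonnegative-or-linear mixtures of two kinds of latent
dimensions: *universal* latents shared by every network, and *idiosyncratic*
latents private to each network.  Simulated brain "subjects" mix a configurable
subset of the universal latents (the aligned world) or an independent latent
set (the null world) into voxel responses that are then column-standardized,
emulating session z-scored betas.

Stimuli are generated jointly for a large fit split (used to estimate PC bases)
and a smaller evaluation split (used for all metrics), and split
deterministically by index.  Everything is reproducible bit-for-bit from the
configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Literal

import numpy as np

from .activations import ActivationSet

__all__ = [
    "WorldConfig",
    "LatentWorld",
    "make_latents",
    "make_network",
    "make_brain",
    "make_null_world",
    "shared_variance_fraction",
    "population_shared_fraction",
]


class ConfigError(ValueError):
    """Raised for an invalid world configuration."""


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the simulated world.

    Defaults describe the standard aligned desk-scale world: 6 networks of 3
    layers x 60 channels mixing 3 universal and 6 idiosyncratic latents, with
    the universal loadings (scale 1.0) dominating the idiosyncratic ones
    (scale 0.3) so that shared structure carries the top variance, light
    observation noise, and 4 subjects whose voxels mix all universal latents.
    """

    n_stim_fit: int = 600
    n_stim_eval: int = 200
    n_networks: int = 6
    n_layers: int = 3
    n_channels: int = 60
    n_spatial: int = 1
    n_universal: int = 3
    n_idio: int = 6
    universal_scale: float = 1.0
    idio_scale: float = 0.3
    noise_sd: float = 0.1
    nonneg: bool = False
    n_subjects: int = 4
    n_voxels: int = 200
    brain_latents: str = "all"  # "all" | "subset:k" | "disjoint"
    brain_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_stim_fit": self.n_stim_fit,
            "n_stim_eval": self.n_stim_eval,
            "n_networks": self.n_networks,
            "n_layers": self.n_layers,
            "n_channels": self.n_channels,
            "n_spatial": self.n_spatial,
            "n_universal": self.n_universal,
            "n_subjects": self.n_subjects,
            "n_voxels": self.n_voxels,
        }
        for name, val in counts.items():
            if int(val) != val or val < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {val!r}")
        if self.n_idio < 0:
            raise ConfigError("n_idio must be >= 0")
        if self.n_stim_eval < 20:
            raise ConfigError("n_stim_eval must be >= 20")
        for name in ("universal_scale", "idio_scale", "noise_sd", "brain_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        self._parse_brain_latents()

    def _parse_brain_latents(self) -> int | None:
        """Number of universal latents the brain mixes, or None for disjoint."""
        spec = self.brain_latents
        if spec == "all":
            return self.n_universal
        if spec == "disjoint":
            return None
        if spec.startswith("subset:"):
            k = int(spec.split(":", 1)[1])
            if not 1 <= k <= self.n_universal:
                raise ConfigError(
                    f"subset size {k} outside 1..{self.n_universal}"
                )
            return k
        raise ConfigError(f"unknown brain_latents policy {spec!r}")

    @property
    def n_stim(self) -> int:
        return self.n_stim_fit + self.n_stim_eval

    @property
    def fit_slice(self) -> slice:
        return slice(0, self.n_stim_fit)

    @property
    def eval_slice(self) -> slice:
        return slice(self.n_stim_fit, self.n_stim)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        return cls(**d)


@dataclass(frozen=True)
class LatentWorld:
    """All latent matrices and mixing weights of one simulated world.

    Rows of every latent matrix cover the fit split followed by the evaluation
    split, in stimulus order shared by all generated objects.
    """

    config: WorldConfig
    Z_shared: np.ndarray          # n_stim x n_universal
    Z_idio: tuple[np.ndarray, ...]    # per network, n_stim x n_idio
    Z_brain: np.ndarray           # n_stim x L_brain
    W: tuple[tuple[np.ndarray, ...], ...]  # [network][layer]: (n_univ+n_idio) x channels x spatial
    B: tuple[np.ndarray, ...]     # per subject, L_brain x n_voxels
    brain_latent_kind: Literal["shared", "disjoint"]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-component generator derived from the world seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def make_latents(config: WorldConfig) -> LatentWorld:
    """Draw every latent matrix and mixing weight of a world.

    Latent columns are iid standard normal over all fit+eval stimuli; network
    mixing weights are standard normal scaled by ``universal_scale`` (shared
    block) and ``idio_scale`` (idiosyncratic block); subject weights are
    standard normal.  The ``brain_latents`` policy selects which universal
    latents the brain mixes, or draws fresh independent ones for ``disjoint``.
    """
    c = config
    n = c.n_stim
    Z_shared = _rng(c.seed, 0).standard_normal((n, c.n_universal))
    Z_idio = tuple(
        _rng(c.seed, 1, i).standard_normal((n, c.n_idio)) for i in range(c.n_networks)
    )
    k = c._parse_brain_latents()
    if k is None:
        Z_brain = _rng(c.seed, 2).standard_normal((n, c.n_universal))
        kind: Literal["shared", "disjoint"] = "disjoint"
    else:
        Z_brain = Z_shared[:, :k].copy()
        kind = "shared"
    W = tuple(
        tuple(
            np.concatenate(
                [
                    c.universal_scale
                    * _rng(c.seed, 3, i, l, 0).standard_normal(
                        (c.n_universal, c.n_channels, c.n_spatial)
                    ),
                    c.idio_scale
                    * _rng(c.seed, 3, i, l, 1).standard_normal(
                        (c.n_idio, c.n_channels, c.n_spatial)
                    ),
                ],
                axis=0,
            )
            for l in range(c.n_layers)
        )
        for i in range(c.n_networks)
    )
    B = tuple(
        _rng(c.seed, 4, s).standard_normal((Z_brain.shape[1], c.n_voxels))
        for s in range(c.n_subjects)
    )
    return LatentWorld(
        config=c, Z_shared=Z_shared, Z_idio=Z_idio, Z_brain=Z_brain, W=W, B=B,
        brain_latent_kind=kind,
    )


def make_null_world(config: WorldConfig) -> LatentWorld:
    """Aligned network structure, but brain latents independent of all of it."""
    return make_latents(replace(config, brain_latents="disjoint"))


def make_network(
    world: LatentWorld, network_id: int, config: WorldConfig | None = None
) -> ActivationSet:
    """Materialize one network's raw layer activations over all stimuli.

    Each layer's tensor is ``[Z_shared | Z_idio] . W_layer`` plus Gaussian
    observation noise, rectified when ``nonneg`` is set.  Layers of the same
    network share latents but draw independent weights and noise.
    """
    c = config or world.config
    if not 0 <= network_id < c.n_networks:
        raise IndexError(f"network_id {network_id} outside 0..{c.n_networks - 1}")
    Z = np.hstack([world.Z_shared, world.Z_idio[network_id]])
    layers: dict[str, np.ndarray] = {}
    for l in range(c.n_layers):
        A = np.tensordot(Z, world.W[network_id][l], axes=(1, 0))
        if c.noise_sd > 0:
            A = A + c.noise_sd * _rng(c.seed, 5, network_id, l).standard_normal(A.shape)
        if c.nonneg:
            A = np.maximum(A, 0.0)
        layers[f"layer{l}"] = A
    return ActivationSet(network_id=f"net{network_id}", layers=layers, split="all")


def make_brain(
    world: LatentWorld, subject_id: int, config: WorldConfig | None = None
) -> np.ndarray:
    """One subject's stimuli x voxels response matrix, column-standardized.

    Voxels are linear mixtures of the brain latents plus subject-specific
    Gaussian noise; each voxel (column) is then z-scored across stimuli,
    emulating session-standardized response amplitudes.
    """
    c = config or world.config
    if not 0 <= subject_id < c.n_subjects:
        raise IndexError(f"subject_id {subject_id} outside 0..{c.n_subjects - 1}")
    V = world.Z_brain @ world.B[subject_id]
    if c.brain_noise_sd > 0:
        V = V + c.brain_noise_sd * _rng(c.seed, 6, subject_id).standard_normal(V.shape)
    V = V - V.mean(axis=0)
    sd = V.std(axis=0)
    return V / np.where(sd > 0, sd, 1.0)


def shared_variance_fraction(
    world: LatentWorld, series: np.ndarray, rows: slice | np.ndarray | None = None
) -> np.ndarray:
    """Ground-truth fraction of each column's variance explained by Z_shared.

    Computed as the R-squared of an ordinary least-squares fit (with intercept)
    of the column on the universal latents, row-aligned with ``series``.  This
    is the generator-side oracle against which universality estimates can be
    validated.
    """
    series = np.atleast_2d(np.asarray(series, dtype=np.float64).T).T
    Z = world.Z_shared if rows is None else world.Z_shared[rows]
    if Z.shape[0] != series.shape[0]:
        raise ValueError("row count of series must match selected latent rows")
    Zc = Z - Z.mean(axis=0)
    Yc = series - series.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Zc, Yc, rcond=None)
    resid = Yc - Zc @ coef
    tot = np.einsum("ij,ij->j", Yc, Yc)
    res = np.einsum("ij,ij->j", resid, resid)
    frac = np.zeros(series.shape[1])
    ok = tot > 0
    frac[ok] = 1.0 - res[ok] / tot[ok]
    return np.clip(frac, 0.0, 1.0)


def population_shared_fraction(
    world: LatentWorld, network_id: int, layer: int, loadings: np.ndarray
) -> np.ndarray:
    """Exact population shared-variance fraction of linear readout directions.

    For a direction v over channels, the population variance of its activation
    readout splits into a universal part |Ws' v|^2, an idiosyncratic part
    |Wi' v|^2, and a noise part ``noise_sd^2 |v|^2`` (unit-variance latents).
    Only valid for the linear single-spatial-position world (no rectification),
    where pooled activations are exactly the latent mixture.
    """
    c = world.config
    if c.n_spatial != 1 or c.nonneg:
        raise ValueError(
            "population fractions require a linear world (n_spatial=1, nonneg off)"
        )
    W = world.W[network_id][layer][:, :, 0]  # (n_universal + n_idio) x channels
    V = np.asarray(loadings, dtype=np.float64)
    sv = np.sum((W[: c.n_universal] @ V) ** 2, axis=0)
    iv = np.sum((W[c.n_universal :] @ V) ** 2, axis=0)
    nv = c.noise_sd**2 * np.sum(V**2, axis=0)
    tot = sv + iv + nv
    return np.where(tot > 0, sv / np.where(tot > 0, tot, 1.0), 0.0)
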