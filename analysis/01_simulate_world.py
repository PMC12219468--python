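"""Simulate the aligned latent world and persist activations and brain data.

Writes ``results/analysis/world.h5``: one HDF5 group per network with one
dataset per layer (rows in stimulus order, fit split first), plus one dataset
per simulated subject.  The same world is reproduced bit-identically by every
later driver from the configuration seed.
"""

from dataclasses import replace

from analysis_config import CONFIG
from unidims.io import write_world_h5
from unidims.pipeline import build_analysis, seed_for
from unidims.world import population_shared_fraction


def main() -> None:
    world_cfg = replace(CONFIG.world, seed=seed_for(CONFIG.seed, "world"))
    state = build_analysis(world_cfg, fold_seed=seed_for(CONFIG.seed, "folds"))
    out = f"{CONFIG.out_dir}/world.h5"
    import pathlib

    pathlib.Path(CONFIG.out_dir).mkdir(parents=True, exist_ok=True)
    write_world_h5(
        out,
        state.networks_all,
        state.subjects_all,
        config_json=world_cfg.to_json(),
        seed=world_cfg.seed,
    )
    c = world_cfg
    frac = population_shared_fraction(
        state.world, 0, 0, state.bases["net0"]["layer0"].loadings
    )
    print(
        f"simulated {c.n_networks} networks x {c.n_layers} layers x "
        f"{c.n_channels} channels over {c.n_stim} stimuli "
        f"({c.n_stim_fit} fit / {c.n_stim_eval} eval), {c.n_subjects} subjects"
    )
    print(
        f"net0/layer0 ground truth: {int((frac >= 0.9).sum())} dimensions are "
        f">=90% universal-latent variance, "
        f"{int((frac <= 0.1).sum())} are <=10%"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
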