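"""Pool activations, fit per-layer PC bases, and project the evaluation set.

Each layer is reduced to its latent dimensions: global max pooling removes the
spatial axis, PCA on the fit-split activations (centered on fit-split channel
means, all components up to the matrix rank retained) defines the basis, and
the evaluation split is projected into it.  Writes ``results/analysis/pcs.h5``.
"""

import pathlib
from dataclasses import replace

from analysis_config import CONFIG
from unidims.io import write_pc_h5
from unidims.pipeline import build_analysis, seed_for


def main() -> None:
    world_cfg = replace(CONFIG.world, seed=seed_for(CONFIG.seed, "world"))
    state = build_analysis(world_cfg, fold_seed=seed_for(CONFIG.seed, "folds"))
    pathlib.Path(CONFIG.out_dir).mkdir(parents=True, exist_ok=True)
    out = f"{CONFIG.out_dir}/pcs.h5"
    write_pc_h5(out, state.bases, state.scores_eval)
    n_dims = sum(Y.shape[1] for Y in state.targets.values())
    ranks = sorted(
        {b.rank for layers in state.bases.values() for b in layers.values()}
    )
    print(f"extracted {n_dims} dimensions across "
          f"{world_cfg.n_networks * world_cfg.n_layers} layers "
          f"(per-layer ranks: {ranks})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
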