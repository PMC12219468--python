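"""Score every dimension: universality and brain similarity.

Runs the pipeline through the scoring stage (earlier stages are reused if
their artifacts exist) and reports how the two metrics distribute.  Writes
``results/analysis/scores.csv`` with one row per (network, layer, PC rank):
per-predictor and per-subject cross-validated correlations, their
median/mean aggregates, and the between-subject reliability.
"""

import pandas as pd

from analysis_config import CONFIG
from unidims.pipeline import run_all


def main() -> None:
    run_all(CONFIG)
    frame = pd.read_csv(f"{CONFIG.out_dir}/scores.csv")
    print(f"scored {len(frame)} dimensions")
    print(
        "universality:     "
        f"median {frame.universality.median():+.3f}, "
        f"90th pct {frame.universality.quantile(0.9):+.3f}, "
        f"max {frame.universality.max():+.3f}"
    )
    print(
        "brain similarity: "
        f"median {frame.brain_similarity.median():+.3f}, "
        f"90th pct {frame.brain_similarity.quantile(0.9):+.3f}, "
        f"max {frame.brain_similarity.max():+.3f}"
    )
    top = frame.nlargest(5, "universality")[
        ["network_id", "layer_id", "pc_rank", "universality", "brain_similarity"]
    ]
    print("most universal dimensions:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
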