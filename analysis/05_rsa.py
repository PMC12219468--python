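"""Representational similarity analysis, full versus universal-subspace.

For each network: select the best layer on the train half of the evaluation
stimuli, report the held-out test similarity to the simulated subjects, and
compare against reconstructions that keep only the top-10 / top-5 most
universal dimensions of that layer.  Results in ``results/analysis/rsa.json``.
"""

from analysis_config import CONFIG
from unidims.pipeline import run_all


def main() -> None:
    summary = run_all(CONFIG)
    print("network  layer    full    top-10  top-5")
    for nid, res in summary["rsa"].items():
        red = res["test_similarity_reduced"]
        print(
            f"{nid:<8} {res['selected_layer']:<8} "
            f"{res['test_similarity_full']:+.3f}  "
            f"{red['10']:+.3f}  {red['5']:+.3f}"
        )
    drops = [
        res["test_similarity_full"] - res["test_similarity_reduced"]["5"]
        for res in summary["rsa"].values()
    ]
    print(
        f"largest decrease from keeping only 5 universal dimensions: "
        f"{max(drops):+.3f} (negative = reduction improved similarity)"
    )


if __name__ == "__main__":
    main()
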