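"""Relate universality to brain similarity: rank correlation and significance.

Reports the Spearman correlation between the two metrics across all scored
dimensions, the partial Spearman controlling for PC rank, and the one-sided
stimulus-label permutation p-value, plus the quantile-binned trend.  Reuses
completed stages; results land in ``results/analysis/inference.json`` and the
assembled ``summary.json``.
"""

from analysis_config import CONFIG
from unidims.pipeline import run_all


def main() -> None:
    summary = run_all(CONFIG)
    print(
        f"Spearman(universality, brain similarity) = {summary['rho']:+.3f} "
        f"over {summary['n_dimensions']} dimensions"
    )
    print(f"partial Spearman given PC rank          = {summary['rho_partial']:+.3f}")
    print(
        f"permutation test: p = {summary['p_value']:.4f} "
        f"({summary['n_permutations']} label permutations)"
    )
    print("quantile bins (100 dims each), universality -> brain similarity:")
    for b in summary["quantile_bins"]:
        print(f"  {b['universality']:+.3f} -> {b['brain_similarity']:+.3f}")


if __name__ == "__main__":
    main()
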