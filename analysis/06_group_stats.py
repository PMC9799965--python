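"""Permutation group statistics: mixed ANOVA, FDR, consolidation,
mesoscale session tests, score correlations and cohort demographics.

Prints the significant time-of-day and chronotype effects found on the
synthetic cohort; tables land under results/run/stats/.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import load_run, run_config

from chrononet.pipeline import stage_mesoscale, stage_metrics, stage_stats


def main() -> None:
    cfg = run_config()
    out, panels, design, parc, nets = load_run(cfg)
    local_tbl, global_tbl, auc_tbl = stage_metrics(nets, parc, cfg, out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        meso = stage_mesoscale(nets, parc, cfg, out)
        res = stage_stats(local_tbl, global_tbl, auc_tbl, meso, design, cfg, out)

    g = res["global_anova"]
    sig = g[g.significant]
    print(f"global ANOVA: {len(sig)}/{len(g)} significant "
          f"(effect x metric x density) after FDR")
    for (eff, metric), grp in sig.groupby(["effect", "metric"]):
        ds = ", ".join(f"{d:.2f}" for d in sorted(grp.density))
        print(f"  {eff:11s} {metric:16s} at densities {ds}")

    cons = res["consolidated"]
    hit = cons[cons.consolidated]
    print(f"nodal effects significant in >half of densities: {len(hit)} "
          f"(of {len(cons)} effect x metric x region combinations)")
    for eff, grp in hit.groupby("effect"):
        regions = sorted(grp.region_id.unique())
        print(f"  {eff:11s} regions {regions}")

    mt = res["mesoscale_tests"]
    for _, row in mt.iterrows():
        print(f"mesoscale {row.test:30s} {row.coefficient:12s} "
              f"p={row.p_perm if row.p_perm == row.p_perm else float('nan'):.4g} "
              f"{'*' if row.significant else ''}")

    corr = res["correlations"]
    csig = corr[corr.significant]
    print(f"score correlations: {len(csig)}/{len(corr)} significant after FDR")
    print("cohort demographics tests:")
    print(res["cohort"].to_string(index=False))
    print(f"stat tables under {out / 'stats'}")


if __name__ == "__main__":
    main()
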