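"""Identify provincial and connector hubs on the group-average networks.

Hubs are degree-above-mean regions of the session-average matrix
binarized at density 0.05; connectors have participation >= 0.3 over the
7 systems.  Writes hub tables and connectogram edge lists under
results/run/hubs/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import load_run, run_config

from chrononet.pipeline import stage_hubs


def main() -> None:
    cfg = run_config()
    out, panels, design, parc, nets = load_run(cfg)
    tables = stage_hubs(nets, parc, cfg, out)
    for ses, tbl in tables.items():
        hubs = tbl[tbl.is_hub]
        top = hubs.system.value_counts()
        lead = f"{top.index[0]} ({top.iloc[0]} hubs)" if len(top) else "none"
        print(f"{ses:8s} {len(hubs)} hubs at density {cfg.hub_density}: "
              f"{(hubs.hub_type == 'connector').sum()} connector, "
              f"{(hubs.hub_type == 'provincial').sum()} provincial; "
              f"densest system: {lead}")
    print(f"hub tables under {out / 'hubs'}")


if __name__ == "__main__":
    main()
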