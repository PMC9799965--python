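"""Build Fisher-z connectivity matrices and session group averages.

Writes results/run/networks/group_average_{session}.csv and prints the
average within- vs between-system connectivity per session — the evening
between-system values should sit visibly above the morning ones because
of the injected integration effect.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import load_run, run_config


def main() -> None:
    cfg = run_config()
    out, panels, design, parc, nets = load_run(cfg)
    sysidx = parc.system_of()
    same = sysidx[:, None] == sysidx[None, :]
    np.fill_diagonal(same, False)
    off = ~same & ~np.eye(parc.n_regions, dtype=bool)
    print(f"built {len(nets)} weighted networks "
          f"({parc.n_regions}x{parc.n_regions} Fisher-z)")
    for ses in ("morning", "evening"):
        zs = np.mean([w.z for w in nets if w.meta["session"] == ses], axis=0)
        print(f"  {ses:8s} mean z within-system {zs[same].mean():.3f}, "
              f"between-system {zs[off].mean():.3f}")
    print(f"group averages under {out / 'networks'}")


if __name__ == "__main__":
    main()
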