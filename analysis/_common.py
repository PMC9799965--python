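"""Shared configuration for the numbered analysis scripts.

One scaled synthetic cohort stands in for the emulated study: 12 subjects
per chronotype (instead of 31), 56 cortical regions in the 7 mirrored
systems (instead of 200), T=325 time points at TR=1.8 s.  An evening
integration increase (delta=0.15 on between-system correlations) and an
ET chronotype effect (+0.1 on within-system correlations of the
somatomotor regions) are injected so every downstream stage has signal to
find.  All scripts share the seed, so each one can cheaply re-derive the
upstream objects it needs.
"""

from pathlib import Path

from chrononet.connectome import DENSITY_GRID
from chrononet.parcellation import default_parcellation
from chrononet.pipeline import RunConfig, stage_data, stage_networks

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 7

_PARC = default_parcellation(56)
SOMMOT_REGIONS = _PARC.table.loc[_PARC.table.system == "SomMot",
                                 "region_id"].tolist()

SIMULATE = dict(
    n_per_group=12,
    n_regions=56,
    t_points=325,
    tod_integration_delta=0.15,
    chrono_effect=(SOMMOT_REGIONS, 0.10),
)


def run_config(**over) -> RunConfig:
    kw = dict(
        out_dir=str(RESULTS / "run"),
        seed=SEED,
        simulate=SIMULATE,
        densities=DENSITY_GRID,
        # structural resolution between the two sessions' block-merge
        # thresholds for this cohort geometry (see docs/methods.md)
        gamma_grid=(0.9,),
        omega_grid=(0.1,),
        n_perm=2000,
        n_null=20,
        n_reps=5,
        hub_density=0.05,
    )
    kw.update(over)
    return RunConfig(**kw)


def load_run(config: RunConfig):
    """(Re)derive panels, design, parcellation and z-networks for a config."""
    out = Path(config.out_dir)
    panels, design, parc = stage_data(config, out)
    nets = stage_networks(panels, parc, out)
    return out, panels, design, parc, nets
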