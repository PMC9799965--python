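"""Hub identification and provincial/connector classification.

Hubs are found on the group-average connectivity matrix of a session,
binarized at a display density (default 0.05): a region is a hub when its
degree exceeds the mean degree.  A hub whose participation coefficient
(over the seven systems) reaches the connector threshold (default 0.3)
is a connector hub; otherwise it is provincial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectome import WeightedNetwork, threshold_binarize
from .metrics import participation_coefficient
from .parcellation import Parcellation


def group_average_network(layers: list[WeightedNetwork]) -> WeightedNetwork:
    """Elementwise mean of the Fisher-z matrices across subjects."""
    if not layers:
        raise ValueError("need at least one layer")
    n = layers[0].n_regions
    if any(l.n_regions != n for l in layers):
        raise ValueError("layers must share the same region count")
    z = np.mean([l.z for l in layers], axis=0)
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    sessions = {l.meta.get("session") for l in layers}
    meta = {"n_layers": len(layers)}
    if len(sessions) == 1:
        meta["session"] = sessions.pop()
    return WeightedNetwork(z, meta=meta)


def identify_hubs(
    w: WeightedNetwork,
    parcellation: Parcellation,
    density: float = 0.05,
    connector_threshold: float = 0.3,
) -> pd.DataFrame:
    """Hub table for one (typically group-average) network.

    Columns: region_id, system, degree, participation, is_hub, hub_type
    ({provincial, connector, none}).  A regular graph yields an empty hub
    set (no degree strictly exceeds the mean).
    """
    net = threshold_binarize(w, density)
    k = net.degrees()
    part = participation_coefficient(net, parcellation.system_of())
    is_hub = k > k.mean()
    hub_type = np.where(
        is_hub, np.where(part >= connector_threshold, "connector", "provincial"),
        "none",
    )
    return pd.DataFrame(
        {
            "region_id": parcellation.table["region_id"].to_numpy(),
            "label": parcellation.table["label"].to_numpy(),
            "system": parcellation.table["system"].to_numpy(),
            "degree": k,
            "participation": part,
            "is_hub": is_hub,
            "hub_type": hub_type,
            "density": density,
        }
    )


def connectogram_edges(
    w: WeightedNetwork, parcellation: Parcellation, density: float = 0.05
) -> pd.DataFrame:
    """Edge list at the display density, tagged within/between module.

    Mirrors the red (between-system) vs black (within-system) distinction
    of a connectogram, as a plain table for external plotting.
    """
    net = threshold_binarize(w, density)
    sysidx = parcellation.system_of()
    iu, ju = np.nonzero(np.triu(net.a, k=1))
    return pd.DataFrame(
        {
            "i": iu + 1,
            "j": ju + 1,
            "weight": w.z[iu, ju],
            "scope": np.where(sysidx[iu] == sysidx[ju], "within", "between"),
        }
    )
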