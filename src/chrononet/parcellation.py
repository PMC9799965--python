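"""Cortical parcellation lookup (Schaefer/Yeo-style, 200 parcels / 7 systems).

A :class:`Parcellation` maps each region of interest (ROI) to a hemisphere
and to one of seven large-scale functional systems.  Region ids are 1-based
and contiguous; by convention ids 1..N/2 are left-hemisphere (LH) and
N/2+1..N right-hemisphere (RH).  The seven-system partition is the module
set used by the participation coefficient and by recruitment/integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical seven-system names (Yeo ordering) with per-hemisphere parcel
#: counts for the default 200-region synthetic lookup (they sum to 100).
DEFAULT_SYSTEMS: list[tuple[str, int]] = [
    ("Vis", 15),
    ("SomMot", 16),
    ("DorsAttn", 13),
    ("SalVentAttn", 12),
    ("Limbic", 10),
    ("Cont", 13),
    ("Default", 21),
]

REQUIRED_COLUMNS = ("region_id", "label", "hemisphere", "system")


@dataclass
class Parcellation:
    """Region lookup table: id, label, hemisphere, system, optional MNI xyz."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"parcellation missing columns: {missing}")
        t = t.sort_values("region_id").reset_index(drop=True)
        ids = t["region_id"].to_numpy()
        if len(ids) == 0:
            raise ValueError("empty parcellation")
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("region_ids must be unique and contiguous from 1")
        if t["label"].duplicated().any():
            raise ValueError("region labels must be unique")
        bad = set(t["hemisphere"].unique()) - {"LH", "RH"}
        if bad:
            raise ValueError(f"unknown hemisphere codes: {sorted(bad)}")
        self.table = t

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    @property
    def systems(self) -> list[str]:
        """System names in order of first appearance."""
        return list(dict.fromkeys(self.table["system"]))

    def system_of(self) -> np.ndarray:
        """Integer system index per region (order of :attr:`systems`)."""
        index = {s: i for i, s in enumerate(self.systems)}
        return self.table["system"].map(index).to_numpy()

    def system_sizes(self) -> dict[str, int]:
        return self.table["system"].value_counts().to_dict()

    @classmethod
    def from_csv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_parcellation(
    n_regions: int = 200,
    systems: list[tuple[str, int]] | None = None,
) -> Parcellation:
    """Build a synthetic Schaefer-style lookup table.

    With the defaults this mirrors the layout of the 200-parcel/7-network
    cortical atlas (ids 1-100 LH, 101-200 RH, each hemisphere running
    through the seven systems in Yeo order).  It is a synthetic stand-in:
    labels are generated, not the atlas's parcel names, and no coordinates
    are included.

    Parameters
    ----------
    n_regions
        Total region count.
    systems
        ``[(name, size), ...]``. If sizes sum to ``n_regions // 2`` the
        layout is mirrored across hemispheres; if they sum to ``n_regions``
        systems are laid out contiguously and the hemisphere boundary falls
        at ``n_regions // 2``.
    """
    if systems is None:
        if n_regions % 2:
            raise ValueError("default mirrored layout needs an even n_regions")
        half = n_regions // 2
        base = sum(s for _, s in DEFAULT_SYSTEMS)
        sizes = _partition_sizes(half, base, DEFAULT_SYSTEMS)
        systems = list(zip((n for n, _ in DEFAULT_SYSTEMS), sizes))
        total = 2 * half
    else:
        total = sum(s for _, s in systems)
        if total == n_regions // 2 and n_regions % 2 == 0:
            total = n_regions
        elif total != n_regions:
            raise ValueError("system sizes must sum to n_regions (or half of it)")

    rows = []
    per_hemi = sum(s for _, s in systems)
    if per_hemi * 2 == total:  # mirrored
        rid = 1
        for hemi in ("LH", "RH"):
            for name, size in systems:
                for k in range(1, size + 1):
                    rows.append((rid, f"{hemi}_{name}_{k}", hemi, name))
                    rid += 1
    else:  # contiguous systems, hemisphere split at the midpoint
        rid = 1
        half = total // 2
        for name, size in systems:
            for k in range(1, size + 1):
                hemi = "LH" if rid <= half else "RH"
                rows.append((rid, f"{hemi}_{name}_{k}", hemi, name))
                rid += 1
    table = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return Parcellation(table)


def _partition_sizes(half: int, base: int, systems) -> list[int]:
    """Scale the default per-hemisphere sizes to sum to ``half``."""
    raw = [s * half / base for _, s in systems]
    sizes = [max(1, int(round(x))) for x in raw]
    # fix rounding drift on the largest system
    drift = half - sum(sizes)
    sizes[int(np.argmax(sizes))] += drift
    if min(sizes) < 1:
        raise ValueError(f"n_regions too small for {len(systems)} systems")
    return sizes
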