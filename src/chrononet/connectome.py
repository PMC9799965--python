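"""Functional connectome construction from ROI time series.

The pipeline entry point for real or simulated data: per subject-session
T×N ROI time-series panels are turned into Fisher-z correlation matrices
(weighted networks) and then proportionally thresholded and binarized at a
grid of network densities, so every subject's binary graph has the same
edge count at a given density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import Parcellation

#: Analysis densities: 0.05 to 0.5 in steps of 0.05.
DENSITY_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.05, 2))

SESSIONS = ("morning", "evening")
CHRONOTYPES = ("MT", "ET")


@dataclass
class TimeSeriesPanel:
    """One subject-session block of region-averaged BOLD signals (T×N)."""

    subject_id: str
    session: str
    chronotype: str
    data: np.ndarray = field(repr=False)
    tr: float = 1.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("panel data must be a T×N matrix")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.isfinite(self.data).all():
            raise ValueError("panel contains missing/non-finite values")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        if self.chronotype not in CHRONOTYPES:
            raise ValueError(f"unknown chronotype {self.chronotype!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class WeightedNetwork:
    """Fisher-z transformed Pearson correlation matrix (zero diagonal)."""

    z: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if not np.isfinite(z).all():
            raise ValueError("z contains non-finite entries")
        if not np.allclose(z, z.T):
            raise ValueError("z must be symmetric")
        if np.abs(np.diag(z)).max(initial=0.0) != 0.0:
            raise ValueError("z must have a zero diagonal")
        self.z = z

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected simple graph as a 0/1 adjacency with its edge density."""

    a: np.ndarray = field(repr=False)
    density: float = float("nan")

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.a = a.astype(np.uint8)
        if np.isnan(self.density):
            n = a.shape[0]
            pairs = n * (n - 1) / 2
            self.density = float(a.sum() / 2 / pairs) if pairs else 0.0

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(int)


# ---------------------------------------------------------------------------
# I/O


def write_timeseries(panel: TimeSeriesPanel, path, parcellation: Parcellation) -> None:
    """Write a panel as TSV: one column per region label, one row per TR."""
    df = pd.DataFrame(panel.data, columns=parcellation.labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_timeseries(
    path,
    parcellation: Parcellation,
    subject_id: str = "unknown",
    session: str = "morning",
    chronotype: str = "MT",
    tr: float = 1.8,
) -> TimeSeriesPanel:
    """Load a TSV time-series panel and align columns to parcellation order.

    The header must contain exactly the parcellation's region labels (any
    column order); columns are reordered to region_id order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    want = parcellation.labels
    have = list(df.columns)
    if set(have) != set(want):
        extra = sorted(set(have) - set(want))[:5]
        miss = sorted(set(want) - set(have))[:5]
        raise ValueError(
            f"{path.name}: columns do not match parcellation "
            f"({len(have)} vs {len(want)}; missing e.g. {miss}, extra e.g. {extra})"
        )
    data = df[want].to_numpy(dtype=float)
    if not np.isfinite(data).all():
        raise ValueError(f"{path.name}: non-numeric or missing cells")
    return TimeSeriesPanel(subject_id, session, chronotype, data, tr)


def load_cohort(design_path, timeseries_dir, parcellation: Parcellation):
    """Load every panel referenced by a design table.

    The design TSV has one row per subject-session with columns
    ``subject_id, session, chronotype, ...``; panels are read from
    ``<timeseries_dir>/<subject_id>_<session>.tsv``.
    """
    design = pd.read_csv(design_path, sep="\t")
    panels = []
    for _, row in design.iterrows():
        f = Path(timeseries_dir) / f"{row.subject_id}_{row.session}.tsv"
        panels.append(
            load_timeseries(
                f, parcellation, str(row.subject_id), row.session, row.chronotype
            )
        )
    return panels, design


# ---------------------------------------------------------------------------
# Network construction


def correlation_matrix(panel: TimeSeriesPanel, clip_eps: float = 1e-7) -> WeightedNetwork:
    """Pearson correlation + Fisher r-to-z, with |r| clipped below 1.

    The clip (``|r| <= 1 - clip_eps``) keeps atanh finite for degenerate
    (perfectly collinear) inputs; it is a no-op for generic data.
    """
    x = panel.data
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0)) + 1
        raise ValueError(f"region {bad} has a constant time series (zero variance)")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1 + clip_eps, 1 - clip_eps)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return WeightedNetwork(
        z, meta={"subject_id": panel.subject_id, "session": panel.session,
                 "chronotype": panel.chronotype}
    )


def edge_count_at_density(n: int, density: float) -> int:
    """Edges retained at a proportional threshold: round(d·N(N−1)/2).

    Rounds half away from zero so the same rule applies at every density.
    """
    pairs = n * (n - 1) / 2
    return int(np.floor(density * pairs + 0.5))


def threshold_binarize(w: WeightedNetwork, density: float) -> BinaryNetwork:
    """Keep the strongest |z| edges at the requested density and binarize.

    Edges are ranked by absolute weight (magnitude, so strong negative
    correlations are kept); ties are broken by ascending (i, j) pair order,
    which makes the result deterministic and edge sets nested across
    densities.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = w.n_regions
    iu, ju = np.triu_indices(n, k=1)
    mag = np.abs(w.z[iu, ju])
    k = edge_count_at_density(n, density)
    # primary key: descending |z|; then ascending i, then ascending j
    order = np.lexsort((ju, iu, -mag))
    keep = order[:k]
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    return BinaryNetwork(a, density=float(density))


def export_edge_list(w: WeightedNetwork, path) -> None:
    """Write the upper triangle as an (i, j, weight) TSV with 1-based ids."""
    n = w.n_regions
    iu, ju = np.triu_indices(n, k=1)
    pd.DataFrame({"i": iu + 1, "j": ju + 1, "weight": w.z[iu, ju]}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def save_matrix_csv(m: np.ndarray, path, labels=None) -> None:
    pd.DataFrame(m, columns=labels).to_csv(path, index=False, float_format="%.10g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
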