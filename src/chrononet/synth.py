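"""Synthetic cohorts, toy graphs and planted multilayer benchmarks.

The cohort generator emulates the structure the downstream analysis
assumes: a two-chronotype cohort (MT "larks" vs ET "owls"), two scanning
sessions per subject (morning/evening), and region time series drawn from
a zero-mean multivariate normal whose correlation matrix is block-constant
over the seven functional systems.  Session and chronotype effects are
injected additively on the target correlations: a time-of-day effect
raises between-system correlations in the evening (more integration), and
a chronotype effect shifts within-system correlations for a chosen region
set in ET subjects.

The model is deliberately minimal — no temporal autocorrelation, no
hemodynamics, no motion — because every downstream stage consumes only
zero-lag Pearson correlations.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    BinaryNetwork,
    TimeSeriesPanel,
    WeightedNetwork,
    write_json,
    write_timeseries,
)
from .parcellation import Parcellation, default_parcellation

_PD_FLOOR = 1e-6  # eigenvalue floor for positive-definiteness repair


@dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the emulated study: 31 subjects per chronotype, 200
    regions in 7 systems (ids 1-100 LH, 101-200 RH), 325 time points at
    TR = 1.8 s.  Correlation levels (within-system 0.35, between-system
    0.1) and the measurement noise (0.25 SD white noise on unit-variance
    signals) are generator choices at realistic resting-state magnitudes;
    effect sizes default to zero.
    """

    n_per_group: int = 31
    n_regions: int = 200
    systems: list[tuple[str, int]] | None = None
    t_points: int = 325
    tr: float = 1.8
    rho_within: float = 0.35
    rho_between: float = 0.1
    tod_integration_delta: float = 0.0
    chrono_effect: tuple[list[int], float] | None = None
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_between < self.rho_within < 1:
            raise ValueError("need 0 <= rho_between < rho_within < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.t_points < 3 or self.n_per_group < 1:
            raise ValueError("degenerate cohort dimensions")
        if self.systems is not None:
            total = sum(s for _, s in self.systems)
            if total not in (self.n_regions, self.n_regions // 2):
                raise ValueError("system sizes must sum to n_regions (or half)")
        # fail fast if the base targets are not positive definite
        parc = self.parcellation()
        for session in ("morning", "evening"):
            for chrono in ("MT", "ET"):
                target_correlation(self, parc, session, chrono)

    def parcellation(self) -> Parcellation:
        return default_parcellation(self.n_regions, self.systems)


def _repair_pd(r: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= _PD_FLOOR:
        return r
    vals = np.maximum(vals, _PD_FLOOR)
    r2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return (r2 + r2.T) / 2


def target_correlation(
    config: CohortConfig,
    parcellation: Parcellation,
    session: str,
    chronotype: str,
) -> np.ndarray:
    """Latent correlation matrix for one subject-session condition."""
    sysidx = parcellation.system_of()
    same = sysidx[:, None] == sysidx[None, :]
    r = np.where(same, config.rho_within, config.rho_between)
    if session == "evening" and config.tod_integration_delta:
        r = np.where(~same, r + config.tod_integration_delta, r)
    if chronotype == "ET" and config.chrono_effect is not None:
        regions, delta = config.chrono_effect
        mask = np.zeros(config.n_regions, dtype=bool)
        mask[np.asarray(regions) - 1] = True  # region ids are 1-based
        both = np.outer(mask, mask) & same
        r = np.where(both, r + delta, r)
    np.fill_diagonal(r, 1.0)
    if np.abs(r).max() > 1:
        raise ValueError("injected effects push correlations outside [-1, 1]")
    r = _repair_pd(r)
    # repair must succeed: Cholesky is the contract
    np.linalg.cholesky(r)
    return r


def _substream(seed: int, subject_id: str, session: str) -> np.random.Generator:
    """Per-(subject, session) RNG from a stable hash of the identifiers.

    Adding subjects or sessions does not perturb existing draws.
    """
    tag = zlib.crc32(f"{subject_id}|{session}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def simulate_panel(
    config: CohortConfig,
    parcellation: Parcellation,
    subject_id: str,
    session: str,
    chronotype: str,
) -> TimeSeriesPanel:
    r = target_correlation(config, parcellation, session, chronotype)
    rng = _substream(config.seed, subject_id, session)
    chol = np.linalg.cholesky(r)
    x = rng.standard_normal((config.t_points, config.n_regions)) @ chol.T
    if config.noise_sd:
        x = x + config.noise_sd * rng.standard_normal(x.shape)
    return TimeSeriesPanel(subject_id, session, chronotype, x, config.tr)


def simulate_cohort(config: CohortConfig):
    """Draw the full cohort.

    Returns ``(panels, design)``: one :class:`TimeSeriesPanel` per
    subject-session plus a design table (one row per subject-session) with
    chronotype, questionnaire scores and covariates.  Scores are drawn at
    the emulated study's group means/SDs (ME differs sharply by chronotype;
    AM, ESS, age and sex are exchangeable between groups).
    """
    parc = config.parcellation()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD351]))
    panels, rows = [], []
    for chrono in ("MT", "ET"):
        for k in range(1, config.n_per_group + 1):
            sid = f"{chrono}{k:03d}"
            me_mu, me_sd = (15.7, 2.4) if chrono == "MT" else (28.5, 3.8)
            me = float(rng.normal(me_mu, me_sd))
            am = float(rng.normal(21.9, 3.5))
            ess = float(np.clip(rng.normal(5.7, 2.7), 0, 24))
            age = float(np.clip(rng.normal(24.0, 3.2), 20, 35))
            sex = "F" if rng.random() < 0.63 else "M"
            for session in ("morning", "evening"):
                panels.append(simulate_panel(config, parc, sid, session, chrono))
                rows.append(
                    dict(subject_id=sid, session=session, chronotype=chrono,
                         ME=round(me, 2), AM=round(am, 2), ESS=round(ess, 2),
                         age=round(age, 1), sex=sex)
                )
    design = pd.DataFrame(rows)
    return panels, design


def write_cohort(config: CohortConfig, outdir) -> Path:
    """Simulate and write the cohort: panel TSVs, design.tsv, parcellation.csv
    and a JSON sidecar with the full configuration."""
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    parc = config.parcellation()
    panels, design = simulate_cohort(config)
    for p in panels:
        write_timeseries(p, outdir / "timeseries" / f"{p.subject_id}_{p.session}.tsv", parc)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    parc.to_csv(outdir / "parcellation.csv")
    cfg = {k: v for k, v in vars(config).items()}
    write_json(cfg, outdir / "cohort_config.json")
    return outdir


# ---------------------------------------------------------------------------
# Toy graphs (oracle fixtures)


def make_toy_graph(kind: str, n: int, seed: int | None = None, **params) -> BinaryNetwork:
    """Deterministic graph families for closed-form metric checks.

    Kinds: star, cycle, complete, path, ring_lattice (``k`` neighbours per
    side), two_cliques (two disconnected K_{n/2}), planted_partition
    (``n_communities``, ``p_in``, ``p_out``; seeded).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    a = np.zeros((n, n), dtype=np.uint8)
    if kind == "star":
        a[0, 1:] = 1
    elif kind == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        for i in range(n):
            a[i, (i + 1) % n] = 1
    elif kind == "complete":
        a[:] = 1
        np.fill_diagonal(a, 0)
        return BinaryNetwork(a)
    elif kind == "path":
        for i in range(n - 1):
            a[i, i + 1] = 1
    elif kind == "ring_lattice":
        k = int(params.get("k", 2))
        if n <= 2 * k:
            raise ValueError("ring lattice needs n > 2k")
        for i in range(n):
            for d in range(1, k + 1):
                a[i, (i + d) % n] = 1
    elif kind == "two_cliques":
        if n < 4 or n % 2:
            raise ValueError("two_cliques needs an even n >= 4")
        h = n // 2
        a[:h, :h] = 1
        a[h:, h:] = 1
        np.fill_diagonal(a, 0)
        return BinaryNetwork(a)
    elif kind == "planted_partition":
        c = int(params.get("n_communities", 2))
        p_in = float(params.get("p_in", 0.9))
        p_out = float(params.get("p_out", 0.05))
        if n % c:
            raise ValueError("n_communities must divide n")
        labels = np.repeat(np.arange(c), n // c)
        rng = np.random.default_rng(seed)
        iu, ju = np.triu_indices(n, k=1)
        p = np.where(labels[iu] == labels[ju], p_in, p_out)
        on = rng.random(len(iu)) < p
        a[iu[on], ju[on]] = 1
    else:
        raise ValueError(f"unknown toy graph kind {kind!r}")
    a = a | a.T
    return BinaryNetwork(a)


# ---------------------------------------------------------------------------
# Planted multilayer benchmark


@dataclass
class PlantedMultilayer:
    """Weighted planted-partition layers sharing one true labelling."""

    layers: list[WeightedNetwork]
    true_labels: np.ndarray  # (n_layers, n_regions), identical rows
    params: dict = field(default_factory=dict)


def planted_layers(
    n_layers: int,
    n_regions: int,
    n_communities: int,
    p_in: float,
    p_out: float,
    weight_scale: float = 1.0,
    seed: int = 0,
    sizes: list[int] | None = None,
) -> PlantedMultilayer:
    """Stack of independent weighted planted-partition graphs.

    Every layer shares the same community labels; edges appear with
    probability ``p_in`` within and ``p_out`` between communities and carry
    uniform(0.5, 1.5)·weight_scale weights.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if sizes is None:
        if n_regions % n_communities:
            raise ValueError("n_communities must divide n_regions (or pass sizes)")
        sizes = [n_regions // n_communities] * n_communities
    if sum(sizes) != n_regions:
        raise ValueError("sizes must sum to n_regions")
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_regions, k=1)
    p = np.where(labels[iu] == labels[ju], p_in, p_out)
    layers = []
    for s in range(n_layers):
        on = rng.random(len(iu)) < p
        w = np.zeros((n_regions, n_regions))
        w[iu[on], ju[on]] = weight_scale * rng.uniform(0.5, 1.5, on.sum())
        w = w + w.T
        layers.append(WeightedNetwork(w, meta={"layer": s, "planted": True}))
    true = np.tile(labels, (n_layers, 1))
    return PlantedMultilayer(
        layers, true,
        params=dict(n_layers=n_layers, n_regions=n_regions, sizes=sizes,
                    p_in=p_in, p_out=p_out, weight_scale=weight_scale, seed=seed),
    )
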