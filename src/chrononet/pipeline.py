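"""End-to-end analysis: data → networks → metrics → mesoscale → hubs → stats.

Every stage is a plain function over in-memory objects plus a writer that
drops CSV outputs under one results directory; :func:`run_pipeline` chains
them from a single :class:`RunConfig` (YAML-loadable) and records a
manifest with the config hash, seeds and per-stage row counts.  All
randomness descends from one root seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (
    DENSITY_GRID,
    correlation_matrix,
    load_cohort,
    save_matrix_csv,
    threshold_binarize,
    write_json,
)
from .hubs import connectogram_edges, group_average_network, identify_hubs
from .mesoscale import (
    allegiance_matrix,
    export_system_edges,
    grid_search_gamma_omega,
    optimize_multilayer,
    recruitment_integration,
    system_allegiance,
    system_recruitment_integration,
)
from .metrics import (
    auc_over_thresholds,
    global_metrics,
    local_metrics,
    modularity_single,
    small_worldness,
)
from .parcellation import Parcellation
from .stats import (
    bh_fdr,
    cohort_tests,
    consolidate_thresholds,
    perm_identity_regression,
    perm_mixed_anova,
    perm_mixed_anova_table,
    perm_oneway,
    perm_partial_correlation,
)
from .synth import CohortConfig, write_cohort

GLOBAL_METRICS = ("char_path_length", "clustering", "efficiency",
                  "assortativity", "synchronization", "sigma", "modularity")
NODAL_TEST_METRICS = ("degree", "betweenness", "clustering", "efficiency",
                      "path_length", "participation")
SESSIONS = ("morning", "evening")


@dataclass
class RunConfig:
    """Everything one run needs; loadable from YAML."""

    out_dir: str = "results/run"
    seed: int = 0
    # data: either a simulate block or paths to an existing cohort
    simulate: dict | None = None
    design_path: str | None = None
    timeseries_dir: str | None = None
    parcellation_path: str | None = None
    # analysis parameters
    densities: tuple[float, ...] = DENSITY_GRID
    gamma_grid: tuple[float, ...] = (1.2,)
    omega_grid: tuple[float, ...] = (0.1,)
    n_perm: int = 30000
    n_null: int = 100
    n_reps: int = 10
    hub_density: float = 0.05
    connector_threshold: float = 0.3
    scores: tuple[str, ...] = ("ME", "AM", "ESS")
    covariates: tuple[str, ...] = ("age", "sex")

    def __post_init__(self) -> None:
        if self.simulate is None and not (
            self.design_path and self.timeseries_dir and self.parcellation_path
        ):
            raise ValueError("need either a simulate block or cohort paths")
        for p in (self.design_path, self.timeseries_dir, self.parcellation_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"path does not exist: {p}")
        if len(self.densities) == 0 or len(self.gamma_grid) == 0 or len(self.omega_grid) == 0:
            raise ValueError("density and (gamma, omega) grids must be non-empty")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def substream(self, stage: str) -> int:
        """Stage-named 31-bit seed derived from the root seed."""
        tag = zlib.crc32(stage.encode())
        return int(np.random.SeedSequence([self.seed, tag]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stages


def stage_data(config: RunConfig, out: Path):
    """Simulate or load the cohort; returns (panels, design, parcellation)."""
    if config.simulate is not None:
        sim = CohortConfig(**{**config.simulate, "seed": config.substream("simulate")})
        cohort_dir = write_cohort(sim, out / "cohort")
        parc = sim.parcellation()
        panels, design = load_cohort(cohort_dir / "design.tsv",
                                     cohort_dir / "timeseries", parc)
    else:
        parc = Parcellation.from_csv(config.parcellation_path)
        panels, design = load_cohort(config.design_path, config.timeseries_dir, parc)
    return panels, design, parc


def stage_networks(panels, parc, out: Path):
    """Fisher-z networks per panel plus session group averages."""
    nets = [correlation_matrix(p) for p in panels]
    (out / "networks").mkdir(parents=True, exist_ok=True)
    for session in SESSIONS:
        layers = [w for w in nets if w.meta["session"] == session]
        if layers:
            avg = group_average_network(layers)
            save_matrix_csv(avg.z, out / "networks" / f"group_average_{session}.csv",
                            labels=parc.labels)
    return nets


def stage_metrics(nets, parc, config: RunConfig, out: Path):
    """Per subject-session-density nodal and global metrics, plus AUCs."""
    rows_local, rows_global = [], []
    seed0 = config.substream("metrics")
    for w in nets:
        meta = w.meta
        for di, density in enumerate(config.densities):
            net = threshold_binarize(w, density)
            loc = local_metrics(net, parc)
            loc.insert(0, "subject_id", meta["subject_id"])
            loc.insert(1, "session", meta["session"])
            loc.insert(2, "chronotype", meta["chronotype"])
            loc.insert(3, "density", density)
            rows_local.append(loc)
            g = global_metrics(net).as_dict()
            sw = small_worldness(
                net, n_null=config.n_null,
                seed=int(np.random.SeedSequence(
                    [seed0, zlib.crc32(meta["subject_id"].encode()), di]
                ).generate_state(1)[0] % (2**31)),
            )
            g["sigma"] = sw.sigma
            q, _ = modularity_single(net, gamma=1.0, seed=seed0 + di,
                                     n_reps=max(2, config.n_reps // 2))
            g["modularity"] = q
            g.update(subject_id=meta["subject_id"], session=meta["session"],
                     chronotype=meta["chronotype"], density=density)
            rows_global.append(g)
    local_tbl = pd.concat(rows_local, ignore_index=True)
    global_tbl = pd.DataFrame(rows_global)

    grid = np.asarray(config.densities)
    auc_rows = []
    for (sid, session, ct), grp in global_tbl.groupby(
            ["subject_id", "session", "chronotype"], sort=True):
        grp = grp.sort_values("density")
        for mname in GLOBAL_METRICS:
            vals = grp[mname].to_numpy()
            ok = np.isfinite(vals)
            auc = auc_over_thresholds(grid[ok], vals[ok]) if ok.sum() >= 2 else np.nan
            auc_rows.append(dict(subject_id=sid, session=session, chronotype=ct,
                                 scope="GLOBAL", region_id=0, metric=mname, auc=auc))
    for (sid, session, ct, rid), grp in local_tbl.groupby(
            ["subject_id", "session", "chronotype", "region_id"], sort=True):
        grp = grp.sort_values("density")
        for mname in NODAL_TEST_METRICS:
            vals = grp[mname].to_numpy()
            ok = np.isfinite(vals)
            auc = auc_over_thresholds(grid[ok], vals[ok]) if ok.sum() >= 2 else np.nan
            auc_rows.append(dict(subject_id=sid, session=session, chronotype=ct,
                                 scope="nodal", region_id=rid, metric=mname, auc=auc))
    auc_tbl = pd.DataFrame(auc_rows)

    (out / "metrics").mkdir(parents=True, exist_ok=True)
    local_tbl.to_csv(out / "metrics" / "local_metrics.csv", index=False)
    global_tbl.to_csv(out / "metrics" / "global_metrics.csv", index=False)
    auc_tbl.to_csv(out / "metrics" / "auc.csv", index=False)
    return local_tbl, global_tbl, auc_tbl


def stage_mesoscale(nets, parc, config: RunConfig, out: Path):
    """Per-session multilayer partitions, allegiance and R/I tables."""
    meso_dir = out / "mesoscale"
    meso_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    seed0 = config.substream("mesoscale")
    for session in SESSIONS:
        layers = [w for w in nets if w.meta["session"] == session]
        if not layers:
            continue
        if len(config.gamma_grid) * len(config.omega_grid) > 1:
            gs = grid_search_gamma_omega(layers, config.gamma_grid,
                                         config.omega_grid, seed=seed0,
                                         n_reps=config.n_reps)
            part = gs.partition
            gs.surface.to_csv(meso_dir / f"gridsearch_{session}.csv", index=False)
        else:
            part = optimize_multilayer(layers, gamma=config.gamma_grid[0],
                                       omega=config.omega_grid[0], seed=seed0,
                                       n_reps=config.n_reps)
        alle = allegiance_matrix(part, session=session)
        ri = recruitment_integration(alle, parc)
        sysmat = system_allegiance(alle, parc)
        sys_ri = system_recruitment_integration(sysmat)
        save_matrix_csv(alle.p, meso_dir / f"allegiance_{session}.csv", parc.labels)
        ri.to_csv(meso_dir / f"recruitment_integration_{session}.csv", index=False)
        save_matrix_csv(sysmat.p, meso_dir / f"system_allegiance_{session}.csv",
                        sysmat.names)
        sys_ri.to_csv(meso_dir / f"system_ri_{session}.csv", index=False)
        export_system_edges(sysmat).to_csv(meso_dir / f"chord_{session}.csv",
                                           index=False)
        results[session] = dict(partition=part, allegiance=alle, ri=ri,
                                system=sysmat, system_ri=sys_ri)
    return results


def stage_hubs(nets, parc, config: RunConfig, out: Path):
    hub_dir = out / "hubs"
    hub_dir.mkdir(parents=True, exist_ok=True)
    tables = {}
    for session in SESSIONS:
        layers = [w for w in nets if w.meta["session"] == session]
        if not layers:
            continue
        avg = group_average_network(layers)
        tbl = identify_hubs(avg, parc, density=config.hub_density,
                            connector_threshold=config.connector_threshold)
        tbl.insert(0, "session", session)
        tbl.to_csv(hub_dir / f"hubs_{session}.csv", index=False)
        connectogram_edges(avg, parc, config.hub_density).to_csv(
            hub_dir / f"connectogram_{session}.csv", index=False)
        tables[session] = tbl
    return tables


def _wide_by_session(tbl: pd.DataFrame, value: str, keys: list[str]):
    """Pivot a long table into aligned morning/evening matrices per subject."""
    wide = tbl.pivot_table(index="subject_id", columns=["session"] + keys,
                           values=value, sort=True)
    subjects = wide.index.to_numpy()
    cols = wide["morning"].columns
    return (subjects, cols,
            wide["morning"].to_numpy(), wide["evening"].to_numpy())


def stage_stats(local_tbl, global_tbl, auc_tbl, meso, design, config: RunConfig,
                out: Path):
    """Group statistics: mixed ANOVA + FDR + threshold consolidation,
    mesoscale session tests, covariate-controlled score correlations and
    cohort demographics tests."""
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    seed0 = config.substream("stats")
    subj = design.drop_duplicates("subject_id").set_index("subject_id")

    # --- global metrics: effect × metric × density -------------------------
    grows = []
    for mname in GLOBAL_METRICS:
        subjects, cols, morn, eve = _wide_by_session(
            global_tbl, mname, ["density"])
        group = subj.loc[subjects, "chronotype"].to_numpy()
        ok_cols = np.isfinite(morn).all(axis=0) & np.isfinite(eve).all(axis=0)
        res = {}
        if ok_cols.any():
            res = perm_mixed_anova_table(morn[:, ok_cols], eve[:, ok_cols],
                                         group, n_perm=config.n_perm, seed=seed0)
        for eff, (obs, pv) in res.items():
            for c, o, p in zip(np.asarray(cols)[ok_cols], obs, pv):
                grows.append(dict(effect=eff, metric=mname, density=c,
                                  statistic=o, p_perm=p))
        # densities with missing values (e.g. undefined assortativity):
        for c in np.asarray(cols)[~ok_cols]:
            sel = np.isfinite(morn[:, list(cols).index(c)]) & \
                  np.isfinite(eve[:, list(cols).index(c)])
            if sel.sum() >= 4 and len(np.unique(group[sel])) == 2:
                r = perm_mixed_anova(morn[sel, list(cols).index(c)],
                                     eve[sel, list(cols).index(c)], group[sel],
                                     n_perm=config.n_perm, seed=seed0)
                for eff, sr in r.items():
                    grows.append(dict(effect=eff, metric=mname, density=c,
                                      statistic=sr.statistic, p_perm=sr.p_perm))
    ganova = pd.DataFrame(grows)
    if len(ganova):
        parts = []
        for (eff, mname), grp in ganova.groupby(["effect", "metric"]):
            grp = grp.copy()
            p_adj, rej = bh_fdr(grp["p_perm"].to_numpy())
            grp["p_fdr"], grp["significant"] = p_adj, rej
            parts.append(grp)
        ganova = pd.concat(parts, ignore_index=True)
    ganova.to_csv(stats_dir / "global_anova.csv", index=False)

    # --- nodal metrics: effect × metric × density × region -----------------
    nrows = []
    for mname in NODAL_TEST_METRICS:
        for density in config.densities:
            sub = local_tbl[local_tbl["density"] == density]
            subjects, cols, morn, eve = _wide_by_session(sub, mname, ["region_id"])
            group = subj.loc[subjects, "chronotype"].to_numpy()
            ok = np.isfinite(morn).all(axis=0) & np.isfinite(eve).all(axis=0)
            if not ok.any():
                continue
            res = perm_mixed_anova_table(morn[:, ok], eve[:, ok], group,
                                         n_perm=config.n_perm, seed=seed0)
            rids = np.asarray(cols)[ok]
            for eff, (obs, pv) in res.items():
                p_adj, rej = bh_fdr(pv)  # family: regions, per metric×density
                for rid, o, p, pf, rj in zip(rids, obs, pv, p_adj, rej):
                    nrows.append(dict(effect=eff, metric=mname, density=density,
                                      region_id=int(rid), statistic=o,
                                      p_perm=p, p_fdr=pf, significant=rj))
    nanova = pd.DataFrame(nrows)
    nanova.to_csv(stats_dir / "nodal_anova.csv", index=False)

    # consolidation: significant in more than half of the densities
    crows = []
    if len(nanova):
        for (eff, mname, rid), grp in nanova.groupby(
                ["effect", "metric", "region_id"]):
            flags = grp["significant"].to_numpy()
            crows.append(dict(effect=eff, metric=mname, region_id=rid,
                              n_densities=len(flags),
                              n_significant=int(flags.sum()),
                              consolidated=consolidate_thresholds(flags)))
    consolidated = pd.DataFrame(crows)
    consolidated.to_csv(stats_dir / "consolidated.csv", index=False)

    # --- mesoscale session tests ------------------------------------------
    mrows = []
    if set(SESSIONS) <= set(meso):
        for coef in ("recruitment", "integration"):
            x = meso["morning"]["ri"][coef].to_numpy()
            y = meso["evening"]["ri"][coef].to_numpy()
            try:
                reg = perm_identity_regression(x, y, n_perm=config.n_perm,
                                               seed=seed0)
                mrows.append(dict(test="identity_regression", coefficient=coef,
                                  statistic=reg.statistic, p_perm=reg.p_perm))
            except ValueError:
                # degenerate session (e.g. constant coefficient): regression
                # against the identity line is undefined
                mrows.append(dict(test="identity_regression", coefficient=coef,
                                  statistic=np.nan, p_perm=np.nan))
            ow = perm_oneway(y, x, n_perm=config.n_perm, seed=seed0)
            mrows.append(dict(test="oneway_evening_minus_morning", coefficient=coef,
                              statistic=ow.statistic, p_perm=ow.p_perm))
    meso_tests = pd.DataFrame(mrows)
    if len(meso_tests):
        meso_tests["p_fdr"] = np.nan
        meso_tests["significant"] = False
        ok = np.isfinite(meso_tests["p_perm"].to_numpy())
        if ok.any():
            p_adj, rej = bh_fdr(meso_tests.loc[ok, "p_perm"].to_numpy())
            meso_tests.loc[ok, "p_fdr"] = p_adj
            meso_tests.loc[ok, "significant"] = rej
    meso_tests.to_csv(stats_dir / "mesoscale_tests.csv", index=False)

    # --- correlations with questionnaire scores ---------------------------
    cov_cols = [c for c in config.covariates if c in subj.columns]
    score_cols = [c for c in config.scores if c in subj.columns]
    corr_rows = []
    gauc = auc_tbl[auc_tbl["scope"] == "GLOBAL"]
    for session in SESSIONS:
        ses = gauc[gauc["session"] == session]
        for mname in GLOBAL_METRICS:
            v = ses[ses["metric"] == mname].set_index("subject_id")["auc"]
            v = v.dropna()
            if len(v) < len(cov_cols) + 4:
                continue
            cov = subj.loc[v.index, cov_cols] if cov_cols else None
            for score in score_cols:
                sr = perm_partial_correlation(
                    v.to_numpy(), subj.loc[v.index, score].to_numpy(),
                    covariates=cov, n_perm=config.n_perm, seed=seed0)
                corr_rows.append(dict(session=session, metric=mname, score=score,
                                      r=sr.statistic, p_perm=sr.p_perm))
    corr = pd.DataFrame(corr_rows)
    if len(corr):
        parts = []
        for session, grp in corr.groupby("session"):
            grp = grp.copy()
            grp["p_fdr"], grp["significant"] = bh_fdr(grp["p_perm"].to_numpy())
            parts.append(grp)
        corr = pd.concat(parts, ignore_index=True)
    corr.to_csv(stats_dir / "correlations_global.csv", index=False)

    # --- cohort demographics ----------------------------------------------
    demo = design.drop_duplicates("subject_id")
    ct = cohort_tests(demo)
    ct.to_csv(stats_dir / "cohort_tests.csv", index=False)

    return dict(global_anova=ganova, nodal_anova=nanova,
                consolidated=consolidated, mesoscale_tests=meso_tests,
                correlations=corr, cohort=ct)


# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    panels, design, parc = stage_data(config, out)
    nets = stage_networks(panels, parc, out)
    local_tbl, global_tbl, auc_tbl = stage_metrics(nets, parc, config, out)
    meso = stage_mesoscale(nets, parc, config, out)
    hub_tables = stage_hubs(nets, parc, config, out)
    stats_out = stage_stats(local_tbl, global_tbl, auc_tbl, meso, design,
                            config, out)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "n_subjects": int(design["subject_id"].nunique()),
        "n_panels": len(panels),
        "n_regions": parc.n_regions,
        "densities": list(config.densities),
        "rows": {
            "local_metrics": len(local_tbl),
            "global_metrics": len(global_tbl),
            "auc": len(auc_tbl),
            "global_anova": len(stats_out["global_anova"]),
            "nodal_anova": len(stats_out["nodal_anova"]),
            "consolidated": len(stats_out["consolidated"]),
            "mesoscale_tests": len(stats_out["mesoscale_tests"]),
            "correlations": len(stats_out["correlations"]),
        },
        "sessions_mesoscale": sorted(meso),
        "hub_sessions": sorted(hub_tables),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
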