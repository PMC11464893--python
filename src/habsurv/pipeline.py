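"""End-to-end orchestration: simulate -> design -> fit -> validate -> map.

A :class:`RunConfig` (YAML-loadable, schema-checked) drives the whole
chain on synthetic data; every run writes CSV/JSON artefacts plus a
manifest recording the config hash, seed and output checksums, so a rerun
with the same config is byte-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import design as dsg
from . import mapping as mp
from . import mcmc
from . import synthetic as syn
from . import validation as val
from .models import FittedRSF, FittedSurvival, summary_table

log = logging.getLogger("habsurv")

STAGES = ("simulate", "design", "fit-rsf", "fit-survival", "validate", "map", "rank")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    outdir: str = "runs/demo"
    seed: int = 1
    life_stages: tuple[str, ...] = ("nesting", "early_brood", "late_brood")
    nrows: int = 120
    ncols: int = 120
    n_animals: int = 60
    n_used: int = 250
    n_units: int = 150
    n_withheld: int = 8
    chains: int = 2
    iterations: int = 1500
    burnin: int = 750
    thin: int = 3
    year: int = 0
    check_interval: int = 10
    asui_radius_m: float = 2500.0
    survival_thresholds: tuple[float, float, float] | None = None
    write_rasters: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("life_stages", "survival_thresholds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        bad = set(cfg.life_stages) - set(syn.STAGE_DURATIONS)
        if bad:
            raise ValueError(f"unknown life stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


@dataclass
class RunContext:
    """In-memory objects passed between stages, plus the output manifest."""

    cfg: RunConfig
    world: object = None
    truth: object = None
    cache: dict = field(default_factory=dict)
    used: dict = field(default_factory=dict)        # stage -> used point table
    splits: dict = field(default_factory=dict)      # stage -> HoldoutSplit
    designs: dict = field(default_factory=dict)     # stage -> (table, scaling, specs, groups)
    histories: dict = field(default_factory=dict)   # stage -> (train_eh, test_eh, units)
    rsf: dict = field(default_factory=dict)         # stage -> FittedRSF
    surv: dict = field(default_factory=dict)        # stage -> FittedSurvival
    surfaces: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def record(self, stage: str, paths: list[str]) -> None:
        self.manifest.setdefault("stages", {})[stage] = {
            "outputs": {os.path.relpath(p, self.cfg.outdir): _checksum(p) for p in paths}
        }
        self.write_manifest()

    def write_manifest(self) -> None:
        self.manifest.update(config_hash=self.cfg.hash(), seed=self.cfg.seed,
                             config=dataclasses.asdict(self.cfg))
        with open(os.path.join(self.cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=list)


def _settings(cfg: RunConfig) -> mcmc.MCMCSettings:
    return mcmc.MCMCSettings(chains=cfg.chains, iterations=cfg.iterations,
                             burnin=cfg.burnin, thin=cfg.thin)


def _stage_specs(ctx: RunContext, stage: str) -> list[cov.CovariateSpec]:
    radii = syn.STAGE_RADII[stage]
    out = []
    for s in syn.default_covariate_specs():
        if s.kind in ("proportion", "height"):
            out.append(cov.CovariateSpec(s.name, s.group, s.kind,
                                         tuple(r for r in s.radii if r in radii),
                                         temporal=s.temporal))
        else:
            out.append(s)
    return out


def _safe_surv_cat(surface, failed_vals, hatched_vals, thresholds, mask):
    """Point-distribution survival thresholds, falling back to surface
    quartiles when the failed/successful medians coincide or invert
    (near-flat predicted surfaces cannot separate the two samples)."""
    try:
        return mp.categorize_survival(surface, failed_vals, hatched_vals,
                                      thresholds=thresholds, mask=mask)
    except ValueError as err:
        log.warning("survival thresholds degenerate (%s); using surface quartiles", err)
        vals = surface[mask] if mask is not None else surface
        thr = tuple(np.nanquantile(vals, (0.25, 0.5, 0.75)))
        return mp.categorize_survival(surface, failed_vals, hatched_vals,
                                      thresholds=thr, mask=mask)


# -- stages ----------------------------------------------------------------

def stage_simulate(ctx: RunContext) -> None:
    cfg = ctx.cfg
    sim = syn.SimConfig(nrows=cfg.nrows, ncols=cfg.ncols,
                        n_animals=cfg.n_animals, seed=cfg.seed)
    ctx.world = syn.generate_landscape(sim)
    ctx.truth = syn.realize_truth(sim, ctx.world)
    outs = []
    os.makedirs(cfg.outdir, exist_ok=True)
    if cfg.write_rasters:
        ctx.world.write(os.path.join(cfg.outdir, "landscape"))
    for stage in cfg.life_stages:
        used = syn.simulate_used_points(ctx.world, ctx.truth, stage,
                                        cfg.n_used, cache=ctx.cache)
        ctx.used[stage] = used
        p = os.path.join(cfg.outdir, f"used_{stage}.csv")
        used.to_csv(p, index=False)
        outs.append(p)
        units = syn.make_units(ctx.world, ctx.truth, stage, cfg.n_units,
                               cache=ctx.cache)
        eh = syn.simulate_fates(units, ctx.truth, stage,
                                check_interval=cfg.check_interval)
        ctx.histories[stage] = {"units": units, "eh": eh}
        p = os.path.join(cfg.outdir, f"encounter_{stage}.csv")
        eh.to_csv(p, index=False)
        outs.append(p)
    ctx.record("simulate", outs)


def stage_design(ctx: RunContext) -> None:
    cfg = ctx.cfg
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD351]))
    outs = []
    for stage in cfg.life_stages:
        used = ctx.used[stage]
        split = val.holdout_split(used, "animal",
                                  min(cfg.n_withheld, used["animal"].nunique() - 2),
                                  rng=rng)
        ctx.splits[stage] = split
        anchors = ctx.truth.animals.rename(
            columns={"lek_x" if stage == "nesting" else "nest_x": "x",
                     "lek_y" if stage == "nesting" else "nest_y": "y"}
        )[["animal", "x", "y"]]
        dists = ctx.truth.movement_distances(stage)
        specs = cov.resolve_decay_alphas(split.train, ctx.world,
                                         _stage_specs(ctx, stage))
        table = dsg.sample_available(split.train, anchors, dists,
                                     stack=ctx.world, rng=rng)
        table = cov.attach_covariates(table, ctx.world, specs, cache=ctx.cache)
        groups = cov.candidate_columns(specs)
        cols = [c for cands in groups.values() for c in cands] + ["dist_anchor"]
        table, scaling = cov.scale_and_center(table, cols)
        # withheld animals: same covariates, scaled with the training params
        test = cov.attach_covariates(split.test, ctx.world, specs, cache=ctx.cache)
        test = cov.apply_scaling(test, scaling)
        ctx.designs[stage] = {"table": table, "scaling": scaling,
                              "specs": specs, "groups": groups, "test": test}
        p = os.path.join(cfg.outdir, f"design_{stage}.csv")
        table.to_csv(p, index=False)
        outs.append(p)
        # survival design: scaled candidate columns joined onto the
        # already-simulated encounter history by unit id
        units = ctx.histories[stage]["units"]
        ucov = cov.attach_covariates(units[["unit", "x", "y", "year"]].copy(),
                                     ctx.world, specs, cache=ctx.cache)
        ucov = cov.apply_scaling(ucov, scaling)
        cand_cols = [c for cands in groups.values() for c in cands]
        eh = ctx.histories[stage]["eh"]
        eh_design = eh.drop(columns=[c for c in eh.columns if c in cand_cols])
        eh_design = eh_design.merge(ucov[["unit", *cand_cols]], on="unit")
        ctx.histories[stage]["eh_design"] = eh_design
    ctx.record("design", outs)


def _fit_family(ctx: RunContext, stage: str, family: str):
    cfg = ctx.cfg
    d = ctx.designs[stage]
    settings = _settings(cfg)
    if family == "rsf":
        data, scaling = d["table"], d["scaling"]
        spec = mcmc.ModelSpec("logistic", fixed=("dist_anchor",),
                              groups={g: list(c) for g, c in d["groups"].items()},
                              random=("site", "year", "animal"))
        seed = ctx.cfg.seed * 1000 + hash(stage) % 997
    else:
        data = ctx.histories[stage]["eh_design"]
        scaling = d["scaling"]
        spec = mcmc.ModelSpec("exposure",
                              groups={g: list(c) for g, c in d["groups"].items()},
                              random=("site", "year"))
        seed = ctx.cfg.seed * 1000 + 500 + hash(stage) % 997
    seed = abs(seed) % (2**31)
    selection, _ = mcmc.bliss_select(spec, data, settings, seed=seed)
    final = mcmc.final_spec_from_bliss(spec, selection)
    draws = mcmc.fit(final, data, settings, seed=seed + 1)
    winners = [selection[g]["winner"] for g in spec.groups]
    if family == "rsf":
        fitted = FittedRSF(draws=draws, covariates=list(final.fixed),
                           scaling=scaling, stage=stage,
                           confounders=("dist_anchor",))
        ctx.rsf[stage] = fitted
    else:
        fitted = FittedSurvival(draws=draws, covariates=winners, scaling=scaling,
                                stage=stage, duration=syn.STAGE_DURATIONS[stage])
        ctx.surv[stage] = fitted
    p = os.path.join(cfg.outdir, f"{family}_{stage}_summary.csv")
    summary_table(fitted).to_csv(p, index=False)
    pj = os.path.join(cfg.outdir, f"{family}_{stage}_selection.json")
    with open(pj, "w") as fh:
        json.dump({"bliss": selection,
                   "convergence": mcmc.gelman_rubin(draws)
                   if cfg.chains >= 2 else None}, fh, indent=2)
    return [p, pj]


def stage_fit_rsf(ctx: RunContext) -> None:
    outs = []
    for stage in ctx.cfg.life_stages:
        outs += _fit_family(ctx, stage, "rsf")
    ctx.record("fit-rsf", outs)


def stage_fit_survival(ctx: RunContext) -> None:
    outs = []
    for stage in ctx.cfg.life_stages:
        outs += _fit_family(ctx, stage, "survival")
    ctx.record("fit-survival", outs)


def stage_validate(ctx: RunContext) -> None:
    cfg = ctx.cfg
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A1]))
    report = {}
    for stage in cfg.life_stages:
        d = ctx.designs[stage]
        fitted = ctx.rsf[stage]
        covs = [c for c in fitted.covariates if c not in fitted.confounders]
        beta = pd.DataFrame({c: fitted.draws.stacked(f"beta_{c}") for c in covs})
        avail = d["table"][d["table"]["used"] == 0]
        test_used = d["test"]
        w_avail = np.exp(avail[covs].to_numpy(float) @
                         np.array([fitted.coefficient_medians()[c] for c in covs]))
        w_test = np.exp(test_used[covs].to_numpy(float) @
                        np.array([fitted.coefficient_medians()[c] for c in covs]))
        cv = val.rsf_cross_validate(w_avail, w_test)
        uhc = val.uhc_plot(beta, avail, test_used, covs, rng=rng)
        eh = ctx.histories[stage]["eh_design"]
        unit_ids = pd.unique(eh["unit"])
        test_units = rng.choice(unit_ids, size=max(5, len(unit_ids) // 5),
                                replace=False)
        eh_test = eh[eh["unit"].isin(test_units)]
        sfit = ctx.surv[stage]
        gdraws = pd.DataFrame({"intercept": sfit.draws.stacked("intercept"),
                               **{c: sfit.draws.stacked(f"beta_{c}")
                                  for c in sfit.covariates}})
        ppc = val.survival_ppc(gdraws, eh_test, sfit.covariates, rng=rng)
        report[stage] = {
            "rsf_cv": {k: cv[k] for k in ("rho", "r2", "slope", "bins_used")},
            "uhc_coverage": {c: u["coverage"] for c, u in uhc.items()},
            "survival_ppc": {k: ppc[k] for k in
                             ("p_value", "observed_discrepancy",
                              "replicated_discrepancy")},
        }
    p = os.path.join(cfg.outdir, "validation.json")
    with open(p, "w") as fh:
        json.dump(report, fh, indent=2)
    ctx.record("validate", [p])


def stage_map(ctx: RunContext) -> None:
    cfg = ctx.cfg
    outs = []
    sel_surfaces, surv_surfaces, sel_cats = [], [], {}
    for stage in cfg.life_stages:
        d = ctx.designs[stage]
        surf = mp.predict_selection(ctx.rsf[stage], ctx.world, d["specs"],
                                    year=cfg.year, cache=ctx.cache)
        used_tr = d["table"][d["table"]["used"] == 1]
        hsi_at_used = surf.hsi[ctx.world.xy_to_rowcol(
            used_tr["x"].to_numpy(float), used_tr["y"].to_numpy(float))]
        cat = mp.categorize_selection(surf, hsi_at_used)
        ssurf = mp.predict_survival(ctx.surv[stage], ctx.world, d["specs"],
                                    year=cfg.year, cache=ctx.cache)
        eh = ctx.histories[stage]["eh_design"]
        fates = eh.groupby("unit")["y"].min()
        units = ctx.histories[stage]["units"].set_index("unit")
        fx = units.loc[fates[fates == 0].index]
        hx = units.loc[fates[fates == 1].index]
        def at(surface, tab):
            return surface[ctx.world.xy_to_rowcol(tab["x"].to_numpy(float),
                                                  tab["y"].to_numpy(float))]
        scat = _safe_surv_cat(ssurf, at(ssurf, fx), at(ssurf, hx),
                              cfg.survival_thresholds, cat.classes >= 1)
        sel_surfaces.append(surf)
        surv_surfaces.append(ssurf)
        sel_cats[stage] = (cat, scat)
        for name, cs in (("selection", cat), ("survival", scat)):
            p = os.path.join(cfg.outdir, f"map_{name}_{stage}.csv")
            mp.area_summary(cs.classes, cs.labels, ctx.world.pixel_size).to_csv(
                p, index=False)
            outs.append(p)
    comp_sel = mp.composite_selection(sel_surfaces)
    pooled_used = np.concatenate([
        comp_sel[ctx.world.xy_to_rowcol(
            ctx.designs[s]["table"].query("used == 1")["x"].to_numpy(float),
            ctx.designs[s]["table"].query("used == 1")["y"].to_numpy(float))]
        for s in cfg.life_stages])
    comp_sel_cat = mp.categorize_selection(comp_sel, pooled_used)
    comp_surv = mp.composite_survival(surv_surfaces,
                                      habitat_mask=comp_sel_cat.classes >= 1)
    fx_vals = np.concatenate([
        comp_surv[ctx.world.xy_to_rowcol(
            ctx.histories[s]["units"]["x"].to_numpy(float),
            ctx.histories[s]["units"]["y"].to_numpy(float))]
        for s in cfg.life_stages])
    # pooled fates across stages for the composite thresholds
    pooled_failed, pooled_hatched = [], []
    for s in cfg.life_stages:
        eh = ctx.histories[s]["eh_design"]
        fates = eh.groupby("unit")["y"].min()
        units = ctx.histories[s]["units"].set_index("unit")
        vals = comp_surv[ctx.world.xy_to_rowcol(
            units["x"].to_numpy(float), units["y"].to_numpy(float))]
        vs = pd.Series(vals, index=units.index)
        pooled_failed.append(vs[fates[fates == 0].index].dropna().to_numpy())
        pooled_hatched.append(vs[fates[fates == 1].index].dropna().to_numpy())
    comp_surv_cat = _safe_surv_cat(
        comp_surv, np.concatenate(pooled_failed), np.concatenate(pooled_hatched),
        cfg.survival_thresholds, comp_sel_cat.classes >= 1)
    del fx_vals
    ctx.surfaces = {"per_stage": sel_cats, "composite_selection": comp_sel_cat,
                    "composite_survival": comp_surv_cat,
                    "comp_sel": comp_sel, "comp_surv": comp_surv}
    for name, cs in (("selection_composite", comp_sel_cat),
                     ("survival_composite", comp_surv_cat)):
        p = os.path.join(cfg.outdir, f"map_{name}.csv")
        mp.area_summary(cs.classes, cs.labels, ctx.world.pixel_size).to_csv(
            p, index=False)
        outs.append(p)
    ctx.record("map", outs)


def stage_rank(ctx: RunContext) -> None:
    cfg = ctx.cfg
    ranked = mp.rank_overlay(ctx.surfaces["composite_selection"],
                             ctx.surfaces["composite_survival"],
                             pixel_size=ctx.world.pixel_size)
    p1 = os.path.join(cfg.outdir, "rank_areas.csv")
    ranked.areas.to_csv(p1, index=False)
    asui = ctx.world.bands["dist_lek"] < cfg.asui_radius_m
    mgmt = mp.management_categories(ctx.surfaces["composite_selection"], asui,
                                    ctx.surfaces["composite_survival"])
    p2 = os.path.join(cfg.outdir, "management_areas.csv")
    mp.area_summary(mgmt, mp.MANAGEMENT_CLASSES, ctx.world.pixel_size).to_csv(
        p2, index=False)
    ctx.record("rank", [p1, p2])


_STAGE_FUNCS = {"simulate": stage_simulate, "design": stage_design,
                "fit-rsf": stage_fit_rsf, "fit-survival": stage_fit_survival,
                "validate": stage_validate, "map": stage_map, "rank": stage_rank}


def run_pipeline(cfg: RunConfig, upto: str | None = None) -> RunContext:
    """Run stages in order (optionally stopping at ``upto``); returns the
    context holding all in-memory artefacts and the manifest path."""
    if upto is not None and upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; stages are {STAGES}")
    os.makedirs(cfg.outdir, exist_ok=True)
    ctx = RunContext(cfg=cfg)
    for stage in STAGES:
        log.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](ctx)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        if stage == upto:
            break
    return ctx
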