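"""Synthetic landscapes, telemetry, and reproductive fates with known truth.

This module emulates the study system — a sagebrush-steppe landscape with
lek-centred breeding, nest and brood telemetry, and interval-censored fate
monitoring — so that every downstream stage (covariate engineering, design
construction, MCMC fitting, validation, mapping) can be tested against a
known generating process without any restricted data.

The generative model mirrors the inferential one:

* continuous covariates are spatially autocorrelated Gaussian random
  fields (kernel-convolution synthesis), land-cover fractions squashed to
  (0, 1); point/line features (leks, streams, springs) yield Euclidean
  distance bands;
* used locations are drawn with probability proportional to
  ``exp(X beta_true)`` within each animal's availability disc;
* nest/brood fates follow daily Bernoulli survival with
  ``logit(DS) = gamma0 + X beta + site + year`` random intercepts, observed
  only at periodic checks (interval-censored encounter histories).

All randomness flows from a single seed through named substreams, so every
artefact is bit-for-bit reproducible from :class:`SimConfig`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .covariates import CovariateSpec, attach_covariates, scaled_band_name
from .landscape import LandscapeStack

__all__ = [
    "STAGE_DURATIONS",
    "FieldSpec",
    "SimConfig",
    "SimTruth",
    "generate_landscape",
    "realize_truth",
    "simulate_used_points",
    "simulate_fates",
]

#: Stage-specific exposure durations in days (nesting; early and late brood).
STAGE_DURATIONS = {"nesting": 38, "early_brood": 21, "late_brood": 28}


@dataclass(frozen=True)
class FieldSpec:
    """One synthetic raster band: Gaussian random field or constant.

    ``range_px`` is the autocorrelation range (Gaussian smoothing radius, in
    pixels); ``sill`` the marginal variance; ``kind='proportion'`` squashes
    the field through a logistic so values live in (0, 1); ``temporal``
    fields get one band per simulated year sharing a persistent base field.
    """

    range_px: float = 6.0
    sill: float = 1.0
    constant: float | None = None
    kind: str = "continuous"  # or "proportion"
    temporal: bool = False


def _default_fields() -> dict[str, FieldSpec]:
    """Bands emulating the 12 covariate groups of the study's input layers."""
    return {
        "sagebrush": FieldSpec(8, 1.0, kind="proportion"),
        "sagebrush_height": FieldSpec(8, 1.0),
        "herbaceous": FieldSpec(6, 1.0, kind="proportion"),
        "wet_meadow": FieldSpec(4, 1.0, kind="proportion"),
        "bare_ground": FieldSpec(6, 1.0, kind="proportion"),
        "annual_grass": FieldSpec(6, 1.0, kind="proportion", temporal=True),
        "conifer": FieldSpec(10, 1.0, kind="proportion"),
        "burned": FieldSpec(12, 1.0, kind="proportion", temporal=True),
        "saline_lake": FieldSpec(10, 1.0, kind="proportion"),
        "elevation": FieldSpec(20, 1.0),
        "slope": FieldSpec(5, 1.0),
        "roughness": FieldSpec(5, 1.0),
        "hli": FieldSpec(7, 1.0),
        "cti": FieldSpec(7, 1.0),
    }


#: Candidate window radii by life stage: all stages use the min / mean /
#: max daily-movement radii; nesting adds the recess-core (75 m) and
#: recess-movement (260 m) scales, early brood 260 m, late brood 370 m.
STAGE_RADII = {
    "nesting": (75.0, 167.9, 260.0, 439.5, 1451.7),
    "early_brood": (167.9, 260.0, 439.5, 1451.7),
    "late_brood": (167.9, 370.0, 439.5, 1451.7),
}


def default_covariate_specs() -> list[CovariateSpec]:
    """CovariateSpecs for the default landscape, one of 12 groups each.

    Windowed covariates carry the union of all stage candidate radii; a
    per-stage analysis restricts to :data:`STAGE_RADII`.
    """
    radii = (75.0, 167.9, 260.0, 370.0, 439.5, 1451.7)
    return [
        CovariateSpec("sagebrush", "shrubs", "proportion", radii),
        CovariateSpec("sagebrush_height", "shrubs", "height", radii),
        CovariateSpec("herbaceous", "herbaceous_meadows", "proportion", radii),
        CovariateSpec("wet_meadow", "herbaceous_meadows", "proportion", radii),
        CovariateSpec("bare_ground", "bare_ground", "proportion", radii),
        CovariateSpec("annual_grass", "annual_grass", "proportion", radii, temporal=True),
        CovariateSpec("conifer", "conifer", "proportion", radii),
        CovariateSpec("burned", "burned", "proportion", radii, temporal=True),
        CovariateSpec("dist_stream", "streams", "distance"),
        CovariateSpec("dist_spring", "springs", "distance"),
        CovariateSpec("saline_lake", "saline_lakes", "proportion", radii),
        CovariateSpec("elevation", "elevation", "topographic"),
        CovariateSpec("slope", "topography", "topographic"),
        CovariateSpec("roughness", "topography", "topographic"),
        CovariateSpec("hli", "temperature_moisture", "topographic"),
        CovariateSpec("cti", "temperature_moisture", "topographic"),
    ]


def _default_selection() -> dict[str, dict[str, float]]:
    return {
        "nesting": {"sagebrush_height_439.5": 0.8, "elevation": 0.5,
                    "conifer_439.5": -0.7, "bare_ground_439.5": -0.4},
        "early_brood": {"sagebrush_height_260": 0.6, "elevation": 0.4,
                        "wet_meadow_260": -0.3},
        "late_brood": {"sagebrush_height_370": 0.6, "herbaceous_370": 0.4,
                       "conifer_370": -0.5},
    }


def _default_survival() -> dict[str, dict[str, float]]:
    # Intercepts chosen so stage cumulative survival matches field-typical
    # values: 0.9749^38 ~ 0.38 (nesting), 0.9940^(21+28) ~ 0.74 (broods).
    return {
        "nesting": {"intercept": 3.64, "sagebrush_439.5": 0.2, "roughness": 0.15},
        "early_brood": {"intercept": 5.11, "burned_439.5": 0.15},
        "late_brood": {"intercept": 5.11, "slope": 0.15},
    }


@dataclass
class SimConfig:
    """Ground-truth configuration for the synthetic study system."""

    nrows: int = 160
    ncols: int = 160
    pixel_size: float = 30.0
    n_sites: int = 4
    n_years: int = 3
    n_animals: int = 60
    fields: dict[str, FieldSpec] = field(default_factory=_default_fields)
    n_leks: int = 6
    n_streams: int = 4
    n_springs: int = 25
    selection_coefs: dict[str, dict[str, float]] = field(default_factory=_default_selection)
    survival_coefs: dict[str, dict[str, float]] = field(default_factory=_default_survival)
    sd_site: float = 0.3
    sd_year: float = 0.2
    sd_animal: float = 0.2
    availability_radius: float = 1500.0
    max_window_radius: float = 1451.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def substream(self, name: str) -> np.random.Generator:
        """Named, reproducible child RNG derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        )


def _grf(rng: np.random.Generator, shape, spec: FieldSpec) -> np.ndarray:
    """Gaussian random field by kernel-convolution of white noise."""
    if spec.constant is not None:
        return np.full(shape, float(spec.constant))
    z = rng.standard_normal(shape)
    if spec.range_px > 0:
        z = ndimage.gaussian_filter(z, sigma=spec.range_px, mode="reflect")
    z = (z - z.mean()) / z.std()
    z = z * np.sqrt(spec.sill)
    return expit(z) if spec.kind == "proportion" else z


def _random_walk_line(rng, nrows, ncols, n_steps=None) -> np.ndarray:
    """Rasterized meandering polyline (stream); returns boolean mask."""
    mask = np.zeros((nrows, ncols), bool)
    n_steps = n_steps or (nrows + ncols)
    r = rng.integers(0, nrows)
    c = 0 if rng.random() < 0.5 else ncols - 1
    drift = 1 if c == 0 else -1
    for _ in range(n_steps):
        if 0 <= r < nrows and 0 <= c < ncols:
            mask[r, c] = True
        else:
            break
        step = rng.choice([-1, 0, 1])
        r += step
        c += drift if rng.random() < 0.8 else 0
    return mask


def generate_landscape(config: SimConfig) -> LandscapeStack:
    """Build the synthetic landscape: covariate bands, features, distances.

    Continuous bands are one Gaussian random field each (one per year for
    temporal fields, sharing a persistent base); leks and springs are random
    interior points; streams are meandering rasterized polylines.  Euclidean
    distance bands ``dist_lek``, ``dist_stream``, ``dist_spring`` (metres)
    are derived from the features.
    """
    min_dim_m = min(config.nrows, config.ncols) * config.pixel_size
    if min_dim_m < 2 * config.max_window_radius:
        raise ValueError(
            f"grid ({min_dim_m:g} m across) cannot contain the largest "
            f"moving-window radius ({config.max_window_radius:g} m)"
        )
    shape = (config.nrows, config.ncols)
    bands: dict[str, np.ndarray] = {}
    for name, fspec in config.fields.items():
        rng = config.substream(f"field:{name}")
        if fspec.temporal and fspec.constant is None:
            base = _grf(rng, shape, FieldSpec(fspec.range_px, fspec.sill))
            for yr in range(config.n_years):
                innov = _grf(rng, shape, FieldSpec(fspec.range_px, fspec.sill))
                z = np.sqrt(0.8) * base + np.sqrt(0.2) * innov
                bands[f"{name}@{yr}"] = expit(z) if fspec.kind == "proportion" else z
        else:
            arr = _grf(rng, shape, fspec)
            if fspec.temporal:
                for yr in range(config.n_years):
                    bands[f"{name}@{yr}"] = arr
            else:
                bands[name] = arr

    px = config.pixel_size
    origin = (0.0, config.nrows * px)
    rng = config.substream("features")
    margin = 0.15
    features: dict[str, np.ndarray] = {}
    for fname, count in (("leks", config.n_leks), ("springs", config.n_springs)):
        xs = rng.uniform(margin * config.ncols * px, (1 - margin) * config.ncols * px, count)
        ys = rng.uniform(margin * config.nrows * px, (1 - margin) * config.nrows * px, count)
        features[fname] = np.column_stack([xs, ys])
    stream_mask = np.zeros(shape, bool)
    for _ in range(config.n_streams):
        stream_mask |= _random_walk_line(rng, config.nrows, config.ncols)
    sr, sc = np.nonzero(stream_mask)
    stack = LandscapeStack(bands=bands, pixel_size=px, origin=origin, features=features)
    sx, sy = stack.rowcol_to_xy(sr, sc)
    features["stream_px"] = np.column_stack([sx, sy])
    bands["stream_mask"] = stream_mask.astype(float)

    def dist_band(point_mask: np.ndarray) -> np.ndarray:
        return ndimage.distance_transform_edt(~point_mask) * px

    for fname, out in (("leks", "dist_lek"), ("springs", "dist_spring")):
        mask = np.zeros(shape, bool)
        r, c = stack.xy_to_rowcol(features[fname][:, 0], features[fname][:, 1])
        mask[r, c] = True
        bands[out] = dist_band(mask)
    bands["dist_stream"] = dist_band(stream_mask)
    return stack


@dataclass
class SimTruth:
    """Realized ground truth: coefficients, intercepts, units, scalings.

    Everything a recovery test needs to score an estimate: the true
    selection and survival coefficients, the realized random-intercept
    values, map-wide covariate scalings used by the generative model, the
    animal roster with lek/nest anchors, and per-call generation logs.
    """

    config: SimConfig
    animals: pd.DataFrame
    site_effects: dict[str, np.ndarray]
    year_effects: dict[str, np.ndarray]
    animal_effects: dict[str, np.ndarray]
    field_scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    specs: list[CovariateSpec] = field(default_factory=default_covariate_specs)
    logs: dict[str, dict] = field(default_factory=dict)

    @property
    def selection_coefs(self) -> dict[str, dict[str, float]]:
        return self.config.selection_coefs

    @property
    def survival_coefs(self) -> dict[str, dict[str, float]]:
        return self.config.survival_coefs

    def substream(self, name: str) -> np.random.Generator:
        return self.config.substream(name)

    def true_daily_survival(self, stage: str, row: pd.Series | None = None) -> float:
        """True DS for a unit, habitat effects and intercepts included."""
        coefs = self.survival_coefs[stage]
        eta = coefs.get("intercept", 0.0)
        if row is not None:
            for name, beta in coefs.items():
                if name != "intercept":
                    eta += beta * row[name]
            if "site" in row.index:
                eta += self.site_effects[stage][int(row["site"])]
            if "year" in row.index:
                eta += self.year_effects[stage][int(row["year"])]
        return float(expit(eta))

    def specs_for(self, coef_names) -> list[CovariateSpec]:
        """Minimal CovariateSpec list producing exactly ``coef_names`` columns."""
        out = []
        for spec in self.specs:
            if spec.kind in ("proportion", "height"):
                radii = tuple(
                    r for r in spec.radii
                    if scaled_band_name(spec.name, r) in coef_names
                )
                if radii:
                    out.append(CovariateSpec(spec.name, spec.group, spec.kind,
                                             radii, temporal=spec.temporal))
            elif spec.name in coef_names:
                out.append(spec)
        return out

    def movement_distances(self, stage: str, n: int = 200) -> np.ndarray:
        """Synthetic daily movement distances whose 90th percentile equals
        the configured availability radius (lognormal, CV ~ 0.75)."""
        rng = self.substream(f"movement:{stage}")
        sigma = 0.7
        mu = np.log(self.config.availability_radius) - 1.2816 * sigma
        return rng.lognormal(mu, sigma, n)


def realize_truth(config: SimConfig, stack: LandscapeStack,
                  specs: list[CovariateSpec] | None = None) -> SimTruth:
    """Assign animals to sites/leks/years, draw random intercepts, and
    record the map-wide covariate scalings the generative model uses."""
    rng = config.substream("truth")
    n = config.n_animals
    sites = rng.integers(0, config.n_sites, n)
    years = rng.integers(0, config.n_years, n)
    leks = stack.features.get("leks")
    if leks is None or len(leks) == 0:
        raise ValueError("landscape has no leks to anchor animals on")
    lek_ix = rng.integers(0, len(leks), n)
    # Nest anchor: drawn uniformly within half the availability radius of the lek.
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = config.availability_radius * 0.5 * np.sqrt(rng.uniform(0, 1, n))
    nest_x = leks[lek_ix, 0] + rad * np.cos(theta)
    nest_y = leks[lek_ix, 1] + rad * np.sin(theta)
    inside = stack.contains(nest_x, nest_y)
    nest_x = np.where(inside, nest_x, leks[lek_ix, 0])
    nest_y = np.where(inside, nest_y, leks[lek_ix, 1])
    animals = pd.DataFrame({
        "animal": np.arange(n), "site": sites, "year": years,
        "lek_x": leks[lek_ix, 0], "lek_y": leks[lek_ix, 1],
        "nest_x": nest_x, "nest_y": nest_y,
    })
    stages = list(STAGE_DURATIONS)
    site_eff = {s: config.sd_site * rng.standard_normal(config.n_sites) for s in stages}
    year_eff = {s: config.sd_year * rng.standard_normal(config.n_years) for s in stages}
    anim_eff = {s: config.sd_animal * rng.standard_normal(n) for s in stages}
    return SimTruth(config=config, animals=animals, site_effects=site_eff,
                    year_effects=year_eff, animal_effects=anim_eff,
                    specs=specs if specs is not None else default_covariate_specs())


def _truth_covariates(stack, truth: SimTruth, table: pd.DataFrame,
                      coef_names, cache) -> pd.DataFrame:
    """Attach and map-standardize exactly the truth-model covariates."""
    specs = [
        CovariateSpec(s.name, s.group, s.kind, s.radii,
                      float(np.mean(stack.bands[s.name])), s.temporal)
        if s.kind == "distance" and s.decay_alpha is None else s
        for s in truth.specs_for(coef_names)
    ]
    out = attach_covariates(table, stack, specs, cache=cache)
    for name in coef_names:
        if name == "intercept":
            continue
        if name not in out:
            raise KeyError(f"truth coefficient {name!r} has no matching covariate spec")
        if name not in truth.field_scaling:
            vals = out[name].to_numpy(float)
            truth.field_scaling[name] = (float(vals.mean()), float(vals.std()) or 1.0)
        mu, sd = truth.field_scaling[name]
        out[name] = (out[name] - mu) / sd
    return out


def simulate_used_points(stack: LandscapeStack, truth: SimTruth, stage: str,
                         n: int, cache: dict | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``n`` used locations with probability ``exp(X beta_true)``.

    Each point is attributed to an animal (round-robin over the roster) and
    drawn from the pixels whose centers lie within the availability radius
    of that animal's anchor (lek for nesting, nest for brood stages), with
    uniform jitter inside the chosen pixel.  Returns columns
    ``x, y, site, year, animal, stage``.
    """
    if stage not in truth.selection_coefs:
        raise KeyError(f"unknown life stage {stage!r}")
    cols = ["x", "y", "site", "year", "animal", "stage"]
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=(float if c in "xy" else object))
                             for c in cols})
    coefs = truth.selection_coefs[stage]
    rng = truth.substream(f"used:{stage}") if rng is None else rng
    cache = {} if cache is None else cache
    anchors = ("lek_x", "lek_y") if stage == "nesting" else ("nest_x", "nest_y")
    counts = np.bincount(np.arange(n) % len(truth.animals), minlength=len(truth.animals))
    radius = truth.config.availability_radius
    px = truth.config.pixel_size
    nr, nc = stack.shape
    frames = []
    for arow, k in zip(truth.animals.itertuples(index=False), counts):
        if k == 0:
            continue
        ax, ay = getattr(arow, anchors[0]), getattr(arow, anchors[1])
        r0, c0 = stack.xy_to_rowcol(ax, ay)
        half = int(np.ceil(radius / px)) + 1
        rr, cc = np.mgrid[max(0, r0 - half):min(nr, r0 + half + 1),
                          max(0, c0 - half):min(nc, c0 + half + 1)]
        rr, cc = rr.ravel(), cc.ravel()
        cx, cy = stack.rowcol_to_xy(rr, cc)
        keep = np.hypot(cx - ax, cy - ay) <= radius
        if not keep.any():
            raise ValueError("availability disc contains no raster pixels")
        cand = pd.DataFrame({"x": cx[keep], "y": cy[keep],
                             "year": getattr(arow, "year")})
        cand = _truth_covariates(stack, truth, cand, list(coefs), cache)
        eta = np.zeros(len(cand))
        for name, beta in coefs.items():
            eta += beta * cand[name].to_numpy(float)
        w = np.exp(eta - eta.max())
        tot = w.sum()
        if not np.isfinite(tot) or tot <= 0:
            raise ValueError("all candidate selection weights are zero")
        idx = rng.choice(len(cand), size=k, p=w / tot)
        jit = rng.uniform(-0.5, 0.5, (k, 2)) * px
        frames.append(pd.DataFrame({
            "x": cand["x"].to_numpy()[idx] + jit[:, 0],
            "y": cand["y"].to_numpy()[idx] + jit[:, 1],
            "site": getattr(arow, "site"), "year": getattr(arow, "year"),
            "animal": getattr(arow, "animal"), "stage": stage,
        }))
    out = pd.concat(frames, ignore_index=True)
    truth.logs[f"used:{stage}"] = {"n": int(n), "animals": int((counts > 0).sum())}
    return out


def simulate_fates(units: pd.DataFrame, truth: SimTruth, stage: str,
                   check_interval: int = 10, duration: int | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Interval-censored encounter histories from daily Bernoulli survival.

    Each unit survives day ``d`` with probability ``DS`` where
    ``logit(DS) = gamma0 + X beta + site + year``; checks occur every
    ``check_interval`` days (final check at ``duration``).  The failure day
    itself is unobserved: a failure is recorded against the whole interval
    containing it, and no later intervals exist for that unit.  Returns
    columns ``unit, entry, exit, t, y, site, year, stage`` plus any
    covariate columns present on ``units``.
    """
    duration = STAGE_DURATIONS.get(stage, duration) if duration is None else duration
    if duration is None or duration <= 0:
        raise ValueError("duration must be a positive number of days")
    if check_interval <= 0:
        raise ValueError("check_interval must be positive")
    if stage not in truth.survival_coefs:
        raise KeyError(f"unknown life stage {stage!r}")
    rng = truth.substream(f"fates:{stage}") if rng is None else rng
    checks = np.arange(check_interval, duration + 1, check_interval)
    if len(checks) == 0 or checks[-1] < duration:
        checks = np.append(checks, duration)
    records = []
    carry = [c for c in units.columns if c not in ("x", "y")]
    for _, row in units.iterrows():
        ds = truth.true_daily_survival(stage, row)
        if ds >= 1.0:
            fail_day = np.inf
        else:
            fail_day = rng.geometric(1.0 - ds)  # first day that fails
        entry = 0
        for exit_day in checks:
            rec = {c: row[c] for c in carry}
            rec.update(entry=entry, exit=int(exit_day), t=int(exit_day - entry),
                       stage=stage)
            if fail_day <= exit_day:
                rec["y"] = 0
                records.append(rec)
                break
            rec["y"] = 1
            records.append(rec)
            entry = int(exit_day)
    eh = pd.DataFrame.from_records(records)
    front = ["unit", "entry", "exit", "t", "y", "site", "year", "stage"]
    cols = [c for c in front if c in eh.columns] + [c for c in eh.columns if c not in front]
    truth.logs[f"fates:{stage}"] = {"units": int(len(units)), "duration": int(duration)}
    return eh[cols]


def make_units(stack: LandscapeStack, truth: SimTruth, stage: str,
               n: int, cache: dict | None = None) -> pd.DataFrame:
    """Nest/brood unit table with truth-model covariates at unit locations.

    Units are placed by drawing used points under the stage's selection
    truth, so survival units occupy selected habitat as in the field.
    """
    pts = simulate_used_points(stack, truth, stage, n, cache=cache)
    pts = pts.rename(columns={"animal": "unit"})
    coef_names = [c for c in truth.survival_coefs[stage] if c != "intercept"]
    pts["unit"] = np.arange(len(pts))
    if coef_names:
        pts = _truth_covariates(stack, truth, pts, coef_names, cache or {})
    return pts
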