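"""Spatial prediction, categorization, ranking and management overlays.

Selection surfaces are habitat selection indices HSI = w / (1 + w) with
w = exp(X beta) (posterior-median coefficients; no intercept, no random
effects, no distance confounders), categorized by the percent-isopleth
method: thresholds at the HSI values containing the top 50 / 25 / 5
percent of used locations.  Survival surfaces are cumulative stage
survival DS ** days, categorized from the distributions of predicted
values at failed versus successful units.  A ranked overlay pairs the two
categorizations so that high selection with high survival ranks top
(productive, source-like habitat) and high selection with very low
survival ranks bottom (potentially maladaptive, sink-like habitat).

Class codes: selection 0 = nonhabitat, 1 = low, 2 = moderate, 3 = high;
survival 0 = very low, 1 = low, 2 = moderate, 3 = high (-1 = unclassified
/ outside habitat).  Ties at a threshold fall in the lower class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import apply_scaling, attach_covariates
from .landscape import LandscapeStack
from .models import FittedRSF, FittedSurvival, cumulative_survival

__all__ = [
    "SelectionSurface",
    "CategorizedSurface",
    "RankedHabitatMap",
    "predict_selection",
    "predict_survival",
    "categorize_selection",
    "categorize_survival",
    "composite_selection",
    "composite_survival",
    "rank_overlay",
    "management_categories",
    "RANK_ORDER",
]

SELECTION_CLASSES = {0: "nonhabitat", 1: "low", 2: "moderate", 3: "high"}
SURVIVAL_CLASSES = {0: "very_low", 1: "low", 2: "moderate", 3: "high"}

#: (selection class, survival class) -> rank, 1 best .. 12 worst.  Within
#: high/moderate survival higher selection ranks better; within low /
#: very-low survival higher selection ranks worse (maladaptive selection).
RANK_ORDER: dict[tuple[int, int], int] = {
    (3, 3): 1, (2, 3): 2, (1, 3): 3,
    (3, 2): 4, (2, 2): 5, (1, 2): 6,
    (1, 1): 7, (2, 1): 8, (3, 1): 9,
    (1, 0): 10, (2, 0): 11, (3, 0): 12,
}


@dataclass
class SelectionSurface:
    """Continuous HSI surface in [0, 1] for one life stage."""

    hsi: np.ndarray
    stage: str
    year: int | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class CategorizedSurface:
    """Integer class raster plus the thresholds that produced it."""

    classes: np.ndarray  # int; -1 marks unclassified pixels
    kind: str            # "selection" | "survival"
    thresholds: tuple[float, ...]
    labels: dict[int, str] = field(default_factory=dict)


@dataclass
class RankedHabitatMap:
    """Ordinal source-to-sink ranks with per-class area summaries."""

    ranks: np.ndarray     # int; 0 = unranked (outside habitat)
    pixel_size: float
    areas: pd.DataFrame   # rank, pixels, km2, pct_region, pct_habitat


def _surface_design(stack: LandscapeStack, covariates, specs, scaling,
                    year=None, cache=None) -> np.ndarray:
    """Scaled design matrix (npix, p) over the whole grid."""
    nr, nc = stack.shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    x, y = stack.rowcol_to_xy(rows.ravel(), cols.ravel())
    tab = pd.DataFrame({"x": x, "y": y})
    if year is not None:
        tab["year"] = year
    tab = attach_covariates(tab, stack, specs, cache=cache)
    missing = [c for c in covariates if c not in tab]
    if missing:
        raise KeyError(f"covariates missing from landscape: {missing}")
    tab = apply_scaling(tab, scaling)
    return tab[list(covariates)].to_numpy(float)


def predict_selection(model: FittedRSF, stack: LandscapeStack,
                      specs, year: int | None = None,
                      cache: dict | None = None) -> SelectionSurface:
    """Pixelwise HSI from posterior-median coefficients.

    Intercepts, random effects and distance confounders are excluded; time
    varying covariates are taken from the requested ``year``.
    """
    cov = [c for c in model.covariates if c not in model.confounders]
    X = _surface_design(stack, cov, specs, model.scaling, year, cache)
    beta = np.array([model.coefficient_medians()[c] for c in cov])
    w = np.exp(X @ beta)
    hsi = (w / (1.0 + w)).reshape(stack.shape)
    return SelectionSurface(hsi=hsi, stage=model.stage, year=year,
                            meta={"covariates": cov})


def predict_survival(model: FittedSurvival, stack: LandscapeStack,
                     specs, year: int | None = None,
                     cache: dict | None = None) -> np.ndarray:
    """Pixelwise cumulative stage survival DS ** duration.

    Unlike selection, the survival intercept is retained (DS is an absolute
    probability); random effects are dropped as in the selection map.
    """
    X = _surface_design(stack, model.covariates, specs, model.scaling, year, cache)
    beta = np.array([model.coefficient_medians()[c] for c in model.covariates])
    eta = model.draws.median("intercept") + X @ beta
    ds = expit(eta).reshape(stack.shape)
    return cumulative_survival(ds, model.duration)


def _check_monotone(thresholds, what: str):
    if not np.all(np.diff(thresholds) > 0):
        raise ValueError(
            f"non-monotone {what} thresholds {tuple(round(t, 6) for t in thresholds)}; "
            "tied or degenerate point distributions"
        )


def categorize_selection(surface: SelectionSurface | np.ndarray,
                         used_values: np.ndarray,
                         percentiles=(50.0, 25.0, 5.0)) -> CategorizedSurface:
    """Percent-isopleth categorization at used locations.

    The high class contains the top 5% of used-point HSI values, moderate
    the next 20%, low the next 25%; pixels below the value containing the
    top 50% of use are nonhabitat.  Thresholds are therefore the 50th,
    75th and 95th quantiles of HSI at used points.
    """
    hsi = surface.hsi if isinstance(surface, SelectionSurface) else np.asarray(surface)
    used_values = np.asarray(used_values, float)
    if used_values.size < 20:
        raise ValueError("need at least 20 used points to set isopleth thresholds")
    qs = [1.0 - p / 100.0 for p in percentiles]
    thr = tuple(float(np.quantile(used_values, q)) for q in qs)
    _check_monotone(thr, "isopleth")
    classes = np.digitize(hsi, thr, right=True).astype(np.int8)
    classes = np.where(np.isfinite(hsi), classes, -1).astype(np.int8)
    return CategorizedSurface(classes=classes, kind="selection",
                              thresholds=thr, labels=dict(SELECTION_CLASSES))


def categorize_survival(surface: np.ndarray, failed_values: np.ndarray,
                        hatched_values: np.ndarray,
                        thresholds: tuple[float, float, float] | None = None,
                        mask: np.ndarray | None = None) -> CategorizedSurface:
    """Four survival classes from failed/successful point distributions.

    Default thresholds: very-low/low boundary = median of predicted values
    at failed points; moderate/high boundary = median at successful points;
    low/moderate boundary = midpoint of the two medians.  Pass explicit
    ``thresholds`` to override.  ``mask`` (True = habitat) limits the
    classified area; outside pixels get class -1.
    """
    failed_values = np.asarray(failed_values, float)
    hatched_values = np.asarray(hatched_values, float)
    if failed_values.size == 0 or hatched_values.size == 0:
        raise ValueError("need both failed and successful points")
    if thresholds is None:
        m_f = float(np.median(failed_values))
        m_s = float(np.median(hatched_values))
        if m_f == m_s:
            warnings.warn("failed and successful distributions share a median")
        thr = (m_f, 0.5 * (m_f + m_s), m_s)
    else:
        thr = tuple(float(v) for v in thresholds)
    _check_monotone(thr, "survival")
    classes = np.digitize(surface, thr, right=True).astype(np.int8)
    if mask is not None:
        classes = np.where(mask, classes, -1).astype(np.int8)
    classes = np.where(np.isfinite(surface), classes, -1).astype(np.int8)
    return CategorizedSurface(classes=classes, kind="survival",
                              thresholds=thr, labels=dict(SURVIVAL_CLASSES))


def composite_selection(surfaces: list[SelectionSurface]) -> np.ndarray:
    """Equal-weight composite: product of max-relativized stage surfaces."""
    shapes = {s.hsi.shape for s in surfaces}
    if len(shapes) != 1:
        raise ValueError("stage surfaces are not on a shared grid")
    out = np.ones_like(surfaces[0].hsi)
    for s in surfaces:
        mx = np.nanmax(s.hsi)
        if mx <= 0:
            raise ValueError(f"stage {s.stage!r} surface has no positive values")
        out = out * (s.hsi / mx)
    return out


def composite_survival(surfaces: list[np.ndarray],
                       habitat_mask: np.ndarray | None = None) -> np.ndarray:
    """Product of cumulative stage survival surfaces (not relativized:
    these are absolute probabilities), masked to habitat."""
    shapes = {np.asarray(s).shape for s in surfaces}
    if len(shapes) != 1:
        raise ValueError("stage surfaces are not on a shared grid")
    out = np.ones_like(np.asarray(surfaces[0], dtype=float))
    for s in surfaces:
        out = out * np.asarray(s, dtype=float)
    if habitat_mask is not None:
        out = np.where(habitat_mask, out, np.nan)
    return out


def rank_overlay(sel: CategorizedSurface, surv: CategorizedSurface,
                 pixel_size: float = 30.0) -> RankedHabitatMap:
    """Ordinal source-to-sink ranks from the 3x4 selection-survival table.

    Only habitat pixels (selection low/moderate/high) are ranked; rank 1 is
    high selection + high survival (productive), rank 12 high selection +
    very low survival (potentially maladaptive).  Area summaries report
    km^2 and percentages under both the whole-region and habitat-only
    denominators.
    """
    s = sel.classes
    v = surv.classes
    if s.shape != v.shape:
        raise ValueError("categorized grids are not aligned")
    habitat = s >= 1
    if np.any(habitat & (v < 0)):
        raise ValueError("habitat pixels without a survival class")
    ranks = np.zeros(s.shape, dtype=np.int8)
    for (cs, cv), rank in RANK_ORDER.items():
        ranks[(s == cs) & (v == cv)] = rank
    px_area_km2 = pixel_size**2 / 1e6
    total_px = s.size
    hab_px = int(habitat.sum())
    rows = []
    for rank in range(1, 13):
        n = int(np.sum(ranks == rank))
        rows.append({"rank": rank, "pixels": n, "km2": n * px_area_km2,
                     "pct_region": 100.0 * n / total_px,
                     "pct_habitat": (100.0 * n / hab_px) if hab_px else 0.0})
    return RankedHabitatMap(ranks=ranks, pixel_size=pixel_size,
                            areas=pd.DataFrame(rows))


MANAGEMENT_CLASSES = {1: "priority_plus", 2: "priority", 3: "general", 4: "other",
                      0: "unclassified"}


def management_categories(sel: CategorizedSurface, asui: np.ndarray,
                          surv: CategorizedSurface) -> np.ndarray:
    """Four example management classes from selection, survival and use.

    ``asui`` is a binary high-use raster (any continuous abundance/space-use
    index must be thresholded by the caller).  Rules, applied in order:

    1. priority+ : high selection and high survival inside high use;
    2. priority  : any habitat (low/moderate/high selection) inside high
       use, or source habitat (top two ranks) outside high use;
    3. general   : high selection with low/no use, or nonhabitat inside
       high use;
    4. other     : moderate selection with low/no use.
    """
    s = sel.classes
    v = surv.classes
    use = np.asarray(asui) > 0
    if s.shape != use.shape or s.shape != v.shape:
        raise ValueError("grids are not aligned")
    source = ((s == 3) & (v == 3)) | ((s == 2) & (v == 3))
    out = np.zeros(s.shape, dtype=np.int8)
    cat1 = (s == 3) & (v == 3) & use
    cat2 = (((s >= 1) & use) | (source & ~use)) & ~cat1
    cat3 = (((s == 3) & ~use) | ((s == 0) & use)) & ~cat1 & ~cat2
    cat4 = (s == 2) & ~use & ~cat1 & ~cat2 & ~cat3
    out[cat4] = 4
    out[cat3] = 3
    out[cat2] = 2
    out[cat1] = 1
    return out


def area_summary(classes: np.ndarray, labels: dict[int, str],
                 pixel_size: float = 30.0) -> pd.DataFrame:
    """Class areas: pixels, km^2 and percent of the mapped region."""
    total = classes.size
    rows = []
    for code, name in sorted(labels.items()):
        n = int(np.sum(classes == code))
        rows.append({"class": name, "code": code, "pixels": n,
                     "km2": n * pixel_size**2 / 1e6,
                     "pct_region": 100.0 * n / total})
    return pd.DataFrame(rows)
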