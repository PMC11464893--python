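"""Used/available design tables and interval encounter histories.

The resource-selection design contrasts telemetry ("used") locations with
"available" locations sampled uniformly within a biologically defined
availability radius — the 90th percentile of observed movement distances
from the anchoring feature (lek for nesting, the individual's nest for
brood stages) — at a fixed 5:1 available:used ratio.  Distance to the
anchor is retained as a confounder covariate on every row.

Survival data are interval-censored encounter histories: one record per
interval between successive checks, carrying entry day, exit day, interval
length and fate, with covariates measured at the interval start.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .landscape import LandscapeStack

__all__ = ["AVAILABLE_RATIO", "sample_available", "build_encounter_history",
           "availability_radius"]

#: Available:used sampling ratio (design constant).
AVAILABLE_RATIO = 5


def availability_radius(distances, percentile: float = 90.0,
                        per_individual: bool = False,
                        individuals=None) -> float | pd.Series:
    """Availability radius: the 90th percentile of movement distances.

    Linear interpolation between order statistics (numpy default).  Pooled
    across individuals by default; ``per_individual=True`` with an
    ``individuals`` label vector returns one radius per individual.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size < 10:
        raise ValueError("need at least 10 movement distances to estimate the percentile")
    if per_individual:
        if individuals is None:
            raise ValueError("per_individual=True requires individual labels")
        s = pd.Series(distances).groupby(np.asarray(individuals))
        return s.quantile(percentile / 100.0)
    return float(np.percentile(distances, percentile))


def _uniform_in_disc(rng, n, cx, cy, radius):
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    return cx + r * np.cos(theta), cy + r * np.sin(theta)


def sample_available(
    used: pd.DataFrame,
    anchors: pd.DataFrame,
    distances,
    stack: LandscapeStack | None = None,
    ratio: int = AVAILABLE_RATIO,
    percentile: float = 90.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build the used/available design table at a fixed ratio.

    Parameters
    ----------
    used
        Used-point table with ``x, y, site, year, animal`` (and optionally
        ``stage``) columns.
    anchors
        One row per animal with ``animal, x, y`` giving the availability
        anchor (lek or nest).
    distances
        Movement distances whose 90th percentile defines the radius.
    stack
        If given, available points falling off the raster are rejected and
        resampled so the ratio stays exact.

    Returns
    -------
    DataFrame with ``used`` (1 used / 0 available), ``x, y`` coordinates,
    the used row's grouping ids inherited by its available rows, and
    ``dist_anchor``, the distance-to-anchor confounder (m).
    """
    rng = np.random.default_rng() if rng is None else rng
    if used.empty:
        return pd.DataFrame(columns=["used", *used.columns, "dist_anchor"])
    radius = availability_radius(distances, percentile)
    if radius <= 0:
        raise ValueError("availability radius must be positive")
    amap = anchors.set_index("animal")
    rows = []
    for rec in used.itertuples(index=False):
        base = rec._asdict()
        ax = float(amap.loc[base["animal"], "x"])
        ay = float(amap.loc[base["animal"], "y"])
        rows.append({**base, "used": 1,
                     "dist_anchor": float(np.hypot(base["x"] - ax, base["y"] - ay))})
        need = ratio
        while need > 0:
            px, py = _uniform_in_disc(rng, need, ax, ay, radius)
            if stack is not None:
                ok = stack.contains(px, py)
                px, py = px[ok], py[ok]
            for xx, yy in zip(px, py):
                rows.append({**base, "x": float(xx), "y": float(yy), "used": 0,
                             "dist_anchor": float(np.hypot(xx - ax, yy - ay))})
            need -= len(px)
    out = pd.DataFrame.from_records(rows)
    front = ["used", "x", "y"]
    return out[front + [c for c in out.columns if c not in front]]


def build_encounter_history(visits: pd.DataFrame) -> pd.DataFrame:
    """Encounter history from a per-unit relocation table.

    ``visits`` must have one row per check: ``unit, day, status`` with
    status 1 (alive at this check) or 0 (failure discovered at this check);
    the first row per unit marks entry (day of discovery).  Any other
    columns (site, year, covariates) are carried from the interval-start
    visit.  Units whose terminal fate is missing are excluded with a
    warning; non-monotone visit days raise.
    """
    records = []
    carry = [c for c in visits.columns if c not in ("day", "status")]
    for unit, grp in visits.groupby("unit", sort=False):
        days = grp["day"].to_numpy()
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"visit days for unit {unit!r} are not strictly increasing")
        status = grp["status"].to_numpy(dtype=float)
        if np.isnan(status[-1]):
            warnings.warn(f"unit {unit!r} has unknown terminal fate; excluded")
            continue
        for i in range(1, len(days)):
            rec = {c: grp.iloc[i - 1][c] for c in carry}
            rec.update(entry=int(days[i - 1]), exit=int(days[i]),
                       t=int(days[i] - days[i - 1]), y=int(status[i]))
            records.append(rec)
            if status[i] == 0:
                break
    eh = pd.DataFrame.from_records(records)
    if eh.empty:
        return eh
    front = ["unit", "entry", "exit", "t", "y"]
    cols = [c for c in front if c in eh.columns] + [c for c in eh.columns if c not in front]
    return eh[cols]
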