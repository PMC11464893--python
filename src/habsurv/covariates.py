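"""Multi-scale covariate engineering.

Raw land-cover bands and feature layers become model covariates in three
steps: (1) circular moving-window (focal) means at candidate radii,
(2) exponential-decay transforms of distance-to-feature bands, and
(3) scaling and centering of the design columns, with the fitted scaling
parameters stored for reuse at map-prediction time.

Candidate radii follow field-estimated movement distances: 167.9, 439.5 and
1451.7 m (minimum / mean / maximum daily movements) for all life stages,
plus 75 m (core nest recess area), 260 m (nest recess / early brood
movement) and 370 m (late brood movement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import LandscapeStack

__all__ = [
    "CANDIDATE_RADII",
    "CovariateSpec",
    "ScalingParams",
    "focal_proportion",
    "decay_distance",
    "scale_and_center",
    "apply_scaling",
    "scaled_band_name",
    "attach_covariates",
]

#: Admissible moving-window radii (m).
CANDIDATE_RADII = (75.0, 167.9, 260.0, 370.0, 439.5, 1451.7)


@dataclass(frozen=True)
class CovariateSpec:
    """Description of one covariate and the scales at which it competes.

    ``kind`` is one of ``proportion`` (land-cover fraction / feature
    density; focal-averaged), ``height`` (continuous; focal-averaged),
    ``distance`` (distance band passed through exponential decay; not
    windowed) or ``topographic`` (static; used at native resolution).
    """

    name: str
    group: str
    kind: str = "proportion"
    radii: tuple[float, ...] = ()
    decay_alpha: float | None = None
    temporal: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("proportion", "height", "distance", "topographic"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        bad = set(self.radii) - set(CANDIDATE_RADII)
        if bad:
            raise ValueError(f"radii {sorted(bad)} not among candidate radii {CANDIDATE_RADII}")
        if self.decay_alpha is not None and self.decay_alpha <= 0:
            raise ValueError("decay_alpha must be positive")


@dataclass
class ScalingParams:
    """Per-column mean and SD (population convention, ddof=0) from fitting.

    Stored once when the design data are standardized and reused verbatim
    for map prediction, so pixels are scored in the fitted model's units.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.means.items():
            if col in out:
                out[col] = (out[col] - mu) / self.sds[col]
        return out

    def transform_array(self, name: str, arr: np.ndarray) -> np.ndarray:
        return (arr - self.means[name]) / self.sds[name]

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(means=dict(d["means"]), sds=dict(d["sds"]))


def _circular_footprint(radius: float, pixel_size: float) -> np.ndarray:
    """Boolean kernel of pixel-center offsets within ``radius`` metres."""
    r_px = int(np.floor(radius / pixel_size))
    dy, dx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    return (np.hypot(dx, dy) * pixel_size) <= radius


def focal_proportion(band: np.ndarray, radius: float, pixel_size: float = 30.0) -> np.ndarray:
    """Circular moving-window mean of ``band``.

    For a 0/1 feature band this is the feature density (feature pixels per
    window pixel); for a fractional-cover band it is the mean proportion.
    Window membership is decided in metric units: a pixel belongs to the
    window when its center lies within ``radius`` of the focal pixel's
    center.  Edge and missing-data windows are normalized by the number of
    valid in-window pixels; a window with no valid pixel yields NaN.
    """
    if radius < pixel_size:
        raise ValueError(f"radius {radius} m is smaller than the pixel size {pixel_size} m")
    fp = _circular_footprint(radius, pixel_size).astype(float)
    valid = np.isfinite(band)
    filled = np.where(valid, band, 0.0)
    num = ndimage.convolve(filled, fp, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), fp, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return out


def decay_distance(distance: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Exponential-decay transform ``exp(-d / alpha)`` of a distance band.

    Maps distance 0 to 1 and decays monotonically toward 0, so a feature's
    influence fades with distance; ``alpha`` (m) is conventionally the mean
    raw distance over the analysis's design rows.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-d / alpha)
    return float(out) if np.isscalar(distance) else out


def scale_and_center(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardize ``columns`` to mean 0, SD 1 (population SD, ddof=0).

    Returns the transformed table and the fitted :class:`ScalingParams`.
    Raises on a zero-variance column, naming it.
    """
    params = ScalingParams()
    out = table.copy()
    for col in columns:
        vals = table[col].to_numpy(dtype=float)
        mu = float(np.mean(vals))
        sd = float(np.std(vals))  # population convention
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot scale")
        params.means[col] = mu
        params.sds[col] = sd
        out[col] = (vals - mu) / sd
    return out, params


def apply_scaling(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Apply previously fitted scaling to new rows (prediction-time path)."""
    return params.transform(table)


def scaled_band_name(name: str, radius: float | None) -> str:
    """Column / derived-band naming convention: ``<covariate>_<radius>``."""
    return name if radius is None else f"{name}_{radius:g}"


def attach_covariates(
    table: pd.DataFrame,
    stack: LandscapeStack,
    specs: list[CovariateSpec],
    year_col: str | None = "year",
    cache: dict | None = None,
) -> pd.DataFrame:
    """Add one column per covariate x candidate scale to a point table.

    Windowed kinds get one column per candidate radius; distance kinds get
    a single decayed column (``decay_alpha`` must be set beforehand, e.g.
    to the mean raw distance over the table); topographic kinds are sampled
    at native resolution.  Focal bands are memoized in ``cache`` keyed by
    (band, radius) so repeated extractions are cheap.
    """
    cache = {} if cache is None else cache
    out = table.copy()
    x = table["x"].to_numpy(float)
    y = table["y"].to_numpy(float)
    years = table[year_col].to_numpy() if (year_col and year_col in table) else None

    def focal_cached(band_key: str, radius: float) -> np.ndarray:
        key = (band_key, radius)
        if key not in cache:
            cache[key] = focal_proportion(
                stack.bands[band_key], radius, stack.pixel_size
            )
        return cache[key]

    def band_keys(spec: CovariateSpec):
        """Yield (band key, year value) pairs covering the table's years."""
        if spec.temporal and years is not None:
            return [(f"{spec.name}@{yr}", yr) for yr in np.unique(years)]
        return [(spec.name, None)]

    for spec in specs:
        if spec.kind in ("proportion", "height"):
            for radius in spec.radii:
                col = scaled_band_name(spec.name, radius)
                vals = np.empty(len(table))
                for band_key, yr in band_keys(spec):
                    arr = focal_cached(band_key, radius)
                    sel = slice(None) if yr is None else (years == yr)
                    row, colix = stack.xy_to_rowcol(x[sel], y[sel])
                    vals[sel] = arr[row, colix]
                out[col] = vals
        elif spec.kind == "distance":
            raw = stack.extract(spec.name, x, y)
            alpha = spec.decay_alpha
            if alpha is None:
                raise ValueError(
                    f"distance covariate {spec.name!r} has no decay_alpha set"
                )
            out[spec.name] = decay_distance(raw, alpha)
        else:  # topographic
            out[spec.name] = stack.extract(spec.name, x, y)
    return out


def resolve_decay_alphas(table: pd.DataFrame, stack: LandscapeStack,
                         specs: list[CovariateSpec]) -> list[CovariateSpec]:
    """Fix each distance covariate's decay scale to the mean raw distance
    over the analysis's design rows (alpha is per-analysis, not per-map)."""
    out = []
    for spec in specs:
        if spec.kind == "distance" and spec.decay_alpha is None:
            raw = stack.extract(spec.name, table["x"].to_numpy(float),
                                table["y"].to_numpy(float))
            alpha = float(np.mean(raw))
            if alpha <= 0:
                alpha = float(stack.pixel_size)
            out.append(CovariateSpec(spec.name, spec.group, spec.kind,
                                     spec.radii, alpha, spec.temporal))
        else:
            out.append(spec)
    return out


def candidate_columns(specs: list[CovariateSpec]) -> dict[str, list[str]]:
    """Group label -> candidate variable-x-scale column names (sorted by radius)."""
    groups: dict[str, list[str]] = {}
    for spec in specs:
        cols = groups.setdefault(spec.group, [])
        if spec.kind in ("proportion", "height"):
            cols.extend(scaled_band_name(spec.name, r) for r in sorted(spec.radii))
        else:
            cols.append(spec.name)
    return groups
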