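"""Fitted-model containers and the standard posterior summaries.

Selection models are summarized by relative selection strength
(RSS = exp(beta): the relative use intensity of two locations one
covariate SD apart, RSS > 1 meaning selection) and the probability of
direction (pd >= 0.85 a moderate, >= 0.95 a strong effect).  Survival
models yield cumulative stage survival DS ** days (38 nesting, 21 early
brood, 28 late brood days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import ScalingParams
from .mcmc import PosteriorDraws

__all__ = [
    "FittedRSF",
    "FittedSurvival",
    "rss",
    "probability_of_direction",
    "cumulative_survival",
]


@dataclass
class FittedRSF:
    """Final selection model: covariates at their selected scales + draws.

    Map prediction discards the intercept and random effects and applies
    the exponential link; ``confounders`` (distance to lek/nest) are kept
    out of the prediction surface as well.
    """

    draws: PosteriorDraws
    covariates: list[str]
    scaling: ScalingParams
    stage: str
    confounders: tuple[str, ...] = ()

    def coefficient_medians(self) -> dict[str, float]:
        return {c: self.draws.median(f"beta_{c}") for c in self.covariates}


@dataclass
class FittedSurvival:
    """Final survival model: covariates, draws, and the stage duration (d)."""

    draws: PosteriorDraws
    covariates: list[str]
    scaling: ScalingParams
    stage: str
    duration: int

    def coefficient_medians(self) -> dict[str, float]:
        return {c: self.draws.median(f"beta_{c}") for c in self.covariates}


def rss(model: FittedRSF, covariate: str, level: float = 0.95) -> dict:
    """Relative selection strength exp(beta) with a credible interval.

    Computed per draw and summarized at the median (the quantile
    equivariance of exp means the median RSS equals exp of the median
    coefficient).
    """
    if covariate not in model.covariates:
        raise KeyError(f"covariate {covariate!r} not in the final model")
    d = np.exp(model.draws.stacked(f"beta_{covariate}"))
    a = (1.0 - level) / 2.0
    return {
        "covariate": covariate,
        "median": float(np.median(d)),
        "lo": float(np.quantile(d, a)),
        "hi": float(np.quantile(d, 1.0 - a)),
        "level": level,
    }


def probability_of_direction(draws: np.ndarray) -> dict:
    """pd = max(P(beta > 0), P(beta < 0)) over posterior draws, in [0.5, 1].

    Flags ``moderate`` at pd >= 0.85 and ``strong`` at pd >= 0.95.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty posterior draws")
    p_pos = float(np.mean(draws > 0))
    p_neg = float(np.mean(draws < 0))
    p = max(p_pos, p_neg)
    return {"pd": p, "moderate": p >= 0.85, "strong": p >= 0.95}


def cumulative_survival(ds, days: int):
    """Stage survival: daily survival raised to the number of stage days."""
    if int(days) != days or days <= 0:
        raise ValueError("days must be a positive integer")
    arr = np.asarray(ds, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("daily survival must lie in (0, 1]")
    out = arr ** int(days)
    return float(out) if np.isscalar(ds) else out


def summary_table(model: FittedRSF | FittedSurvival,
                  levels=(0.85, 0.95)) -> pd.DataFrame:
    """Appendix-style table: median, credible bounds, pd, and (for
    selection models) RSS per covariate."""
    tab = model.draws.summary(levels=levels)
    if isinstance(model, FittedRSF):
        rss_map = {}
        for c in model.covariates:
            r = rss(model, c)
            rss_map[f"beta_{c}"] = r["median"]
        tab["rss"] = tab["parameter"].map(rss_map)
    return tab
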