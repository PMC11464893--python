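"""Out-of-sample validation for selection and survival models.

Three checks, all on data from individuals withheld before fitting:

* **RSF cross-validation** (area-adjusted bin regression): predictions are
  binned, expected test-point counts per bin are proportional to bin
  midpoint value times bin area, and observed counts are regressed on
  expected — reporting Spearman's rank rho, R-squared, and the slope
  (``beta_predict``; 1 is ideal).
* **Used-habitat calibration (UHC)**: per posterior draw, points are
  re-sampled from availability under the draw's coefficients and each
  covariate's density among those simulated used points forms a 95%
  predictive envelope, compared against the observed test-point density.
* **Survival posterior-predictive check**: fates are re-simulated over the
  test exposure structure per draw; the Bayesian predictive p-value is the
  share of draws whose survival-curve discrepancy exceeds the observed
  one (values near 0 or 1 indicate poor fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "HoldoutSplit",
    "holdout_split",
    "rsf_cross_validate",
    "uhc_plot",
    "survival_ppc",
    "km_curve",
]


@dataclass
class HoldoutSplit:
    """Individual-level train/test split (never row-level)."""

    withheld_ids: np.ndarray
    train: pd.DataFrame
    test: pd.DataFrame

    def assert_leakage_free(self, id_col: str) -> None:
        overlap = set(self.train[id_col]) & set(self.test[id_col])
        if overlap:
            raise AssertionError(f"individuals in both splits: {sorted(overlap)[:5]}")


def holdout_split(table: pd.DataFrame, id_col: str = "animal",
                  n_withheld: int = 50,
                  rng: np.random.Generator | None = None) -> HoldoutSplit:
    """Withhold ``n_withheld`` whole individuals as the testing set."""
    rng = np.random.default_rng() if rng is None else rng
    ids = pd.unique(table[id_col])
    if n_withheld >= len(ids):
        raise ValueError("cannot withhold all individuals")
    withheld = rng.choice(ids, size=n_withheld, replace=False)
    mask = table[id_col].isin(withheld)
    split = HoldoutSplit(withheld_ids=np.asarray(withheld),
                         train=table[~mask].reset_index(drop=True),
                         test=table[mask].reset_index(drop=True))
    split.assert_leakage_free(id_col)
    return split


def rsf_cross_validate(surface_values: np.ndarray, test_values: np.ndarray,
                       bins: int = 10) -> dict:
    """Area-adjusted RSF cross-validation over ranked prediction bins.

    ``surface_values``: RSF scores (w) across the availability domain
    (e.g. all mapped pixels); ``test_values``: scores at withheld used
    points.  Scores are cut into ``bins`` ranked bins at quantiles of the
    prediction distribution (approximately equal-area bins); the expected
    test count in bin i is ``N w_i A_i / sum_j w_j A_j`` with ``w_i A_i``
    the bin's total RSF weight.  Empty bins are collapsed with a warning.

    Returns Spearman's rho between bin rank and area-adjusted observed
    frequency, the R-squared and slope of observed-on-expected regression.
    """
    surface_values = np.asarray(surface_values, float).ravel()
    surface_values = surface_values[np.isfinite(surface_values)]
    test_values = np.asarray(test_values, float).ravel()
    lo, hi = surface_values.min(), surface_values.max()
    if hi <= lo:
        raise ValueError("prediction surface is constant; cannot bin")
    # ranked bins at quantiles of the prediction distribution, so bins
    # cover (approximately) equal areas of the availability domain
    edges = np.unique(np.quantile(surface_values, np.linspace(0, 1, bins + 1)))
    edges[0], edges[-1] = lo - 1e-12, hi + 1e-12
    area = np.histogram(surface_values, bins=edges)[0].astype(float)
    wsum = np.histogram(surface_values, bins=edges, weights=surface_values)[0]
    obs = np.histogram(np.clip(test_values, lo, hi), bins=edges)[0].astype(float)
    bins = len(area)
    keep = area > 0
    if keep.sum() < bins:
        warnings.warn(f"collapsed {int(bins - keep.sum())} empty bins")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-empty bins")
    area, obs, wsum = area[keep], obs[keep], wsum[keep]
    # expected use of bin i: its total RSF weight, normalized
    expected = len(test_values) * wsum / np.sum(wsum)
    rank = np.arange(len(area))
    adj_freq = obs / area
    rho = stats.spearmanr(rank, adj_freq).statistic
    reg = stats.linregress(expected, obs)
    return {"rho": float(rho), "r2": float(reg.rvalue**2),
            "slope": float(reg.slope), "bins_used": int(keep.sum()),
            "observed": obs.tolist(), "expected": expected.tolist()}


def _weighted_sample(rng, weights, size):
    p = weights / weights.sum()
    return rng.choice(len(weights), size=size, p=p)


def uhc_plot(beta_draws: pd.DataFrame, avail: pd.DataFrame,
             test_used: pd.DataFrame, covariates: list[str],
             n_draws: int = 200, grid_size: int = 50,
             rng: np.random.Generator | None = None) -> dict:
    """Used-habitat calibration envelopes per covariate.

    ``beta_draws``: rows of posterior coefficient draws with one column per
    covariate; ``avail``: availability sample with covariate columns (the
    same scaled units); ``test_used``: withheld used points.  For each
    retained draw, ``len(test_used)`` points are drawn from availability
    with weight exp(X beta); the covariate's kernel density among those
    forms the predictive distribution.  Returns, per covariate, the
    evaluation grid, 95% envelope, observed density and the fraction of
    grid points where the observed density lies inside the envelope.
    """
    rng = np.random.default_rng() if rng is None else rng
    if len(beta_draws) < 100:
        raise ValueError("need at least 100 posterior draws for UHC")
    take = rng.choice(len(beta_draws), size=min(n_draws, len(beta_draws)),
                      replace=False)
    Xa = avail[covariates].to_numpy(float)
    n_test = len(test_used)
    out = {}
    dens_sets = {c: [] for c in covariates}
    grids = {}
    for c in covariates:
        vals = np.concatenate([avail[c].to_numpy(float), test_used[c].to_numpy(float)])
        if np.std(vals) == 0:
            warnings.warn(f"covariate {c!r} is degenerate; skipped in UHC")
            continue
        grids[c] = np.linspace(vals.min(), vals.max(), grid_size)
    for ix in take:
        beta = beta_draws.iloc[ix][covariates].to_numpy(float)
        w = np.exp(Xa @ beta - np.max(Xa @ beta))
        sim_ix = _weighted_sample(rng, w, n_test)
        for c in grids:
            sim_vals = avail[c].to_numpy(float)[sim_ix]
            kde = stats.gaussian_kde(sim_vals + 1e-9 * rng.standard_normal(n_test))
            dens_sets[c].append(kde(grids[c]))
    for c, grid in grids.items():
        dens = np.asarray(dens_sets[c])
        lo = np.quantile(dens, 0.025, axis=0)
        hi = np.quantile(dens, 0.975, axis=0)
        obs = stats.gaussian_kde(test_used[c].to_numpy(float))(grid)
        inside = (obs >= lo) & (obs <= hi)
        out[c] = {"grid": grid, "lo": lo, "hi": hi, "observed": obs,
                  "coverage": float(np.mean(inside))}
    return out


def plot_uhc(envelopes: dict, path: str) -> None:
    """Write the UHC panel figure (one panel per covariate): the 95%
    predictive envelope with the observed test-point density overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(envelopes)
    fig, axes = plt.subplots(1, max(len(names), 1),
                             figsize=(3.2 * max(len(names), 1), 3.0),
                             squeeze=False)
    for ax, name in zip(axes[0], names):
        env = envelopes[name]
        ax.fill_between(env["grid"], env["lo"], env["hi"], alpha=0.4,
                        label="predicted 95%")
        ax.plot(env["grid"], env["observed"], lw=1.5, label="observed")
        ax.set_title(f"{name} (coverage {env['coverage']:.2f})", fontsize=9)
        ax.set_xlabel("covariate (scaled)")
    axes[0, 0].set_ylabel("density")
    axes[0, -1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_curve(eh: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival curve over interval exit days.

    At each distinct exit day the conditional interval survival is the
    share of intervals ending that day with fate 1; the curve is the
    cumulative product (Mayfield-style, matching interval censoring).
    """
    days = np.sort(pd.unique(eh["exit"]))
    surv = np.empty(len(days))
    s = 1.0
    for i, d in enumerate(days):
        sub = eh[eh["exit"] == d]
        s *= float(np.mean(sub["y"]))
        surv[i] = s
    return days, surv


def survival_ppc(gamma_draws: pd.DataFrame, test: pd.DataFrame,
                 covariates: list[str], n_draws: int = 500,
                 rng: np.random.Generator | None = None) -> dict:
    """Bayesian predictive p-value from re-simulated survival curves.

    For each posterior draw, interval daily survival is computed from the
    draw's intercept and coefficients, fates are re-simulated over the test
    exposure structure (units censored after their first simulated
    failure), and the discrepancy is the maximum absolute difference
    between a realized product-limit curve and the draw's model curve.
    The p-value is the share of draws whose replicated discrepancy is at
    least the observed one.
    """
    rng = np.random.default_rng() if rng is None else rng
    if test.empty:
        raise ValueError("test encounter histories are empty")
    t = test["t"].to_numpy(float)
    if np.sum(t) <= 0:
        raise ValueError("test data carry zero exposure")
    X = test[covariates].to_numpy(float) if covariates else np.zeros((len(test), 0))
    take = rng.choice(len(gamma_draws), size=min(n_draws, len(gamma_draws)),
                      replace=False)
    days_obs, s_obs = km_curve(test)
    units = test["unit"].to_numpy()
    order = np.argsort(test["entry"].to_numpy(), kind="stable")
    d_obs_all, d_rep_all = [], []
    for ix in take:
        row = gamma_draws.iloc[ix]
        eta = np.full(len(test), float(row["intercept"]))
        if covariates:
            eta += X @ row[covariates].to_numpy(float)
        ds = expit(eta)
        p_int = ds ** t
        # model curve at observed exit days (exposure-weighted mean DS)
        ds_bar = float(np.sum(ds * t) / np.sum(t))
        s_model = ds_bar ** days_obs.astype(float)
        # replicate fates with censoring after first failure, per unit
        y_rep = (rng.uniform(size=len(test)) < p_int).astype(int)
        rep = test[["unit", "entry", "exit", "t"]].copy()
        rep["y"] = y_rep
        alive: dict = {}
        keep_rows = np.ones(len(rep), bool)
        for i in order:
            u = units[i]
            if not alive.get(u, True):
                keep_rows[i] = False
            elif y_rep[i] == 0:
                alive[u] = False
        rep = rep[keep_rows]
        days_rep, s_rep = km_curve(rep)
        s_rep_on_obs = np.interp(days_obs, days_rep, s_rep)
        d_obs_all.append(float(np.max(np.abs(s_obs - s_model))))
        d_rep_all.append(float(np.max(np.abs(s_rep_on_obs - s_model))))
    d_obs_all = np.asarray(d_obs_all)
    d_rep_all = np.asarray(d_rep_all)
    return {"p_value": float(np.mean(d_rep_all >= d_obs_all)),
            "observed_discrepancy": float(np.mean(d_obs_all)),
            "replicated_discrepancy": float(np.mean(d_rep_all)),
            "curve_days": days_obs.tolist(), "curve_surv": s_obs.tolist()}
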