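"""Metropolis-within-Gibbs machinery for the two hierarchical models.

Both model families share one sampler:

* **used/available logistic**: ``logit P(used) = b0 + X beta + site + year
  + animal`` random intercepts;
* **binomial exposure-time survival**: ``logit DS_i = g0 + X beta + site +
  year``, with interval success probability ``DS_i ** t_i`` (daily survival
  raised to the interval length).

Habitat coefficients carry Lasso (Laplace) shrinkage priors with a single
tuning parameter ``lambda ~ Uniform(0.001, 10)`` shared within a model;
random intercepts are normal with a uniform prior on their variance
(Uniform(0, 100), uniform-on-SD available as an option).  Multi-scale
covariate groups are handled by Bayesian latent indicator scale selection
(BLISS): a categorical indicator per group picks which candidate
variable-by-scale column enters the linear predictor at each iteration,
updated by a discrete Gibbs draw from its full conditional.  Because each
group keeps exactly one coefficient, the indicator swap is fixed-dimension
and no trans-dimensional proposal is needed; the posterior is the same as
the reversible-jump formulation usually cited for BLISS.

Fixed-effect and intercept updates are adaptive random-walk Metropolis
(adaptation during burn-in only); ``lambda`` is a Gibbs draw from its
truncated-Gamma full conditional.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

__all__ = [
    "ModelSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "fit",
    "bliss_select",
    "final_spec_from_bliss",
    "gelman_rubin",
]


@dataclass
class ModelSpec:
    """Structure of one hierarchical model.

    ``fixed`` columns get Laplace priors but do not compete across scales
    (confounders such as distance-to-lek/nest go here, and the winners of a
    BLISS stage when refitting the final model); ``groups`` maps a group
    label to its candidate variable-by-scale columns for BLISS.  ``random``
    lists grouping-factor columns (site/year, plus animal for selection
    models only).
    """

    likelihood: str  # "logistic" | "exposure"
    fixed: tuple[str, ...] = ()
    groups: dict[str, list[str]] = field(default_factory=dict)
    random: tuple[str, ...] = ()
    response: str | None = None
    exposure_col: str = "t"
    lambda_bounds: tuple[float, float] = (0.001, 10.0)
    variance_bound: float = 100.0
    variance_prior: str = "variance"  # or "sd"

    def __post_init__(self) -> None:
        if self.likelihood not in ("logistic", "exposure"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.response is None:
            self.response = "used" if self.likelihood == "logistic" else "y"
        seen: set[str] = set(self.fixed)
        if len(seen) != len(self.fixed):
            raise ValueError("duplicated fixed-effect columns")
        for g, cands in self.groups.items():
            if len(set(cands)) != len(cands):
                raise ValueError(f"duplicated candidate columns in group {g!r}")
            overlap = seen & set(cands)
            if overlap:
                raise ValueError(f"columns {sorted(overlap)} appear in more than one place")
            seen |= set(cands)
        if self.variance_prior not in ("variance", "sd"):
            raise ValueError("variance_prior must be 'variance' or 'sd'")

    @property
    def coefficient_names(self) -> list[str]:
        return list(self.fixed) + list(self.groups)


@dataclass
class MCMCSettings:
    """Chain-length settings; defaults follow the study design
    (3 chains, 30,000 iterations, first 20,000 discarded, thin 5)."""

    chains: int = 3
    iterations: int = 30_000
    burnin: int = 20_000
    thin: int = 5
    adapt: bool = True
    store_random_levels: bool = False
    init_attempts: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.burnin < self.iterations):
            raise ValueError("need 0 < burnin < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Per-chain posterior draws plus BLISS indicator traces.

    ``params[name]`` has shape ``(chains, retained)``; ``indicators[group]``
    holds integer indices into ``group_candidates[group]``.
    """

    params: dict[str, np.ndarray]
    indicators: dict[str, np.ndarray]
    group_candidates: dict[str, list[str]]
    meta: dict

    def stacked(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        return self.params[name].reshape(-1)

    def median(self, name: str) -> float:
        return float(np.median(self.stacked(name)))

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        d = self.stacked(name)
        return float(np.quantile(d, a)), float(np.quantile(d, 1.0 - a))

    def prob_direction(self, name: str) -> float:
        d = self.stacked(name)
        if d.size == 0:
            raise ValueError("no draws")
        p = float(np.mean(d > 0))
        return max(p, 1.0 - p)

    def indicator_frequencies(self) -> dict[str, dict[str, float]]:
        out = {}
        for g, draws in self.indicators.items():
            cands = self.group_candidates[g]
            counts = np.bincount(draws.reshape(-1), minlength=len(cands))
            freqs = counts / counts.sum()
            out[g] = {c: float(f) for c, f in zip(cands, freqs)}
        return out

    def summary(self, levels=(0.85, 0.95)) -> pd.DataFrame:
        rows = []
        for name in self.params:
            d = self.stacked(name)
            row = {"parameter": name, "median": float(np.median(d))}
            for lv in levels:
                a = (1 - lv) / 2
                row[f"lo{int(lv * 100)}"] = float(np.quantile(d, a))
                row[f"hi{int(lv * 100)}"] = float(np.quantile(d, 1 - a))
            p = float(np.mean(d > 0))
            row["pd"] = max(p, 1 - p)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_long_dataframe(self) -> pd.DataFrame:
        frames = []
        for name, arr in self.params.items():
            ch, n = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(ch), n),
                "iteration": np.tile(np.arange(n), ch),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)

    def save(self, csv_path: str, json_path: str | None = None) -> None:
        self.to_long_dataframe().to_csv(csv_path, index=False)
        if json_path:
            payload = {
                "meta": self.meta,
                "summary": self.summary().to_dict(orient="records"),
                "indicator_frequencies": self.indicator_frequencies(),
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2)


# --------------------------------------------------------------------------
# likelihoods


def _log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a <= 0, numerically stable."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(a < -0.693, np.log1p(-np.exp(a)), np.log(-np.expm1(a)))
    return np.where(a >= 0, -np.inf, out)


def _make_loglik(likelihood: str, y: np.ndarray, t: np.ndarray | None):
    if likelihood == "logistic":
        def ll(eta: np.ndarray) -> np.ndarray:
            return y * eta - np.logaddexp(0.0, eta)
    else:
        def ll(eta: np.ndarray) -> np.ndarray:
            log_ds = -np.logaddexp(0.0, -eta)  # log sigmoid(eta)
            a = t * log_ds                      # log DS^t
            return np.where(y == 1, a, _log1mexp(a))
    return ll


# --------------------------------------------------------------------------
# sampler


class _ChainState:
    """Mutable state of one chain; owns the linear predictor."""

    def __init__(self, spec, cols, y, t, factors, rng):
        self.spec = spec
        self.cols = cols                  # name -> column array
        self.factors = factors            # name -> (codes, n_levels)
        self.rng = rng
        self.loglik = _make_loglik(spec.likelihood, y, t)
        n = len(y)
        self.b0 = 0.0
        self.beta = {c: 0.0 for c in spec.fixed}
        self.gcoef = {g: 0.0 for g in spec.groups}
        self.gind = {g: 0 for g in spec.groups}
        self.b = {f: np.zeros(nl) for f, (_, nl) in factors.items()}
        self.sig2 = {f: 1.0 for f in factors}
        lo, hi = spec.lambda_bounds
        self.lam = float(np.sqrt(lo * hi))
        self.eta = np.zeros(n)
        self.ll = None
        self.steps = {"b0": 0.2,
                      **{f"beta:{c}": 0.2 for c in spec.fixed},
                      **{f"gcoef:{g}": 0.2 for g in spec.groups},
                      **{f"b:{f}": 0.3 for f in factors},
                      **{f"sig2:{f}": 0.8 for f in factors}}
        self.accepts = {k: [0, 0] for k in self.steps}

    # -- linear predictor ------------------------------------------------
    def recompute_eta(self):
        eta = np.full_like(self.eta, self.b0)
        for c, bv in self.beta.items():
            if bv != 0.0:
                eta += bv * self.cols[c]
        for g, bv in self.gcoef.items():
            if bv != 0.0:
                eta += bv * self.cols[self.spec.groups[g][self.gind[g]]]
        for f, (codes, _) in self.factors.items():
            eta += self.b[f][codes]
        self.eta = eta
        self.ll = self.loglik(eta)

    def initialize(self, y, t):
        if self.spec.likelihood == "logistic":
            p = np.clip(np.mean(y), 1e-3, 1 - 1e-3)
        else:
            surv_days = float(np.sum(np.where(y == 1, t, np.maximum(t - 1, 0))))
            p = np.clip(surv_days / max(float(np.sum(t)), 1.0), 1e-3, 1 - 1e-3)
        self.b0 = float(logit(p))
        self.recompute_eta()

    def total_ll(self):
        return float(np.sum(self.ll))

    # -- update blocks ---------------------------------------------------
    def _mh_scalar(self, key, get, setv, xcol=None, logprior=None):
        old = get()
        step = self.steps[key]
        new = old + step * self.rng.standard_normal()
        eta_new = self.eta + (new - old) * (xcol if xcol is not None else 1.0)
        ll_new = self.loglik(eta_new)
        delta = float(np.sum(ll_new) - np.sum(self.ll))
        if logprior is not None:
            delta += logprior(new) - logprior(old)
        self.accepts[key][1] += 1
        if np.log(self.rng.uniform()) < delta:
            setv(new)
            self.eta = eta_new
            self.ll = ll_new
            self.accepts[key][0] += 1

    def update_intercept(self):
        self._mh_scalar("b0", lambda: self.b0,
                        lambda v: setattr(self, "b0", v))

    def update_coefficients(self):
        lap = lambda v: -self.lam * abs(v)  # noqa: E731  Laplace log-prior
        for c in self.spec.fixed:
            self._mh_scalar(f"beta:{c}", lambda c=c: self.beta[c],
                            lambda v, c=c: self.beta.__setitem__(c, v),
                            xcol=self.cols[c], logprior=lap)
        for g in self.spec.groups:
            col = self.cols[self.spec.groups[g][self.gind[g]]]
            self._mh_scalar(f"gcoef:{g}", lambda g=g: self.gcoef[g],
                            lambda v, g=g: self.gcoef.__setitem__(g, v),
                            xcol=col, logprior=lap)

    def update_indicators(self):
        for g, cands in self.spec.groups.items():
            if len(cands) < 2:
                self.gind[g] = 0
                continue
            bv = self.gcoef[g]
            cur = self.gind[g]
            x_cur = self.cols[cands[cur]]
            lls = np.empty(len(cands))
            for j, cand in enumerate(cands):
                if j == cur:
                    lls[j] = np.sum(self.ll)
                else:
                    eta_j = self.eta + bv * (self.cols[cand] - x_cur)
                    lls[j] = np.sum(self.loglik(eta_j))
            pr = np.exp(lls - lls.max())
            pr /= pr.sum()
            new = int(self.rng.choice(len(cands), p=pr))
            if new != cur:
                self.eta = self.eta + bv * (self.cols[cands[new]] - x_cur)
                self.ll = self.loglik(self.eta)
                self.gind[g] = new

    def update_random_effects(self):
        for f, (codes, nl) in self.factors.items():
            key = f"b:{f}"
            bold = self.b[f]
            prop = bold + self.steps[key] * self.rng.standard_normal(nl)
            eta_new = self.eta + (prop - bold)[codes]
            ll_new = self.loglik(eta_new)
            dll = np.bincount(codes, weights=ll_new - self.ll, minlength=nl)
            dprior = -0.5 * (prop**2 - bold**2) / self.sig2[f]
            accept = np.log(self.rng.uniform(size=nl)) < (dll + dprior)
            if accept.any():
                bnew = np.where(accept, prop, bold)
                self.eta = self.eta + (bnew - bold)[codes]
                self.ll = self.loglik(self.eta)
                self.b[f] = bnew
            self.accepts[key][0] += int(accept.sum())
            self.accepts[key][1] += nl

    def _log_sig2_target(self, f, s2):
        b = self.b[f]
        lp = -0.5 * len(b) * np.log(2 * np.pi * s2) - 0.5 * np.sum(b**2) / s2
        if self.spec.variance_prior == "sd":
            lp -= 0.5 * np.log(s2)  # uniform on sd => density 1/(2 sd) on variance
        return lp

    def update_variances(self):
        bound = self.spec.variance_bound
        for f in self.factors:
            key = f"sig2:{f}"
            old = self.sig2[f]
            new = old * np.exp(self.steps[key] * self.rng.standard_normal())
            self.accepts[key][1] += 1
            if not (0.0 < new < bound):
                continue
            delta = (self._log_sig2_target(f, new) - self._log_sig2_target(f, old)
                     + np.log(new) - np.log(old))  # log-scale proposal Jacobian
            if np.log(self.rng.uniform()) < delta:
                self.sig2[f] = new
                self.accepts[key][0] += 1

    def update_lambda(self):
        k = len(self.beta) + len(self.gcoef)
        if k == 0:
            return
        lo, hi = self.spec.lambda_bounds
        rate = sum(abs(v) for v in self.beta.values()) + sum(
            abs(v) for v in self.gcoef.values()
        )
        u = self.rng.uniform()
        if rate <= 0:
            # density ~ lambda^k on (lo, hi)
            p = k + 1.0
            self.lam = float((lo**p + u * (hi**p - lo**p)) ** (1.0 / p))
            return
        dist = stats.gamma(a=k + 1.0, scale=1.0 / rate)
        c_lo, c_hi = dist.cdf(lo), dist.cdf(hi)
        if c_hi - c_lo < 1e-12:
            self.lam = lo if dist.cdf(lo) > 0.5 else hi
            return
        self.lam = float(dist.ppf(c_lo + u * (c_hi - c_lo)))

    def adapt_steps(self):
        for key, (acc, tot) in self.accepts.items():
            if tot == 0:
                continue
            rate = acc / tot
            target = 0.38 if key.startswith(("b0", "beta", "gcoef", "sig2")) else 0.35
            self.steps[key] = float(
                np.clip(self.steps[key] * np.exp(1.2 * (rate - target)), 1e-4, 10.0)
            )
            self.accepts[key] = [0, 0]


def _prepare(spec: ModelSpec, data: pd.DataFrame):
    y = data[spec.response].to_numpy(dtype=float)
    t = None
    if spec.likelihood == "exposure":
        t = data[spec.exposure_col].to_numpy(dtype=float)
        if np.any(t < 1):
            raise ValueError("interval lengths must be >= 1")
        if not np.any(y == 0):
            warnings.warn("no failing intervals; daily survival only bounded from below")
    else:
        if not (np.any(y == 0) and np.any(y == 1)):
            raise ValueError("logistic likelihood needs both used and available rows")
    cols: dict[str, np.ndarray] = {}
    for name in list(spec.fixed) + [c for g in spec.groups.values() for c in g]:
        if name not in data:
            raise KeyError(f"covariate column {name!r} missing from data")
        cols[name] = np.ascontiguousarray(data[name].to_numpy(dtype=float))
    factors = {}
    for f in spec.random:
        codes, levels = pd.factorize(data[f], sort=True)
        factors[f] = (codes.astype(np.int64), len(levels))
    return y, t, cols, factors


def fit(spec: ModelSpec, data: pd.DataFrame,
        settings: MCMCSettings | None = None, seed: int = 0) -> PosteriorDraws:
    """Sample the joint posterior of the specified model by MCMC.

    Runs ``settings.chains`` independent chains from over-dispersed starts,
    adapting random-walk step sizes during burn-in only, and retains every
    ``thin``-th post-burn-in draw.  Returns a :class:`PosteriorDraws` with
    the intercept, habitat coefficients, random-effect SDs, the Lasso
    tuning parameter ``lambda`` and per-group BLISS indicator traces.
    """
    settings = settings or MCMCSettings()
    y, t, cols, factors = _prepare(spec, data)
    nret = settings.retained
    pnames = (["intercept"] + [f"beta_{c}" for c in spec.fixed]
              + [f"beta_{g}" for g in spec.groups]
              + [f"sd_{f}" for f in factors] + (["lambda"] if spec.coefficient_names else []))
    params = {p: np.empty((settings.chains, nret)) for p in pnames}
    if settings.store_random_levels:
        for f, (_, nl) in factors.items():
            for l in range(nl):
                params[f"b_{f}[{l}]"] = np.empty((settings.chains, nret))
    indicators = {g: np.empty((settings.chains, nret), dtype=np.int64)
                  for g in spec.groups}
    ss = np.random.SeedSequence([int(seed), 0x5EED])
    child_seeds = ss.spawn(settings.chains)
    for ch in range(settings.chains):
        rng = np.random.default_rng(child_seeds[ch])
        state = _ChainState(spec, cols, y, t, factors, rng)
        for attempt in range(settings.init_attempts):
            state.initialize(y, t)
            # over-dispersed starts: jitter intercept and coefficients
            state.b0 += 0.5 * rng.standard_normal()
            for c in state.beta:
                state.beta[c] = 0.3 * rng.standard_normal()
            for g in state.gcoef:
                state.gcoef[g] = 0.3 * rng.standard_normal()
                state.gind[g] = int(rng.integers(len(spec.groups[g])))
            state.recompute_eta()
            if np.isfinite(state.total_ll()):
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initialization")
        kept = 0
        for it in range(settings.iterations):
            state.update_intercept()
            state.update_coefficients()
            if spec.groups:
                state.update_indicators()
            if factors:
                state.update_random_effects()
                state.update_variances()
            state.update_lambda()
            if settings.adapt and it < settings.burnin and (it + 1) % 50 == 0:
                state.adapt_steps()
            if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
                if kept < nret:
                    params["intercept"][ch, kept] = state.b0
                    for c in spec.fixed:
                        params[f"beta_{c}"][ch, kept] = state.beta[c]
                    for g in spec.groups:
                        params[f"beta_{g}"][ch, kept] = state.gcoef[g]
                        indicators[g][ch, kept] = state.gind[g]
                    for f in factors:
                        params[f"sd_{f}"][ch, kept] = np.sqrt(state.sig2[f])
                        if settings.store_random_levels:
                            for l, bv in enumerate(state.b[f]):
                                params[f"b_{f}[{l}]"][ch, kept] = bv
                    if spec.coefficient_names:
                        params["lambda"][ch, kept] = state.lam
                    kept += 1
    meta = {"likelihood": spec.likelihood, "chains": settings.chains,
            "iterations": settings.iterations, "burnin": settings.burnin,
            "thin": settings.thin, "seed": int(seed),
            "response": spec.response, "fixed": list(spec.fixed),
            "groups": {g: list(c) for g, c in spec.groups.items()},
            "random": list(spec.random)}
    return PosteriorDraws(params=params, indicators=indicators,
                          group_candidates={g: list(c) for g, c in spec.groups.items()},
                          meta=meta)


def bliss_select(spec: ModelSpec, data: pd.DataFrame,
                 settings: MCMCSettings | None = None, seed: int = 0):
    """Stage-1 scale selection: posterior indicator frequencies per group.

    Returns ``(selection, draws)`` where ``selection[group]`` holds the
    candidate frequencies and the modal winner.  Ties break toward the
    first candidate in list order (candidate lists are conventionally
    sorted by radius, so ties favour the smallest radius).
    """
    for g, cands in spec.groups.items():
        if len(cands) < 1:
            raise ValueError(f"group {g!r} has no candidates")
    draws = fit(spec, data, settings, seed)
    freqs = draws.indicator_frequencies()
    selection = {}
    for g, fmap in freqs.items():
        best, best_f = None, -1.0
        for cand in spec.groups[g]:
            if fmap[cand] > best_f:
                best, best_f = cand, fmap[cand]
        selection[g] = {"frequencies": fmap, "winner": best}
    return selection, draws


def final_spec_from_bliss(spec: ModelSpec, selection: dict) -> ModelSpec:
    """Stage-2 spec: each group replaced by its modal winner as a fixed effect."""
    winners = tuple(selection[g]["winner"] for g in spec.groups)
    return ModelSpec(likelihood=spec.likelihood,
                     fixed=tuple(spec.fixed) + winners,
                     groups={}, random=spec.random, response=spec.response,
                     exposure_col=spec.exposure_col,
                     lambda_bounds=spec.lambda_bounds,
                     variance_bound=spec.variance_bound,
                     variance_prior=spec.variance_prior)


def gelman_rubin(draws: PosteriorDraws | dict[str, np.ndarray]) -> dict[str, float]:
    """Potential scale reduction factor (classic Gelman-Rubin) per parameter.

    For m chains of n draws: within-chain variance W, between-chain
    variance B; PSRF = sqrt(((n-1)/n W + B/n) / W).  Values below 1.1 are
    the conventional convergence threshold.
    """
    params = draws.params if isinstance(draws, PosteriorDraws) else draws
    out = {}
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin needs >= 2 chains")
        m, n = arr.shape
        if n < 10:
            raise ValueError("gelman_rubin needs >= 10 retained draws per chain")
        means = arr.mean(axis=1)
        w = float(np.mean(arr.var(axis=1, ddof=1)))
        b_over_n = float(np.var(means, ddof=1))
        if w == 0.0:
            out[name] = 1.0 if b_over_n == 0.0 else np.inf
            continue
        vhat = (n - 1) / n * w + b_over_n
        out[name] = float(np.sqrt(vhat / w))
    return out
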