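"""Sampler correctness: recovery, shrinkage, BLISS, convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

from habsurv import mcmc

SHORT = mcmc.MCMCSettings(chains=2, iterations=2000, burnin=1000, thin=2)


def logistic_data(n, beta, b0=-1.6, seed=0, k_corr=0.0):
    """Used/available rows with one informative covariate."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (rng.uniform(size=n) < expit(b0 + beta * x)).astype(int)
    return pd.DataFrame({"used": y, "x": x})


def exposure_data(n_units, ds, seed=0, max_day=38, check=10):
    """Interval histories at constant daily survival ``ds`` (direct sim)."""
    rng = np.random.default_rng(seed)
    checks = list(range(check, max_day + 1, check))
    if checks[-1] != max_day:
        checks.append(max_day)
    rows = []
    for u in range(n_units):
        fail = rng.geometric(1 - ds) if ds < 1 else np.inf
        entry = 0
        for c in checks:
            y = int(fail > c)
            rows.append({"unit": u, "entry": entry, "exit": c,
                         "t": c - entry, "y": y})
            entry = c
            if y == 0:
                break
    return pd.DataFrame(rows)


def exposure_mle(eh):
    """Direct numeric MLE of constant daily survival (independent oracle)."""
    t = eh["t"].to_numpy(float)
    y = eh["y"].to_numpy(float)

    def nll(ds):
        p = ds**t
        return -np.sum(np.where(y == 1, np.log(p), np.log1p(-p)))

    res = minimize_scalar(nll, bounds=(1e-6, 1 - 1e-9), method="bounded")
    return float(res.x)


class TestFit:
    def test_logistic_recovers_known_coefficient(self):
        data = logistic_data(3000, beta=1.0, seed=4)
        spec = mcmc.ModelSpec("logistic", fixed=("x",))
        d = mcmc.fit(spec, data, SHORT, seed=1)
        draws = d.stacked("beta_x")
        assert abs(np.median(draws) - 1.0) < 3 * np.std(draws)

    def test_exposure_matches_mle_oracle(self):
        eh = exposure_data(500, ds=0.9749, seed=7)
        d = mcmc.fit(mcmc.ModelSpec("exposure"), eh, SHORT, seed=2)
        post_ds = expit(d.stacked("intercept"))
        mle = exposure_mle(eh)
        assert abs(np.median(post_ds) - mle) < 2 * np.std(post_ds)

    def test_shrinkage_strengthens_with_lambda(self):
        # null covariate: a tight high-lambda prior shrinks it harder
        data = logistic_data(400, beta=0.0, seed=9)
        meds = {}
        for lam in (0.1, 8.0):
            spec = mcmc.ModelSpec("logistic", fixed=("x",),
                                  lambda_bounds=(lam, lam * 1.0001))
            d = mcmc.fit(spec, data, SHORT, seed=3)
            meds[lam] = abs(d.median("beta_x"))
        assert meds[8.0] <= meds[0.1]

    def test_degenerate_outcomes_rejected(self):
        data = pd.DataFrame({"used": np.ones(50, dtype=int),
                             "x": np.random.default_rng(0).normal(size=50)})
        with pytest.raises(ValueError, match="both used and available"):
            mcmc.fit(mcmc.ModelSpec("logistic", fixed=("x",)), data, SHORT)

    def test_row_order_leaves_posterior_unchanged(self):
        data = logistic_data(1500, beta=0.8, seed=11)
        spec = mcmc.ModelSpec("logistic", fixed=("x",))
        d1 = mcmc.fit(spec, data, SHORT, seed=5)
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        d2 = mcmc.fit(spec, shuffled, SHORT, seed=5)
        sd = np.std(d1.stacked("beta_x"))
        assert abs(d1.median("beta_x") - d2.median("beta_x")) < 3 * sd

    def test_random_intercepts_absorb_group_shifts(self):
        rng = np.random.default_rng(21)
        n = 3000
        site = rng.integers(0, 6, n)
        shifts = np.array([-1.0, -0.5, 0.0, 0.2, 0.5, 1.0])
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < expit(-1.0 + 0.8 * x + shifts[site])).astype(int)
        data = pd.DataFrame({"used": y, "x": x, "site": site})
        spec = mcmc.ModelSpec("logistic", fixed=("x",), random=("site",))
        d = mcmc.fit(spec, data, SHORT, seed=6)
        draws = d.stacked("beta_x")
        assert abs(np.median(draws) - 0.8) < 3 * np.std(draws)
        assert d.median("sd_site") > 0.2


class TestBliss:
    @staticmethod
    def _scale_competition(n, beta, seed=0, rho=0.6):
        """Three correlated candidate columns; the second is causal."""
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        cands = {}
        for i, name in enumerate(["v_167.9", "v_439.5", "v_1451.7"]):
            cands[name] = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=n)
        y = (rng.uniform(size=n) < expit(-1.6 + beta * cands["v_439.5"])).astype(int)
        return pd.DataFrame({"used": y, **cands})

    def test_recovers_generating_scale(self):
        data = self._scale_competition(3000, beta=1.0, seed=13)
        spec = mcmc.ModelSpec("logistic",
                              groups={"v": ["v_167.9", "v_439.5", "v_1451.7"]})
        sel, _ = mcmc.bliss_select(spec, data, SHORT, seed=7)
        assert sel["v"]["winner"] == "v_439.5"
        assert sel["v"]["frequencies"]["v_439.5"] > 0.5

    def test_null_group_near_uniform(self):
        # a single dataset carries chance correlations whose likelihood
        # ratios do not vanish with n, so symmetry is a property of the
        # average over data replicates, not of one realization
        quick = mcmc.MCMCSettings(chains=2, iterations=1200, burnin=600, thin=2)
        spec = mcmc.ModelSpec("logistic",
                              groups={"v": ["v_167.9", "v_439.5", "v_1451.7"]})
        freqs = np.zeros(3)
        reps = 8
        for r in range(reps):
            data = self._scale_competition(1000, beta=0.0, seed=100 + r)
            sel, _ = mcmc.bliss_select(spec, data, quick, seed=200 + r)
            freqs += np.array(list(sel["v"]["frequencies"].values()))
        for f in freqs / reps:
            assert abs(f - 1.0 / 3.0) < 0.15

    def test_single_candidate_always_selected(self):
        data = self._scale_competition(500, beta=0.5, seed=19)
        spec = mcmc.ModelSpec("logistic", groups={"v": ["v_439.5"]})
        sel, draws = mcmc.bliss_select(spec, data, SHORT, seed=9)
        assert sel["v"]["frequencies"]["v_439.5"] == 1.0

    def test_duplicated_candidates_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            mcmc.ModelSpec("logistic", groups={"v": ["a", "a"]})


class TestGelmanRubin:
    def test_identical_chains_give_unity(self, rng):
        chain = rng.normal(size=500)
        gr = mcmc.gelman_rubin({"p": np.stack([chain, chain])})
        # B = 0 gives PSRF = sqrt((n-1)/n), unity up to the finite-n factor
        assert gr["p"] == pytest.approx(1.0, abs=2e-3)

    def test_stationary_chains_converged(self, rng):
        arr = rng.normal(size=(3, 5000))
        assert mcmc.gelman_rubin({"p": arr})["p"] < 1.1

    def test_disjoint_chains_flagged(self, rng):
        arr = rng.normal(size=(2, 500)) + np.array([[10.0], [-10.0]])
        assert mcmc.gelman_rubin({"p": arr})["p"] > 5.0

    def test_single_chain_errors(self, rng):
        with pytest.raises(ValueError, match="2 chains"):
            mcmc.gelman_rubin({"p": rng.normal(size=(1, 100))})

    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        arr = rng.normal(size=(4, 2000)) + rng.normal(size=(4, 1)) * 0.05
        ours = mcmc.gelman_rubin({"p": arr})["p"]
        theirs = float(az.rhat(az.from_dict(posterior={"p": arr}))["p"].item())
        assert ours == pytest.approx(theirs, abs=0.05)


class TestSettings:
    def test_retained_draw_arithmetic(self):
        s = mcmc.MCMCSettings(chains=3, iterations=30_000, burnin=20_000, thin=5)
        assert s.retained == 2000

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            mcmc.MCMCSettings(iterations=100, burnin=100)
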