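"""Shared fixtures: small synthetic worlds with known ground truth."""

import numpy as np
import pytest

from habsurv import synthetic as syn


@pytest.fixture(scope="session")
def small_world():
    """100x100 landscape with the default covariate set (3000 m across,
    large enough for every candidate window radius)."""
    cfg = syn.SimConfig(nrows=100, ncols=100, n_animals=30, seed=11,
                        availability_radius=1200.0)
    world = syn.generate_landscape(cfg)
    truth = syn.realize_truth(cfg, world)
    return cfg, world, truth


@pytest.fixture(scope="session")
def tiny_truth():
    """Minimal world/truth for fate simulation tests (no windowed covariates)."""
    from habsurv.covariates import CovariateSpec

    cfg = syn.SimConfig(
        nrows=40, ncols=40, n_animals=10, seed=5,
        fields={"rough": syn.FieldSpec(range_px=3.0)},
        max_window_radius=75.0,
        sd_site=0.0, sd_year=0.0, sd_animal=0.0,
        selection_coefs={"nesting": {"rough": 0.5}},
        survival_coefs={"nesting": {"intercept": 3.0}},
        availability_radius=300.0,
    )
    world = syn.generate_landscape(cfg)
    truth = syn.realize_truth(
        cfg, world, specs=[CovariateSpec("rough", "topography", "topographic")])
    return cfg, world, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def constant_ds_truth(ds: float, seed: int = 5, stage: str = "nesting"):
    """Truth object whose survival model is intercept-only at daily
    survival ``ds`` with no random effects (constant-hazard oracle)."""
    from scipy.special import logit

    cfg = syn.SimConfig(
        nrows=40, ncols=40, n_animals=10, seed=seed,
        fields={"flat": syn.FieldSpec(constant=0.0)},
        max_window_radius=75.0,
        sd_site=0.0, sd_year=0.0, sd_animal=0.0,
        survival_coefs={stage: {"intercept": float(logit(ds))}},
        availability_radius=300.0,
    )
    world = syn.generate_landscape(cfg)
    return cfg, world, syn.realize_truth(cfg, world)
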