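"""Generator properties: determinism, autocorrelation, selection, fates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habsurv import synthetic as syn
from habsurv.landscape import read_ascii_grid

from conftest import constant_ds_truth


def morans_i(arr: np.ndarray) -> float:
    """Moran's I with rook adjacency, computed directly (oracle)."""
    z = arr - arr.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    n_pairs = z[:, :-1].size + z[:-1, :].size
    return float((num / n_pairs) / z.var())


class TestLandscape:
    def test_constant_field_is_degenerate(self):
        cfg = syn.SimConfig(nrows=40, ncols=40,
                            fields={"c": syn.FieldSpec(constant=3.5)},
                            max_window_radius=75.0)
        world = syn.generate_landscape(cfg)
        assert np.all(world.bands["c"] == 3.5)

    def test_same_seed_identical_everything(self, tiny_truth):
        cfg, world, truth = tiny_truth
        cfg2 = syn.SimConfig(**{**cfg.__dict__})
        world2 = syn.generate_landscape(cfg2)
        for name in world.bands:
            np.testing.assert_array_equal(world.bands[name], world2.bands[name])
        truth2 = syn.realize_truth(cfg2, world2, specs=truth.specs)
        pd.testing.assert_frame_equal(truth.animals, truth2.animals)
        u1 = syn.simulate_used_points(world, truth, "nesting", 50)
        u2 = syn.simulate_used_points(world2, truth2, "nesting", 50)
        pd.testing.assert_frame_equal(u1, u2)
        units = pd.DataFrame({"unit": np.arange(40)})
        e1 = syn.simulate_fates(units, truth, "nesting")
        e2 = syn.simulate_fates(units, truth2, "nesting")
        pd.testing.assert_frame_equal(e1, e2)

    def test_autocorrelation_range_orders_morans_i(self):
        out = {}
        for rng_px in (1.0, 10.0):
            cfg = syn.SimConfig(nrows=80, ncols=80, seed=3,
                                fields={"f": syn.FieldSpec(range_px=rng_px)},
                                max_window_radius=75.0)
            out[rng_px] = morans_i(syn.generate_landscape(cfg).bands["f"])
        assert out[10.0] > out[1.0]

    def test_grid_too_small_names_radius(self):
        cfg = syn.SimConfig(nrows=20, ncols=20,
                            fields={"f": syn.FieldSpec()})
        with pytest.raises(ValueError, match="1451.7"):
            syn.generate_landscape(cfg)

    def test_ascii_grid_round_trip(self, tiny_truth, tmp_path):
        _, world, _ = tiny_truth
        world.write(str(tmp_path))
        arr, px, origin = read_ascii_grid(str(tmp_path / "dist_lek.asc"))
        np.testing.assert_allclose(arr, world.bands["dist_lek"], rtol=1e-6)
        assert px == world.pixel_size
        assert origin == pytest.approx(world.origin)


class TestUsedPoints:
    def test_null_selection_matches_availability(self):
        # beta = 0: used points are an independent uniform draw from the
        # availability domain, so two draws share a covariate distribution
        cfg = syn.SimConfig(nrows=100, ncols=100, n_animals=20, seed=21,
                            selection_coefs={"nesting": {"elevation": 0.0}},
                            availability_radius=1000.0)
        world = syn.generate_landscape(cfg)
        truth = syn.realize_truth(cfg, world)
        used = syn.simulate_used_points(world, truth, "nesting", 2000)
        avail = syn.simulate_used_points(world, truth, "nesting", 2000,
                                         rng=np.random.default_rng(777))
        a = world.extract("elevation", used["x"], used["y"])
        b = world.extract("elevation", avail["x"], avail["y"])
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_positive_selection_shifts_mean(self, small_world):
        cfg, world, truth = small_world
        used = syn.simulate_used_points(world, truth, "nesting", 2000)
        # availability reference: null draw from a zero-coefficient truth
        cfg0 = syn.SimConfig(**{**cfg.__dict__,
                                "selection_coefs": {"nesting": {"elevation": 0.0}}})
        truth0 = syn.realize_truth(cfg0, world)
        avail = syn.simulate_used_points(world, truth0, "nesting", 2000)
        elev_used = world.extract("elevation", used["x"], used["y"])
        elev_avail = world.extract("elevation", avail["x"], avail["y"])
        assert elev_used.mean() > elev_avail.mean()  # beta_elevation = +0.5

    def test_zero_points_keeps_schema(self, small_world):
        _, world, truth = small_world
        out = syn.simulate_used_points(world, truth, "nesting", 0)
        assert list(out.columns) == ["x", "y", "site", "year", "animal", "stage"]
        assert out.empty


class TestFates:
    def test_certain_survival_limit(self):
        _, _, truth = constant_ds_truth(ds=1 - 1e-15)
        units = pd.DataFrame({"unit": np.arange(100)})
        eh = syn.simulate_fates(units, truth, "nesting")
        assert (eh["y"] == 1).all()
        assert eh.groupby("unit")["t"].sum().eq(38).all()

    def test_constant_ds_cumulative_survival(self):
        ds = 0.9749
        _, _, truth = constant_ds_truth(ds=ds, seed=9)
        n = 2000
        eh = syn.simulate_fates(pd.DataFrame({"unit": np.arange(n)}), truth,
                                "nesting", check_interval=10)
        surv = (eh.groupby("unit")["y"].min() == 1).mean()
        expected = ds**38
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(surv - expected) < 3 * se

    def test_daily_checks_bookkeeping(self):
        _, _, truth = constant_ds_truth(ds=0.95, seed=13)
        units = pd.DataFrame({"unit": np.arange(200)})
        eh = syn.simulate_fates(units, truth, "nesting", check_interval=1)
        assert (eh["t"] == 1).all()
        per_unit = eh.groupby("unit")
        assert (per_unit["t"].sum() == per_unit["exit"].max()).all()
        assert (per_unit["t"].sum() <= 38).all()
        # at most one failing interval and it is the last
        for _, g in eh.groupby("unit"):
            fails = np.flatnonzero(g["y"].to_numpy() == 0)
            assert len(fails) <= 1
            if len(fails) == 1:
                assert fails[0] == len(g) - 1

    def test_nonpositive_duration_errors(self):
        _, _, truth = constant_ds_truth(ds=0.99)
        units = pd.DataFrame({"unit": [0]})
        with pytest.raises(ValueError):
            syn.simulate_fates(units, truth, "nesting", duration=0)
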