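"""HSI surfaces, isopleth/survival categorization, ranking, management."""

import numpy as np
import pytest

from habsurv import mapping as mp
from habsurv.mapping import CategorizedSurface


def make_sel_cat(classes):
    classes = np.asarray(classes, dtype=np.int8)
    return CategorizedSurface(classes=classes, kind="selection",
                              thresholds=(0.2, 0.4, 0.6),
                              labels=dict(mp.SELECTION_CLASSES))


def make_surv_cat(classes):
    classes = np.asarray(classes, dtype=np.int8)
    return CategorizedSurface(classes=classes, kind="survival",
                              thresholds=(0.3, 0.5, 0.7),
                              labels=dict(mp.SURVIVAL_CLASSES))


class TestHSI:
    def test_zero_covariates_give_half(self):
        w = np.exp(np.zeros((5, 5)))
        hsi = w / (1 + w)
        np.testing.assert_allclose(hsi, 0.5)

    def test_odds_ratio_identity(self):
        # two locations one covariate SD apart have HSI odds ratio exp(beta)
        beta = 0.7
        w1, w2 = np.exp(beta * 1.0), np.exp(beta * 2.0)
        h1, h2 = w1 / (1 + w1), w2 / (1 + w2)
        odds = (h2 / (1 - h2)) / (h1 / (1 - h1))
        assert odds == pytest.approx(np.exp(beta))

    def test_hsi_bounded_and_monotone(self, rng):
        w = np.exp(rng.normal(0, 3, 1000))
        hsi = w / (1 + w)
        assert np.all((hsi > 0) & (hsi < 1))
        order = np.argsort(w)
        assert np.all(np.diff(hsi[order]) >= 0)


class TestCategorizeSelection:
    def test_uniform_used_values_hit_canonical_thresholds(self, rng):
        used = rng.uniform(0, 1, 10_000)
        surface = rng.uniform(0, 1, (50, 50))
        cat = mp.categorize_selection(surface, used)
        np.testing.assert_allclose(cat.thresholds, (0.5, 0.75, 0.95), atol=0.02)

    def test_five_percent_of_used_points_in_high_class(self, rng):
        used = rng.normal(size=5000)
        cat = mp.categorize_selection(np.zeros((2, 2)), used)
        share_high = np.mean(used > cat.thresholds[2])
        assert share_high == pytest.approx(0.05, abs=0.01)

    def test_identical_used_values_error(self):
        with pytest.raises(ValueError, match="thresholds"):
            mp.categorize_selection(np.zeros((2, 2)), np.full(100, 0.4))

    def test_classes_partition_surface(self, rng):
        used = rng.uniform(0, 1, 1000)
        surface = rng.uniform(0, 1, (30, 30))
        cat = mp.categorize_selection(surface, used)
        assert set(np.unique(cat.classes)) <= {0, 1, 2, 3}

    def test_monotone_transform_equivariance(self, rng):
        # thresholds at used points: a monotone transform of surface and
        # used values yields identical classes
        used = rng.uniform(0.1, 0.9, 500)
        surface = rng.uniform(0.1, 0.9, (20, 20))
        c1 = mp.categorize_selection(surface, used)
        c2 = mp.categorize_selection(np.log(surface), np.log(used))
        np.testing.assert_array_equal(c1.classes, c2.classes)


class TestCategorizeSurvival:
    def test_boundaries_between_separated_clusters(self, rng):
        failed = rng.normal(0.2, 0.01, 200)
        hatched = rng.normal(0.8, 0.01, 200)
        surface = rng.uniform(0, 1, (20, 20))
        cat = mp.categorize_survival(surface, failed, hatched)
        lo, mid, hi = cat.thresholds
        assert 0.15 < lo < 0.25 and 0.45 < mid < 0.55 and 0.75 < hi < 0.85

    def test_single_shared_value_errors(self):
        with pytest.raises(ValueError):
            mp.categorize_survival(np.zeros((2, 2)), np.full(10, 0.5),
                                   np.full(10, 0.5))

    def test_classes_partition_masked_area(self, rng):
        failed = rng.normal(0.3, 0.05, 100)
        hatched = rng.normal(0.7, 0.05, 100)
        surface = rng.uniform(0, 1, (20, 20))
        mask = rng.uniform(size=(20, 20)) > 0.5
        cat = mp.categorize_survival(surface, failed, hatched, mask=mask)
        assert np.all(cat.classes[~mask] == -1)
        assert np.all(cat.classes[mask] >= 0)


class TestComposites:
    def test_identical_surfaces_preserve_ranking(self, rng):
        s = mp.SelectionSurface(hsi=rng.uniform(0.01, 1, (10, 10)), stage="a")
        comp = mp.composite_selection([s, s, s])
        np.testing.assert_allclose(comp, (s.hsi / s.hsi.max()) ** 3)
        assert np.all(np.argsort(comp.ravel()) == np.argsort(s.hsi.ravel()))

    def test_zero_stage_nulls_pixel_and_max_is_one(self, rng):
        a = rng.uniform(0.2, 1, (5, 5))
        b = a.copy()
        b[0, 0] = 0.0
        surfs = [mp.SelectionSurface(hsi=x, stage=s)
                 for x, s in ((a, "n"), (b, "e"), (a, "l"))]
        comp = mp.composite_selection(surfs)
        assert comp[0, 0] == 0.0
        for s in surfs:  # relativized per stage
            assert np.nanmax(s.hsi / np.nanmax(s.hsi)) == 1.0

    def test_survival_product_arithmetic(self):
        a = np.full((2, 2), 0.38)
        b = np.full((2, 2), 0.9)
        c = np.full((2, 2), 0.82)
        comp = mp.composite_survival([a, b, c])
        np.testing.assert_allclose(comp, 0.28044)

    def test_unit_stage_is_identity(self, rng):
        a = rng.uniform(0.1, 1, (4, 4))
        comp = mp.composite_survival([a, np.ones_like(a)])
        np.testing.assert_allclose(comp, a)

    def test_nonhabitat_pixels_unclassified(self, rng):
        a = rng.uniform(0.1, 1, (6, 6))
        mask = np.zeros((6, 6), bool)
        mask[:3] = True
        comp = mp.composite_survival([a], habitat_mask=mask)
        assert np.isnan(comp[3:]).all()
        cat = mp.categorize_survival(comp, rng.uniform(0.1, 0.4, 50),
                                     rng.uniform(0.6, 0.9, 50), mask=mask)
        assert np.all(cat.classes[~mask] == -1)


class TestRankOverlay:
    def test_truth_table_exact_on_all_twelve_cells(self):
        sel = np.repeat([1, 2, 3], 4).reshape(3, 4)
        surv = np.tile([0, 1, 2, 3], 3).reshape(3, 4)
        ranked = mp.rank_overlay(make_sel_cat(sel), make_surv_cat(surv))
        for (cs, cv), rank in mp.RANK_ORDER.items():
            assert ranked.ranks[(sel == cs) & (surv == cv)] == rank
        assert sorted(np.unique(ranked.ranks)) == list(range(1, 13))

    def test_top_and_bottom_ranks(self):
        ranked = mp.rank_overlay(make_sel_cat([[3, 3]]), make_surv_cat([[3, 0]]))
        assert ranked.ranks[0, 0] == 1    # high selection + high survival
        assert ranked.ranks[0, 1] == 12   # high selection + very low survival

    def test_area_unit_conversion(self):
        sel = np.full((100, 100), 3, dtype=np.int8)
        surv = np.full((100, 100), 3, dtype=np.int8)
        ranked = mp.rank_overlay(make_sel_cat(sel), make_surv_cat(surv),
                                 pixel_size=30.0)
        assert ranked.areas["km2"].sum() == pytest.approx(9.0)
        assert ranked.areas["pct_habitat"].sum() == pytest.approx(100.0)

    def test_unclassified_habitat_pixel_errors(self):
        sel = make_sel_cat([[2]])
        surv = make_surv_cat([[-1]])
        with pytest.raises(ValueError, match="without a survival class"):
            mp.rank_overlay(sel, surv)


class TestManagementCategories:
    def test_rule_examples(self):
        sel = make_sel_cat([[3, 0, 2]])
        surv = make_surv_cat([[3, 0, 1]])
        asui = np.array([[1, 1, 0]])
        out = mp.management_categories(sel, asui, surv)
        assert out[0, 0] == 1   # high sel + high surv + high use -> priority+
        assert out[0, 1] == 3   # nonhabitat inside high use -> general
        assert out[0, 2] == 4   # moderate selection, low/no use -> other

    def test_source_outside_high_use_is_priority(self):
        sel = make_sel_cat([[3]])
        surv = make_surv_cat([[3]])
        out = mp.management_categories(sel, np.array([[0]]), surv)
        assert out[0, 0] == 2


def test_area_summary_percentages_sum_to_100(rng):
    classes = rng.integers(0, 4, (40, 40)).astype(np.int8)
    tab = mp.area_summary(classes, mp.SELECTION_CLASSES, pixel_size=30.0)
    assert tab["pct_region"].sum() == pytest.approx(100.0)
    assert tab["pixels"].sum() == 1600
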