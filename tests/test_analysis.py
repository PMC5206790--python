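"""Areas, normalized growth curves, bottleneck detection, texture, P:Q."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import binary_fill_holes, label as nd_label

from angioca.analysis import (CurveSet, apparent_area, batch_fold_change,
                              bottleneck_day, effective_area, growth_curves,
                              growth_fold_change, intensity_histogram,
                              normalize_curves, pq_fraction_series,
                              render_intensity)

DX = 0.02


class TestAreas:
    def test_solid_block_apparent_equals_effective(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True
        assert effective_area(mask, DX) == pytest.approx(100 * DX * DX)
        assert apparent_area(mask, DX) == pytest.approx(100 * DX * DX)

    def test_interior_holes_count_toward_apparent_area(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True
        for hole in [(12, 12), (15, 16), (17, 13), (18, 18)]:
            mask[hole] = False
        assert effective_area(mask, DX) == pytest.approx(96 * DX * DX)
        assert apparent_area(mask, DX) == pytest.approx(100 * DX * DX)

    def test_checkerboard_closure_matches_fill_oracle(self):
        """Apparent > effective on a gappy patch, and the value matches an
        independent flood-fill (closing + hole fill) computation."""
        rng = np.random.default_rng(0)
        mask = np.zeros((60, 60), dtype=bool)
        patch = rng.random((20, 20)) < 0.55
        patch[::2, ::2] = True
        mask[20:40, 20:40] = patch
        app = apparent_area(mask, DX)
        assert app > effective_area(mask, DX)
        from scipy.ndimage import binary_closing
        from skimage.morphology import disk

        closed = binary_fill_holes(binary_closing(mask, structure=disk(2)))
        lab, _ = nd_label(closed, structure=np.ones((3, 3)))
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        assert app == pytest.approx(sizes.max() * DX * DX)

    def test_empty_mask_warns_and_returns_zero(self, caplog):
        with caplog.at_level("WARNING", logger="angioca"):
            assert apparent_area(np.zeros((10, 10), dtype=bool), DX) == 0.0
        assert any("empty" in r.message for r in caplog.records)


class TestNormalizedCurves:
    def test_constant_curve_normalizes_to_inverse_window(self):
        days = np.arange(29.0)
        out = normalize_curves(CurveSet(days, np.full((1, 29), 7.3)))
        assert np.allclose(out.values, 1.0 / 28.0)

    def test_unit_integral_and_scale_invariance(self, rng):
        days = np.arange(29.0)
        base = rng.uniform(1, 5, 29)
        curves = CurveSet(days, np.stack([base, 3.7 * base]))
        out = normalize_curves(curves)
        integrals = np.trapezoid(out.values, days, axis=1)
        assert integrals == pytest.approx([1.0, 1.0], abs=1e-12)
        assert np.allclose(out.values[0], out.values[1], rtol=1e-12)

    def test_zero_integral_curve_rejected(self):
        days = np.arange(29.0)
        with pytest.raises(ValueError):
            normalize_curves(CurveSet(days, np.zeros((1, 29))))


class TestBottleneckDay:
    def test_identical_curves_tie_break_to_day_zero(self, rng):
        days = np.arange(29.0)
        base = rng.uniform(1, 2, 29)
        day, sd = bottleneck_day(CurveSet(days, np.stack([base, base, base])))
        assert day == 0.0
        assert np.allclose(sd, 0.0)

    def test_fan_of_curves_pivoting_at_constructed_day(self):
        """A fan whose normalized members all cross at t*=17: the SD
        minimum recovers the pivot despite arbitrary per-curve scales."""
        days = np.arange(29.0)
        # perturbation vanishing at t*=17 with zero trapezoid integral, so
        # the pivot survives integral normalization exactly
        g0 = (days - 17.0) * (days + 7.78)
        u = (days - 17.0) ** 2
        g = g0 - (np.trapezoid(g0, days) / np.trapezoid(u, days)) * u
        slopes = np.linspace(-1.0, 1.0, 7) * 2e-5
        curves = np.stack([1.0 / 28.0 + s * g for s in slopes])
        assert curves.min() > 0
        curves *= np.linspace(1, 4, 7)[:, None]  # arbitrary rescaling
        day, sd = bottleneck_day(CurveSet(days, curves))
        assert day == 17.0
        # interior minimum, not a boundary artifact
        assert sd[17] < sd[0] and sd[17] < sd[-1]

    def test_tie_breaks_toward_earliest_day(self):
        days = np.arange(5.0)
        a = np.array([1.0, 2.0, 1.0, 2.0, 1.0])
        b = np.array([1.0, 2.0, 1.0, 2.0, 1.0])
        # two identical curves: SD identically zero; earliest day wins
        day, _ = bottleneck_day(CurveSet(days, np.stack([a, b])))
        assert day == 0.0

    def test_fewer_than_two_curves_rejected(self):
        with pytest.raises(ValueError):
            bottleneck_day(CurveSet(np.arange(3.0), np.ones((1, 3))))

    def test_invariant_under_per_curve_rescaling(self, rng):
        days = np.arange(29.0)
        vals = rng.uniform(1, 3, (5, 29))
        d1, _ = bottleneck_day(CurveSet(days, vals))
        d2, _ = bottleneck_day(CurveSet(days, vals * rng.uniform(0.1, 9, (5, 1))))
        assert d1 == d2


class TestIntensityHistogram:
    def test_unit_integral(self, rng):
        img = rng.uniform(0, 1000, (50, 50))
        mask = rng.random((50, 50)) < 0.4
        centres, dens = intensity_histogram(img, mask)
        width = centres[1] - centres[0]
        assert np.sum(dens) * width == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_degenerates_with_warning(self, caplog):
        img = np.full((20, 20), 5.0)
        mask = np.ones((20, 20), dtype=bool)
        with caplog.at_level("WARNING", logger="angioca"):
            centres, dens = intensity_histogram(img, mask)
        assert np.sum(dens > 0) == 1

    def test_smooth_texture_has_more_bright_mass_than_granular(self, rng):
        """Day-28-style homogeneous texture vs day-3-style granular
        texture: the smooth image carries more mass above intensity 0.5."""
        mask = np.ones((80, 80), dtype=bool)
        granular = (rng.random((80, 80)) < 0.25).astype(float)  # sparse specks
        smooth = np.clip(0.8 + 0.1 * rng.standard_normal((80, 80)), 0, 1)
        def high_mass(img):
            centres, dens = intensity_histogram(img, mask)
            width = centres[1] - centres[0]
            return np.sum(dens[centres > 0.5]) * width
        assert high_mass(smooth) > high_mass(granular)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            intensity_histogram(np.ones((5, 5)), np.zeros((5, 5), dtype=bool))

    def test_rendered_intensity_brighter_for_proliferative(self):
        from angioca.core import P, Q

        state = np.zeros((30, 30), dtype=np.int8)
        state[5:10, 5:10] = P
        state[20:25, 20:25] = Q
        img = render_intensity(state)
        assert img[7, 7] > img[22, 22] > 0


def _record(days, nP, nQ, area0=1.0, fold=2.0):
    days = np.asarray(days, dtype=float)
    area = np.linspace(area0, area0 * fold, len(days))
    return pd.DataFrame({"day": days, "n_P": nP, "n_Q": nQ,
                         "n_A": 0, "n_N": 0,
                         "effective_area_mm2": area,
                         "apparent_area_mm2": area * 1.2})


class TestPQAndFold:
    def test_all_proliferative_gives_unit_fraction(self):
        rec = _record(range(5), nP=[10, 20, 40, 80, 160], nQ=[0] * 5)
        out = pq_fraction_series([rec])
        assert np.allclose(out["mean"], 1.0)
        assert np.allclose(out["sd"].fillna(0), 0.0)

    def test_two_case_mean_and_sem_match_hand_computation(self):
        r1 = _record(range(3), nP=[8, 2, 1], nQ=[2, 8, 9])     # 0.8, 0.2, 0.1
        r2 = _record(range(3), nP=[6, 4, 3], nQ=[4, 6, 7])     # 0.6, 0.4, 0.3
        out = pq_fraction_series([r1, r2])
        assert out["mean"].values == pytest.approx([0.7, 0.3, 0.2])
        expected_sem = np.std([[0.8, 0.6], [0.2, 0.4], [0.1, 0.3]],
                              axis=1, ddof=1) / np.sqrt(2)
        assert out["sd"].values == pytest.approx(expected_sem)

    def test_day_with_no_living_cells_reported_missing(self):
        r = _record(range(3), nP=[5, 0, 5], nQ=[5, 0, 5])
        out = pq_fraction_series([r])
        assert np.isnan(out["mean"].iloc[1])
        assert out["n_cases"].iloc[1] == 0

    @pytest.mark.parametrize("fold", [1.0, 2.0])
    def test_fold_change_simple_ratios(self, fold):
        rec = _record(range(29), nP=[1] * 29, nQ=[0] * 29, fold=fold)
        assert growth_fold_change(rec) == pytest.approx(fold)

    def test_zero_initial_area_rejected(self):
        rec = _record(range(3), nP=[1, 1, 1], nQ=[0, 0, 0], area0=0.0)
        with pytest.raises(ValueError):
            growth_fold_change(rec)

    def test_batch_fold_matches_arithmetic_oracle(self, rng):
        folds = [1.3, 1.8, 2.4]
        recs = [_record(range(5), nP=[1] * 5, nQ=[0] * 5, fold=f) for f in folds]
        mean, sd = batch_fold_change(recs)
        assert mean == pytest.approx(np.mean(folds))
        assert sd == pytest.approx(np.std(folds, ddof=1))

    def test_growth_curves_require_common_day_grid(self):
        r1 = _record(range(5), nP=[1] * 5, nQ=[0] * 5)
        r2 = _record(range(4), nP=[1] * 4, nQ=[0] * 4)
        with pytest.raises(ValueError):
            growth_curves([r1, r2])
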