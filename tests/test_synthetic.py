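"""Generator behaviour: distributions, determinism, calibration, rasters."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lygusscout as ls
from lygusscout.records import CULTIVATED_CLASSES
from lygusscout.synthetic import calibrate_level_sds


class TestHierarchicalCounts:
    def test_pure_poisson_when_taylor_is_identity(self):
        # a = b = 1 puts the unit variance on the Poisson line and a pure
        # error share removes all hierarchy: counts are i.i.d. Poisson(3)
        spec = ls.HierarchySpec(
            n_states=2, districts_per_state=2, fields_per_district=40,
            variance_shares={"error": 1.0}, grand_mean=3.0,
            taylor_a=1.0, taylor_b=1.0, seed=5, total_sd=None)
        units = ls.generate_hierarchical_counts(spec, "sweep",
                                                units_per_quadrant=4)
        y = units["total"].to_numpy()
        assert len(y) == 160 * 16
        assert abs(y.mean() - 3.0) < 0.1
        assert abs(y.var(ddof=1) / y.mean() - 1.0) < 0.1

    def test_same_seed_reproduces_and_seeds_differ(self):
        spec = ls.HierarchySpec(seed=11)
        a = ls.generate_hierarchical_counts(spec, "sweep")
        b = ls.generate_hierarchical_counts(spec, "sweep")
        pd.testing.assert_frame_equal(a, b)
        c = ls.generate_hierarchical_counts(
            dataclasses.replace(spec, seed=12), "sweep")
        assert not a["total"].equals(c["total"])

    def test_schema_and_design(self):
        units = ls.generate_hierarchical_counts(ls.HierarchySpec(seed=0), "drop")
        assert set(units["quadrant"]) == {1, 2, 3, 4}
        assert (units["total"] == units["adults"] + units["nymphs"]).all()
        assert (units["growth_stage"] == "bloom").all()
        assert (units["unit_size"] == 1.5).all()
        # drop-cloth default: two 1.5 row-m units per quadrant
        per_quad = units.groupby(["field_id", "quadrant"]).size()
        assert (per_quad == 2).all()

    def test_pool_spec_matches_printed_moments(self):
        # validation-pool emulation: unit mean ~2.9, SD ~4.4 across seeds
        means, sds = [], []
        for s in range(15):
            spec = ls.taylor_pool_spec(2.9, 4.4, 0.95, 1.11, 94, seed=s)
            u = ls.generate_hierarchical_counts(spec, "sweep")
            means.append(u["total"].mean())
            sds.append(u["total"].std())
        assert abs(np.mean(means) - 2.9) < 0.35
        assert abs(np.mean(sds) - 4.4) < 0.9

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ls.HierarchySpec(variance_shares={"field": 0.5, "error": 0.2})
        with pytest.raises(ValueError, match="unknown"):
            ls.HierarchySpec(variance_shares={"plot": 1.0})

    def test_underdispersion_without_fallback_raises(self):
        spec = ls.HierarchySpec(variance_shares={"error": 1.0},
                                grand_mean=1.0, taylor_a=0.5, taylor_b=1.0,
                                seed=0, total_sd=None)
        with pytest.raises(ValueError, match="fallback"):
            ls.generate_hierarchical_counts(spec, "sweep",
                                            poisson_fallback=False)

    def test_level_sd_calibration_reproduces_shares_analytically(self):
        # sequential raw-scale components implied by the solved sigmas must
        # return the requested shares
        spec = ls.HierarchySpec(
            variance_shares={"year": 0.1, "field": 0.4, "quadrant": 0.3,
                             "error": 0.2},
            grand_mean=2.0, taylor_a=1.0, taylor_b=1.2, seed=0, total_sd=None)
        sigmas, v_tot = calibrate_level_sds(spec)
        mu = spec.grand_mean
        cum = 1.0
        for lvl in ("year", "state", "district", "field", "quadrant"):
            v = np.expm1(sigmas[lvl] ** 2)
            vc = mu**2 * cum * v
            assert vc == pytest.approx(spec.share(lvl) * v_tot, rel=1e-6)
            cum *= 1.0 + v


class TestTaylorCalibration:
    def test_sweep_refit_centred_on_nominal(self):
        cal = ls.calibrate_taylor_generator(2.9, 4.4, 0.95, 1.11, 94, 4, seed=1)
        assert abs(cal.refit_median_a - 0.95) < 0.05
        assert abs(cal.refit_median_b - 1.11) < 0.05
        # the naive (uncalibrated) generating pair under-delivers, so the
        # calibrated pair must sit above it
        assert cal.a_gen > 0.95 or cal.b_gen > 1.11

    def test_calibration_deterministic(self):
        c1 = ls.calibrate_taylor_generator(0.7, 1.3, 1.08, 1.17, 66, 8, seed=2)
        c2 = ls.calibrate_taylor_generator(0.7, 1.3, 1.08, 1.17, 66, 8, seed=2)
        assert (c1.a_gen, c1.b_gen) == (c2.a_gen, c2.b_gen)


class TestRetention:
    def test_constant_rate_without_slope_or_random_effects(self):
        spec = ls.taylor_pool_spec(2.9, 4.4, 0.95, 1.11, 60, seed=3)
        units = ls.generate_hierarchical_counts(spec, "sweep")
        ret = ls.generate_retention(units, beta0=np.log(10.0), beta1=0.0,
                                    seed=4)
        assert (ret["retained"] <= ret["positions_checked"]).all()
        assert abs(ret["retained"].mean() - 10.0) < 0.5

    def test_mean_retained_at_threshold_density(self, toy_units):
        # at 8 insects per unit the retained mean should match the truncated
        # Poisson expectation of the log-linear rate (~22.5 of 25 positions,
        # i.e. ~90% retention)
        units = toy_units.assign(total=8, adults=8, nymphs=0)
        beta0 = np.log(23.4)
        beta1 = (np.log(0.899 * 25) - beta0) / 8.0
        lam = np.exp(beta0 + beta1 * 8.0)
        k = np.arange(0, 200)
        oracle = float(np.sum(np.minimum(k, 25) * stats.poisson.pmf(k, lam)))
        reps = [ls.generate_retention(units, beta0, beta1, seed=s)["retained"].mean()
                for s in range(40)]
        assert np.mean(reps) == pytest.approx(oracle, abs=0.35)
        # truncation at 25 positions shaves ~0.9 off the log-linear rate
        assert 0.899 * 25 == pytest.approx(22.5, abs=0.03)
        assert oracle == pytest.approx(22.5, abs=1.2)

    def test_density_pairing_is_quadrant_mean(self, toy_units):
        ret = ls.generate_retention(toy_units, beta0=2.0, beta1=0.0, seed=0)
        merged = ret.set_index(["field_id", "quadrant"])["density"]
        assert merged.loc[("A", 3)] == 2.0
        assert merged.loc[("B", 1)] == 1.0


class TestLandscapeGenerator:
    def test_invariants_and_determinism(self):
        land1, ds1 = ls.generate_landscape_dataset(30, seed=9)
        land2, ds2 = ls.generate_landscape_dataset(30, seed=9)
        pd.testing.assert_frame_equal(land1, land2)
        assert np.array_equal(ds1.y, ds2.y)
        props = land1[list(ls.LANDSCAPE_CLASSES)].to_numpy()
        assert (props >= 0).all() and (props <= 1).all()
        for cls in CULTIVATED_CLASSES:
            assert (land1["agriculture"] >= land1[cls] - 1e-9).all()
        # rows pair to two visits per field sharing coordinates
        assert len(ds1) == 60
        assert ds1.truth["sigma2"] == 0.5

    def test_iid_poisson_limit(self):
        _, ds = ls.generate_landscape_dataset(
            200, effects={}, spatial_params={"sigma2": 0.0, "range_km": 1.0},
            stage_sd=0.0, offset_range=(1, 1), alpha0=0.0, seed=10)
        y = ds.y
        assert abs(y.mean() - 1.0) < 0.12
        assert abs(y.var(ddof=1) / max(y.mean(), 1e-9) - 1.0) < 0.15

    def test_rejects_tiny_designs_and_bad_params(self):
        with pytest.raises(ValueError, match="n_fields"):
            ls.generate_landscape_dataset(5, seed=0)
        with pytest.raises(ValueError, match="range_km"):
            ls.generate_landscape_dataset(
                20, spatial_params={"sigma2": 1.0, "range_km": 0.0}, seed=0)


class TestRasterBuffer:
    def test_uniform_raster(self):
        raster = np.ones((10, 10), int)
        out = ls.raster_buffer_proportions(raster, 30.0, (150.0, 150.0), 100.0)
        assert out == {1: 1.0}

    def test_two_class_hand_count(self):
        # 30 m cells, buffer 100 m at (150, 150): 32 cell centres fall inside
        # (6x6 block minus the four corner cells); class A occupies the two
        # westernmost included columns -> 10 of 32 cells
        raster = np.ones((10, 10), int)
        raster[:, :4] = 2
        out = ls.raster_buffer_proportions(raster, 30.0, (150.0, 150.0), 100.0)
        assert out[2] == pytest.approx(10 / 32)
        assert out[1] == pytest.approx(22 / 32)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_sub_cell_buffer_hits_single_cell(self):
        raster = np.arange(100).reshape(10, 10)
        out = ls.raster_buffer_proportions(raster, 30.0, (40.0, 40.0), 5.0)
        assert out == {11: 1.0}

    def test_buffer_outside_extent_raises(self):
        with pytest.raises(ValueError, match="extent"):
            ls.raster_buffer_proportions(np.ones((5, 5), int), 30.0,
                                         (10.0, 10.0), 50.0)
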