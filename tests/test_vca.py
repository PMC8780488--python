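"""Variance components: closed forms, invariance, recovery, CV test."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lygusscout as ls
from tests.conftest import make_units


def _gaussian_nested_frame(nf, nq, nu, vc_field, vc_quad, vc_err, seed):
    rng = np.random.default_rng(seed)
    f = rng.normal(0, np.sqrt(vc_field), nf)
    q = rng.normal(0, np.sqrt(vc_quad), (nf, nq))
    y = (10.0 + f[:, None, None] + q[:, :, None]
         + rng.normal(0, np.sqrt(vc_err), (nf, nq, nu))).ravel()
    frame = pd.DataFrame({
        "year": 2019, "state": "NC", "district": "NC-D1",
        "field_id": np.repeat([f"F{i:03d}" for i in range(nf)], nq * nu),
        "quadrant": np.tile(np.repeat(np.arange(1, nq + 1), nu), nf),
        "unit": np.tile(np.arange(1, nu + 1), nf * nq),
        "method": "sweep", "growth_stage": "squaring", "unit_size": 100.0,
        "adults": y, "nymphs": 0.0, "total": y,
    })
    return frame


class TestNestedVCA:
    def test_balanced_two_level_closed_form(self):
        # 3 fields x 4 replicates, hand ANOVA: MSB = 36, MSW = 42/9,
        # vc_between = (MSB - MSW)/4, vc_within = MSW
        units = make_units({"A": [1, 2, 3, 6], "B": [4, 5, 6, 9],
                            "C": [7, 8, 9, 12]})
        units["quadrant"] = 1
        units["unit"] = units.groupby("field_id").cumcount() + 1
        t = ls.fit_nested_vca(units)
        assert t["field"]["vc"] == pytest.approx((36 - 42 / 9) / 4)
        assert t["error"]["vc"] == pytest.approx(42 / 9)
        assert t["field"]["df"] == 2
        assert t["error"]["df"] == 9
        assert t.to_frame()["pct_variation"].sum() == pytest.approx(100.0)

    def test_constant_response_gives_zero_components(self):
        units = make_units({"A": [5, 5, 5, 5], "B": [5, 5, 5, 5]})
        t = ls.fit_nested_vca(units).to_frame()
        assert (t["vc"] == 0).all()
        assert (t["pct_variation"] == 0).all()

    def test_percent_variation_scale_invariant(self):
        units = make_units({"A": [1, 4, 2, 7], "B": [3, 0, 5, 2],
                            "C": [9, 2, 4, 4]})
        t1 = ls.fit_nested_vca(units).to_frame()
        scaled = units.assign(total=units["total"] * 7.0,
                              adults=units["adults"] * 7.0)
        t2 = ls.fit_nested_vca(scaled).to_frame()
        np.testing.assert_allclose(t1["pct_variation"], t2["pct_variation"],
                                   atol=1e-8)

    def test_negative_component_truncated_to_zero(self):
        # group means identical but huge within-group spread: the
        # between-field moment estimate goes negative and must clamp at 0
        units = make_units({"A": [0, 20, 0, 20], "B": [10, 10, 9, 11]})
        units["quadrant"] = 1
        units["unit"] = units.groupby("field_id").cumcount() + 1
        t = ls.fit_nested_vca(units)
        assert t["field"]["vc"] == 0.0
        assert (t.to_frame()["vc"] >= 0).all()

    def test_gaussian_nested_recovery(self):
        frame = _gaussian_nested_frame(200, 4, 2, 4.0, 2.0, 1.0, seed=1)
        t = ls.fit_nested_vca(frame)
        assert t["field"]["vc"] == pytest.approx(4.0, rel=0.25)
        assert t["field:quadrant"]["vc"] == pytest.approx(2.0, rel=0.15)
        assert t["error"]["vc"] == pytest.approx(1.0, rel=0.1)

    def test_count_generator_share_recovery(self):
        # generated at field 45% / quadrant 32% / error 23%: the averaged
        # recovered percentages stay within +-10 points of the target
        spec = ls.HierarchySpec(
            n_states=5, districts_per_state=2, fields_per_district=10,
            variance_shares={"field": 0.45, "quadrant": 0.32, "error": 0.23},
            grand_mean=2.9, taylor_a=0.95, taylor_b=1.11, seed=0,
            total_sd=None)
        target = {"field": 45.0, "field:quadrant": 32.0, "error": 23.0}
        acc = {k: [] for k in target}
        for s in range(12):
            units = ls.generate_hierarchical_counts(
                dataclasses.replace(spec, seed=s), "sweep",
                units_per_quadrant=2)
            t = ls.fit_nested_vca(units)
            for k in target:
                acc[k].append(t[k]["pct_variation"])
        for k, tgt in target.items():
            assert abs(np.mean(acc[k]) - tgt) < 10.0

    def test_too_few_observations(self):
        units = make_units({"A": [1]})
        with pytest.raises(ValueError, match="at least 2"):
            ls.fit_nested_vca(units)


class TestCVTest:
    def test_identical_samples(self):
        out = ls.cv_asymptotic_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rej = sum(
            ls.cv_asymptotic_test(rng.gamma(2, 1, 150),
                                  rng.gamma(2, 1, 150))["p_value"] < 0.05
            for _ in range(400))
        assert 0.01 <= rej / 400 <= 0.09

    def test_detects_unequal_cv(self):
        rng = np.random.default_rng(3)
        a = rng.gamma(20.0, 1.0, 300)   # CV ~ 0.22
        b = rng.gamma(1.0, 1.0, 300)    # CV ~ 1.0
        assert ls.cv_asymptotic_test(a, b)["p_value"] < 1e-6

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            ls.cv_asymptotic_test([1.0], [1, 2, 3])
        with pytest.raises(ValueError, match="mean"):
            ls.cv_asymptotic_test([0, 0, 0], [1, 2, 3])
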