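"""Power-law fits, Green's formula, stop lines and resampling validation."""

import numpy as np
import pandas as pd
import pytest

import lygusscout as ls
from tests.conftest import make_units


def _exact_law_units(a, b, means):
    """Two units per field placed at m +- d so the sample variance is a*m**b."""
    rows = []
    for i, m in enumerate(means):
        d = np.sqrt(a * m**b / 2.0)
        for j, val in enumerate((m - d, m + d)):
            rows.append(dict(year=2019, state="NC", district="NC-D1",
                             field_id=f"F{i:03d}", quadrant=j + 1, unit=1,
                             method="sweep", growth_stage="squaring",
                             unit_size=100.0, adults=val, nymphs=0.0,
                             total=val))
    return pd.DataFrame(rows)


class TestFitTaylor:
    def test_poisson_line_exact(self):
        fit = ls.fit_taylor(_exact_law_units(1.0, 1.0, [1, 2, 4, 8]))
        assert fit.a == pytest.approx(1.0, abs=1e-10)
        assert fit.b == pytest.approx(1.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_inversion_of_printed_sweep_parameters(self):
        means = np.geomspace(0.3, 30, 20)
        fit = ls.fit_taylor(_exact_law_units(0.95, 1.11, means))
        assert fit.a == pytest.approx(0.95, abs=1e-10)
        assert fit.b == pytest.approx(1.11, abs=1e-10)
        # perfectly colinear pairs leave no residual: the CI collapses on a
        assert fit.ci_a[0] == pytest.approx(0.95, abs=1e-8)
        assert fit.ci_a[1] == pytest.approx(0.95, abs=1e-8)

    def test_zero_groups_excluded(self):
        units = pd.concat([
            _exact_law_units(1.0, 1.0, [1, 2, 4]),
            make_units({"Z": [0, 0, 0, 0]}),
        ], ignore_index=True)
        fit = ls.fit_taylor(units)
        assert fit.n_groups == 3
        assert fit.n_excluded == 1

    def test_too_few_groups(self):
        with pytest.raises(ValueError, match="3 usable groups"):
            ls.fit_taylor(_exact_law_units(1.0, 1.0, [1, 2]))


class TestGreenSampleSize:
    def test_mean_free_when_b_is_two(self):
        for m in (0.1, 1.0, 50.0):
            assert ls.green_sample_size(1.0, 2.0, m, 0.5) == pytest.approx(4.0)

    def test_drop_cloth_plug_in(self):
        # direct arithmetic: 1.08 * 0.7**(-0.83) / 0.0625
        n = ls.green_sample_size(1.08, 1.17, 0.7, 0.25)
        assert n == pytest.approx(1.08 * 0.7 ** (1.17 - 2.0) / 0.25**2)
        assert round(n, 1) == 23.2

    def test_achieves_requested_precision(self, rng):
        # brute force: sampling ceil(N) units from a pool with the matching
        # Taylor variance yields relative SE ~ D
        a, b, m, d_target = 1.08, 1.17, 0.7, 0.25
        n = int(np.ceil(ls.green_sample_size(a, b, m, d_target)))
        var = a * m**b
        reps = 3000
        lam = rng.gamma(m**2 / (var - m), (var - m) / m, (reps, n))
        draws = rng.poisson(lam)
        rel_se = np.sqrt(var / n) / m
        assert rel_se == pytest.approx(d_target, rel=0.05)
        achieved = draws.mean(axis=1).std(ddof=1) / m
        assert achieved == pytest.approx(d_target, rel=0.1)

    def test_monotonicities(self):
        base = ls.green_sample_size(1.0, 1.3, 2.0, 0.25)
        assert ls.green_sample_size(1.0, 1.3, 4.0, 0.25) < base
        assert ls.green_sample_size(1.0, 1.3, 2.0, 0.5) < base
        assert ls.green_sample_size(2.0, 1.3, 2.0, 0.25) > base

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ls.green_sample_size(1.0, 1.1, 0.0, 0.25)
        with pytest.raises(ValueError):
            ls.green_sample_size(1.0, 1.1, 1.0, 1.5)


class TestStopLine:
    def test_poisson_case_constant_boundary(self):
        table = ls.stop_line(1.0, 1.0, 0.25, 10)
        np.testing.assert_allclose(table["T_n"], 16.0)

    @pytest.mark.parametrize("a,b,d", [(0.95, 1.11, 0.25), (1.08, 1.17, 0.25),
                                       (1.0, 1.5, 0.1), (2.0, 1.2, 0.4)])
    def test_algebraic_identity_with_green(self, a, b, d):
        # solving T_n / n = m must reproduce Green's N = n
        table = ls.stop_line(a, b, d, 50)
        m = table["T_n"] / table["n"]
        np.testing.assert_allclose(
            [ls.green_sample_size(a, b, mi, d) for mi in m],
            table["n"], rtol=1e-10)

    def test_drop_cloth_boundary_value(self):
        table = ls.stop_line(1.08, 1.17, 0.25, 23)
        assert table["T_n"].iloc[22] / 23 == pytest.approx(0.70, abs=0.02)

    def test_degenerate_b(self):
        with pytest.raises(ValueError, match="a/D"):
            ls.stop_line(1.0, 2.0, 0.25, 10)


class TestResampleValidation:
    def test_constant_pool_is_deterministic(self):
        res = ls.resample_validation([2] * 50, 0.95, 1.11, D=0.25, n_sim=40,
                                     seed=1)
        expect = int(np.ceil(ls.green_sample_size(0.95, 1.11, 2.0, 0.25)))
        assert res.nmin == res.nmax == expect
        assert res.nsd == 0.0
        assert res.navg == expect

    def test_seed_reproducibility(self):
        pool = ls.negative_binomial_pool(2.9, 4.4, 330, seed=3)
        r1 = ls.resample_validation(pool, 0.95, 1.11, seed=9, n_sim=100)
        r2 = ls.resample_validation(pool, 0.95, 1.11, seed=9, n_sim=100)
        assert r1.per_sim == r2.per_sim

    def test_terminal_mean_tracks_pool_mean(self):
        pool = ls.negative_binomial_pool(2.9, 4.4, 330, seed=5)
        res = ls.resample_validation(pool, 0.95, 1.11, n_sim=500, seed=6)
        term_means = np.array([m for _, m in res.per_sim])
        # the sequential rule stops early on lucky high draws, so terminal
        # means are biased upward; the bias stays bounded (~25% here) and
        # explains why the resampled Navg exceeds the plug-in sample size
        assert term_means.mean() >= pool.mean()
        assert term_means.mean() == pytest.approx(pool.mean(), rel=0.4)

    def test_all_zero_pool_rejected(self):
        with pytest.raises(ValueError, match="positive pooled mean"):
            ls.resample_validation([0, 0, 0], 1.0, 1.1)

    def test_plan_object_round_trip(self):
        fit = ls.fit_taylor(_exact_law_units(0.95, 1.11,
                                             np.geomspace(0.5, 20, 12)))
        plan = ls.SamplingPlan.from_fit(fit, precision_D=0.25, n_max=30)
        assert plan.sample_size(2.9) == pytest.approx(
            ls.green_sample_size(0.95, 1.11, 2.9, 0.25), rel=1e-9)
        assert (plan.stop_table["T_n"] > 0).all()
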