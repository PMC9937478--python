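import numpy as np
import pytest

from saltcost.model import ModelSettings, run_deterministic
from saltcost.uncertainty import (MCConfig, lognormal_params,
                                  percentile_interval, run_monte_carlo,
                                  sample_lognormal)

from conftest import make_small_bundle


class TestLognormalParams:
    def test_degenerate_sd_zero(self):
        mu, sigma = lognormal_params(7.0, 0.0)
        assert mu == pytest.approx(np.log(7.0))
        assert sigma == 0.0

    def test_closed_form_oracle(self):
        mu, sigma = lognormal_params(10.0, 5.4)
        expected_sigma = np.sqrt(np.log(1.0 + (5.4 / 10.0) ** 2))
        assert sigma == pytest.approx(expected_sigma, rel=1e-12)
        assert sigma == pytest.approx(0.5059, abs=5e-4)
        assert mu == pytest.approx(np.log(10.0) - expected_sigma ** 2 / 2, rel=1e-12)

    def test_sampling_round_trip_reproduces_moments(self):
        rng = np.random.default_rng(12345)
        x = sample_lognormal(rng, 10.0, 5.4, size=1_000_000)
        assert x.mean() == pytest.approx(10.0, rel=0.01)
        assert x.std() == pytest.approx(5.4, rel=0.01)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            lognormal_params(0.0, 1.0)


class TestPercentileInterval:
    def test_constant_samples_collapse(self):
        lo, hi = percentile_interval([3.0] * 50, 0.95)
        assert lo == hi == 3.0

    def test_sort_and_interpolate_oracle_1_to_1000(self):
        samples = np.arange(1, 1001, dtype=float)
        lo, hi = percentile_interval(samples, 0.95)
        # rank (n-1)*0.025 = 24.975 -> 25.975 after the +1 offset
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_level_near_one_approaches_min_max(self):
        samples = np.arange(1, 101, dtype=float)
        lo, hi = percentile_interval(samples, 1.0 - 1e-9)
        assert lo == pytest.approx(1.0, abs=1e-5)
        assert hi == pytest.approx(100.0, abs=1e-5)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            percentile_interval([], 0.95)


class TestMCConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            MCConfig(draws=0)
        with pytest.raises(ValueError):
            MCConfig(ui_level=1.0)
        with pytest.raises(ValueError):
            MCConfig(cost_rel_se=-0.1)


class TestRunMonteCarlo:
    def test_degenerate_sampling_equals_deterministic(self, small_bundle):
        cfg = MCConfig(draws=64, seed=0, intake_rel_se=0.0, cost_rel_se=0.0,
                       rr_log_se_frac=0.0)
        summary = run_monte_carlo(small_bundle, cfg)
        det = run_deterministic(small_bundle)
        point = summary.point("direct_total")
        lo, hi = summary.interval("direct_total")
        assert point == lo == hi
        assert point == pytest.approx(det.report.grand_total, rel=1e-12)

    def test_same_seed_bit_identical(self, small_bundle):
        cfg = MCConfig(draws=256, seed=9)
        a = run_monte_carlo(small_bundle, cfg)
        b = run_monte_carlo(small_bundle, cfg)
        assert a.table.equals(b.table)

    def test_different_seeds_differ(self, small_bundle):
        a = run_monte_carlo(small_bundle, MCConfig(draws=256, seed=1))
        b = run_monte_carlo(small_bundle, MCConfig(draws=256, seed=2))
        assert not a.table.equals(b.table)

    def test_doubling_cost_means_doubles_cost_points(self):
        bundle = make_small_bundle()
        doubled = bundle.with_(
            cost_table=bundle.cost_table.assign(
                annual_cost=bundle.cost_table["annual_cost"] * 2.0))
        cfg = MCConfig(draws=10_000, seed=4)
        a = run_monte_carlo(bundle, cfg)
        b = run_monte_carlo(doubled, cfg)
        # relative SEs scale the sampling SD with the mean, and the cost
        # substreams reuse the same normals, so doubling is exact per draw
        assert b.point("direct_total") == pytest.approx(
            2.0 * a.point("direct_total"), rel=1e-9)
        assert b.point("service::hospitalization") == pytest.approx(
            2.0 * a.point("service::hospitalization"), rel=1e-9)

    def test_ui_width_shrinks_with_input_sds(self, small_bundle):
        widths = []
        for scale in (1.0, 0.5, 0.0):
            cfg = MCConfig(draws=2_000, seed=5,
                           intake_rel_se=0.10 * scale,
                           cost_rel_se=0.10 * scale,
                           rr_log_se_frac=0.10 * scale)
            s = run_monte_carlo(small_bundle, cfg)
            lo, hi = s.interval("direct_total")
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2] == 0.0

    def test_median_converges_to_deterministic_as_sds_vanish(self, small_bundle):
        det = run_deterministic(small_bundle).report.grand_total
        errs = []
        for se in (0.10, 0.01):
            cfg = MCConfig(draws=4_000, seed=6, intake_rel_se=se,
                           cost_rel_se=se, rr_log_se_frac=se)
            s = run_monte_carlo(small_bundle, cfg)
            errs.append(abs(s.point("direct_total") - det) / det)
        assert errs[1] < errs[0]
        assert errs[1] < 0.005

    def test_adding_outputs_does_not_perturb_streams(self, small_bundle):
        """Substreams are keyed per input cell, so dropping an entire cost
        service leaves the remaining cells' draws untouched."""
        cfg = MCConfig(draws=500, seed=11)
        full = run_monte_carlo(small_bundle, cfg)
        trimmed_bundle = small_bundle.with_(
            cost_table=small_bundle.cost_table.query(
                "service == 'hospitalization'").reset_index(drop=True))
        trimmed = run_monte_carlo(trimmed_bundle, cfg)
        name = "cell::CHD::hospitalization::male"
        assert trimmed.point(name) == full.point(name)
        assert trimmed.interval(name) == full.interval(name)

    def test_trace_returns_per_draw_frame(self, small_bundle):
        cfg = MCConfig(draws=32, seed=0)
        summary, frame = run_monte_carlo(small_bundle, cfg, trace=True)
        assert len(frame) == 32
        assert "direct_total" in frame.columns

    def test_productivity_couples_to_attributable_fraction(self, small_bundle):
        """In 'total' mortality mode the losses inherit MC uncertainty; in
        'attributable' mode the deaths are taken as given and stay fixed."""
        cfg = MCConfig(draws=500, seed=8)
        total_mode = run_monte_carlo(small_bundle, cfg,
                                     ModelSettings(mortality_kind="total"))
        attrib_mode = run_monte_carlo(small_bundle, cfg,
                                      ModelSettings(mortality_kind="attributable"))
        lo_t, hi_t = total_mode.interval("productivity_total")
        lo_a, hi_a = attrib_mode.interval("productivity_total")
        assert hi_t > lo_t
        assert hi_a == lo_a
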