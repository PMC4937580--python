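"""Cascade-impactor reduction: cumulative curve, quantiles, size metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from aerodepo import (
    AerosolSpec,
    EmptyRunError,
    ExtrapolationError,
    ImpactorRun,
    StageTable,
    ValidationError,
    cumulative_activity_distribution,
    fraction_below,
    gsd_from_quantiles,
    hatch_choate_range,
    quantile_diameter,
    sample_impactor_run,
    size_metrics,
)


def lognormal_cdf(d, median, gsd):
    return norm.cdf(np.log(np.asarray(d) / median) / np.log(gsd))


class TestCumulativeDistribution:
    def test_matches_closed_form_lognormal_cdf(self, nl11_run, dense_table):
        """Stage activities integrated from a log-normal reproduce its CDF
        at every boundary to floating-point accuracy."""
        d, f = cumulative_activity_distribution(nl11_run, dense_table)
        np.testing.assert_allclose(f, lognormal_cdf(d, 2.8, 3.2), atol=1e-12)

    def test_all_activity_in_lowest_bin(self, default_table):
        act = np.zeros(12)
        act[0] = 5.0
        _, f = cumulative_activity_distribution(ImpactorRun(act), default_table)
        assert f[0] == 0.0
        np.testing.assert_array_equal(f[1:], 1.0)

    def test_uniform_bins_give_linear_cumulative(self, default_table):
        _, f = cumulative_activity_distribution(
            ImpactorRun(np.ones(12)), default_table)
        np.testing.assert_allclose(f, np.arange(13) / 12)

    def test_zero_total_raises_empty_run(self, default_table):
        with pytest.raises(EmptyRunError):
            cumulative_activity_distribution(
                ImpactorRun(np.zeros(12)), default_table)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValidationError):
            ImpactorRun(np.array([1.0, -0.5, 2.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=12, max_size=12)
           .filter(lambda v: sum(v) > 0))
    def test_monotone_and_ends_at_one(self, activities):
        """Cumulative curve is non-decreasing and ends at exactly 1 for
        any non-negative stage vector."""
        _, f = cumulative_activity_distribution(
            ImpactorRun(np.array(activities)), StageTable.default())
        assert np.all(np.diff(f) >= 0)
        assert f[-1] == 1.0


class TestQuantiles:
    def test_median_recovers_generating_amad(self, nl11_run, dense_table):
        cdf = cumulative_activity_distribution(nl11_run, dense_table)
        assert quantile_diameter(cdf, 0.5) == pytest.approx(2.8, rel=0.01)

    def test_d16_of_narrow_submicron_aerosol(self, dense_table):
        run = sample_impactor_run(AerosolSpec(0.23, 1.6), dense_table,
                                  noiseless=True)
        cdf = cumulative_activity_distribution(run, dense_table)
        # Hatch–Choate closed form median/GSD (the 16 % point of the
        # log-normal sits at z = -0.9945, within 1 % of median/GSD)
        assert quantile_diameter(cdf, 0.16) == pytest.approx(0.23 / 1.6,
                                                             rel=0.01)

    def test_median_of_log_symmetric_distribution(self, dense_table):
        """q = 0.5 returns the log-symmetry center."""
        run = sample_impactor_run(AerosolSpec(0.55, 2.1), dense_table,
                                  noiseless=True)
        cdf = cumulative_activity_distribution(run, dense_table)
        assert quantile_diameter(cdf, 0.5) == pytest.approx(0.55, rel=1e-6)

    def test_monotone_in_q(self, nl11_run, dense_table):
        # the GSD-3.2 aerosol holds ~1.7 % above 10 μm, so stay below the
        # attained cumulative range
        cdf = cumulative_activity_distribution(nl11_run, dense_table)
        qs = np.linspace(0.05, 0.85, 17)
        ds = [quantile_diameter(cdf, q) for q in qs]
        assert np.all(np.diff(ds) > 0)

    def test_extrapolation_error_names_nearest_quantile(self, dense_table):
        run = sample_impactor_run(AerosolSpec(2.8, 3.2), dense_table,
                                  noiseless=True)
        cdf = cumulative_activity_distribution(run, dense_table)
        # ~1.7 % of a GSD-3.2 aerosol lies above the 10 μm boundary
        with pytest.raises(ExtrapolationError) as err:
            quantile_diameter(cdf, 0.999)
        assert err.value.nearest == pytest.approx(float(cdf[1][-1]))

    @pytest.mark.parametrize("q", [0.1, 0.16, 0.5, 0.84, 0.86])
    def test_mutual_inverse_with_fraction_below(self, nl11_run, dense_table, q):
        """quantile_diameter and fraction_below invert each other on the
        interpolated curve."""
        cdf = cumulative_activity_distribution(nl11_run, dense_table)
        assert fraction_below(cdf, quantile_diameter(cdf, q)) == \
            pytest.approx(q, abs=1e-9)


class TestGsdFromQuantiles:
    def test_monodisperse_limit(self):
        assert gsd_from_quantiles(0.5, 0.5) == 1.0

    def test_square_root_of_ratio(self):
        assert gsd_from_quantiles(1.0, 9.0) == 3.0

    def test_rejects_inverted_quantiles(self):
        with pytest.raises(ValidationError):
            gsd_from_quantiles(9.0, 1.0)

    def test_recovers_generating_gsd(self, dense_table):
        run = sample_impactor_run(AerosolSpec(0.55, 2.1), dense_table,
                                  noiseless=True)
        m = size_metrics(run, dense_table)
        assert m.gsd == pytest.approx(2.1, rel=0.01)


class TestFractionBelow:
    def test_below_grid_is_zero_and_above_is_one(self, nl11_run, dense_table):
        run = ImpactorRun(nl11_run.stage_activities)  # no catch bins
        cdf = cumulative_activity_distribution(run, dense_table)
        assert fraction_below(cdf, 0.001) == 0.0
        assert fraction_below(cdf, 50.0) == 1.0

    def test_lognormal_closed_form(self, dense_table):
        """Sub-micron fraction of the 0.55 μm / GSD 2.1 aerosol equals the
        log-normal CDF at 1 μm, ~0.790."""
        run = sample_impactor_run(AerosolSpec(0.55, 2.1), dense_table,
                                  noiseless=True)
        cdf = cumulative_activity_distribution(run, dense_table)
        expected = float(lognormal_cdf(1.0, 0.55, 2.1))
        assert expected == pytest.approx(0.790, abs=0.001)
        assert fraction_below(cdf, 1.0) == pytest.approx(expected, rel=0.01)

    def test_non_decreasing_in_diameter(self, nl11_run, dense_table):
        cdf = cumulative_activity_distribution(nl11_run, dense_table)
        ds = np.geomspace(0.02, 20, 40)
        fs = [fraction_below(cdf, d) for d in ds]
        assert np.all(np.diff(fs) >= 0)


class TestSizeMetrics:
    def test_noiseless_recovery_of_micron_aerosol(self, nl11_run, dense_table):
        m = size_metrics(nl11_run, dense_table)
        assert m.amad == pytest.approx(2.8, rel=0.01)
        assert m.gsd == pytest.approx(3.2, rel=0.02)

    @pytest.mark.parametrize("amad,gsd", [(2.8, 3.2), (0.55, 2.1), (0.23, 1.6)])
    def test_closed_form_recovery_on_dense_grid(self, dense_table, amad, gsd):
        """(amad, gsd, d16, d84) match the log-normal closed forms within
        2 % for every study aerosol."""
        run = sample_impactor_run(AerosolSpec(amad, gsd), dense_table,
                                  noiseless=True)
        m = size_metrics(run, dense_table)
        assert m.amad == pytest.approx(amad, rel=0.02)
        assert m.gsd == pytest.approx(gsd, rel=0.02)
        assert m.d16 == pytest.approx(amad / gsd, rel=0.02)
        assert m.d84 == pytest.approx(amad * gsd, rel=0.02)

    def test_emitted_fraction_from_loaded_and_residual(self, dense_table):
        run = sample_impactor_run(AerosolSpec(2.8, 3.2), dense_table,
                                  noiseless=True)
        run.loaded_activity, run.residual_activity = 740.0, 410.7
        m = size_metrics(run, dense_table)
        assert m.emitted_fraction == pytest.approx(44.5, abs=1e-9)

    def test_single_stage_run_is_monodisperse(self, default_table):
        act = np.zeros(12)
        act[5] = 3.0
        m = size_metrics(ImpactorRun(act), default_table)
        mid = float(np.sqrt(default_table.cut_diameters[5]
                            * default_table.cut_diameters[6]))
        assert m.gsd == 1.0
        assert m.amad == pytest.approx(mid)
        assert m.d16 == m.d84 == m.amad

    def test_fraction_monotonicity_invariant(self, nl11_run, dense_table):
        m = size_metrics(nl11_run, dense_table)
        assert m.ufp_fraction <= m.sub05_fraction <= m.sub1_fraction \
            <= m.fp_fraction

    def test_poisson_noise_median_recovery(self, dense_table, rng):
        """Median absolute AMAD error over 50 Poisson replicates at 1e5
        counts stays below 5 %."""
        errors = []
        for _ in range(50):
            run = sample_impactor_run(AerosolSpec(2.8, 3.2), dense_table,
                                      count_scale=1e5, seed=rng)
            errors.append(abs(size_metrics(run, dense_table).amad / 2.8 - 1))
        assert np.median(errors) < 0.05

    def test_default_grid_coarsening_regression(self, default_table):
        """AMAD on the default 12-stage table: log-probit interpolation is
        exact at the median of a log-normal, so coarsening the grid leaves
        the AMAD unchanged (frozen regression value)."""
        run = sample_impactor_run(AerosolSpec(2.8, 3.2), default_table,
                                  noiseless=True)
        m = size_metrics(run, default_table)
        assert m.amad == pytest.approx(2.8, rel=1e-9)


class TestHatchChoate:
    def test_micron_aerosol_upper_bound_rounds_to_9(self):
        lo, hi = hatch_choate_range(2.80, 3.2)
        assert (lo, hi) == (pytest.approx(0.875), pytest.approx(8.96))
        assert round(hi) == 9

    def test_monodisperse_collapses(self):
        assert hatch_choate_range(1.7, 1.0) == (1.7, 1.7)

    def test_narrow_submicron_arithmetic(self):
        lo, hi = hatch_choate_range(0.23, 1.6)
        assert lo == pytest.approx(0.14375)
        assert hi == pytest.approx(0.368)


class TestStageTable:
    def test_default_spans_instrument_range(self, default_table):
        assert default_table.n_stages == 12
        assert default_table.cut_diameters[0] == pytest.approx(0.030)
        assert default_table.cut_diameters[-1] == pytest.approx(10.0)

    @pytest.mark.parametrize("edges", [[1.0], [1.0, 1.0, 2.0], [0.0, 1.0],
                                       [2.0, 1.0]])
    def test_rejects_invalid_edges(self, edges):
        with pytest.raises(ValidationError):
            StageTable(np.array(edges))
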