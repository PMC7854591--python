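import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import beadct as bc
from beadct.stats import quantile


def brute_force_outliers(values):
    """Reference outlier filter straight from the fence definition."""
    q1 = quantile(values, 0.25)
    q3 = quantile(values, 0.75)
    iqr = q3 - q1
    return sorted(v for v in values if v > q3 + 1.5 * iqr or v < q1 - 1.5 * iqr)


class TestQuantile:
    def test_midpoint_convention_small_sample(self):
        # (k - 0.5)/n positions: for n=4 and p=0.25 the value interpolates
        # halfway between the first two order statistics
        assert quantile([1, 2, 3, 4], 0.25) == pytest.approx(1.5)
        assert quantile([1, 2, 3, 4], 0.5) == pytest.approx(2.5)

    def test_edges_clamp_to_extremes(self):
        assert quantile([3, 1, 2], 0.0) == 1
        assert quantile([3, 1, 2], 1.0) == 3


class TestBoxplotSummary:
    def test_hundred_is_outlier_of_one_to_ten(self):
        s = bc.boxplot_summary(list(range(1, 11)) + [100])
        assert list(s.outliers) == [100]
        assert s.whisker_high == 10
        assert s.whisker_low == 1

    def test_constant_data_no_outliers(self):
        s = bc.boxplot_summary([5.0] * 9)
        assert s.q1 == s.median == s.q3 == 5.0
        assert len(s.outliers) == 0

    def test_single_value(self):
        s = bc.boxplot_summary([7.0])
        assert s.q1 == s.median == s.q3 == s.whisker_low == s.whisker_high == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bc.boxplot_summary([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1, max_size=60,
        )
    )
    def test_outlier_rule_matches_brute_force(self, values):
        s = bc.boxplot_summary(values)
        assert list(s.outliers) == brute_force_outliers(values)


class TestSwelling:
    def test_contract_arithmetic(self):
        dry = bc.boxplot_summary([100.0] * 5)
        wet = bc.boxplot_summary([151.64] * 5)
        assert bc.swelling_change(dry, wet) == pytest.approx(51.64)

    def test_no_change_is_zero(self):
        s = bc.boxplot_summary([3.0, 4.0, 5.0])
        assert bc.swelling_change(s, s) == 0.0

    def test_isotropically_scaled_phantom_pair(self):
        # "wet" beads are the dry ones dilated isotropically by 1.2x; the
        # equivalent-diameter median must move by +20% despite digitization
        from conftest import digitized_sphere

        radii = [10.0, 11.5, 13.0, 14.5, 16.0]
        diam = []
        for scale in (1.0, 1.2):
            eq = [
                bc.basic_morphometrics(digitized_sphere(r * scale), 1.0)[0]
                for r in radii
            ]
            diam.append(bc.boxplot_summary(eq))
        change = bc.swelling_change(diam[0], diam[1])
        assert change == pytest.approx(20.0, abs=2.0)

    def test_zero_dry_median_rejected(self):
        z = bc.boxplot_summary([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            bc.swelling_change(z, z)


class TestSurfacePerDryWeight:
    def test_monodisperse_spheres_closed_form(self):
        R, d = 84.25, 1.026
        fits = [bc.SphereFit(center_um=(0, 0, 0), radius_um=R, score=1.0)] * 7
        got = bc.surface_per_dry_weight(fits, bc.DryWeightSpec("nonswelling", density=d))
        # 3/(R d) with R in cm
        assert got == pytest.approx(3.0 / (R * 1e-4 * d), rel=1e-9)

    def test_swelling_count_per_gram_arithmetic(self):
        rec = bc.SphereFit(center_um=(0, 0, 0), radius_um=np.sqrt(1e5 / (4 * np.pi)), score=1.0)
        spec = bc.DryWeightSpec("swelling_countpergram", count_per_gram=8e5)
        # median surface 1e5 um2 = 1e-3 cm2, x 8e5 per gram -> 800 cm2/g
        assert bc.surface_per_dry_weight([rec] * 3, spec) == pytest.approx(800.0)

    def test_imaged_count_zero_rejected(self):
        rec = bc.SphereFit(center_um=(0, 0, 0), radius_um=50.0, score=1.0)
        spec = bc.DryWeightSpec("swelling_imagedcount", imaged_count=0, sample_weight=0.008)
        with pytest.raises(ValueError):
            bc.surface_per_dry_weight([rec], spec)


class TestTTest:
    def test_identical_samples_p_one(self):
        t, p, sig = bc.compare_groups_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and not sig

    def test_five_sd_separation_significant(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, 300)
        b = rng.normal(5, 1, 250)
        _, p, sig = bc.compare_groups_ttest(a, b)
        assert p < 1e-3 and sig

    def test_antisymmetric_in_group_order(self):
        a = [1.0, 2.0, 4.0]
        b = [2.0, 3.0, 5.0]
        t_ab, *_ = bc.compare_groups_ttest(a, b)
        t_ba, *_ = bc.compare_groups_ttest(b, a)
        assert t_ab == pytest.approx(-t_ba)

    def test_zero_variance_unequal_means(self):
        _, p, _ = bc.compare_groups_ttest([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0


class TestKsNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(3).normal(10, 2, 10000)
        d, p, reject = bc.ks_normality(x)
        assert 0 <= d <= 1
        assert p > 0.05 and not reject

    def test_lognormal_sample_flagged(self):
        x = np.random.default_rng(3).lognormal(0, 1.0, 10000)
        _, p, reject = bc.ks_normality(x)
        assert p < 0.05 and reject

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bc.ks_normality([2.0] * 10)
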