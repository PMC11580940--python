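"""Standardization of published parental-age regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import germclock as gc
from germclock.standardize import NegativeRateWarning, StudySpecError


def human_spec(**over):
    base = dict(
        species="human",
        units="per_genome",
        maternal_slope=0.37,
        paternal_slope=1.51,
        maternal_intercept=3.61,
        paternal_intercept=6.05,
        accessible_haploid_size=2722501677,
        puberty_age=13.0,
        generation_time=30.0,
    )
    base.update(over)
    return gc.SexSpecificRegressionSpec(**base)


class TestSexSpecific:
    def test_human_worked_example(self):
        from conftest import assert_matches_printed

        dec = gc.standardize_sex_specific(human_spec())
        assert_matches_printed(dec.mu_E, 6.26e-9, sig=3)
        assert_matches_printed(dec.mu_gam, 3.5e-10, sig=2)

    def test_dog_per_site(self):
        spec = gc.SexSpecificRegressionSpec(
            species="dog", units="per_site",
            maternal_slope=1e-10, paternal_slope=3.5e-10,
            maternal_intercept=8e-10, paternal_intercept=2.5e-9,
            puberty_age=1.0, generation_time=4.0,
        )
        dec = gc.standardize_sex_specific(spec)
        assert dec.mu_E == pytest.approx(3.75e-9, rel=1e-12)
        assert dec.mu_gam == pytest.approx(4.5e-10, rel=1e-12)

    def test_chimpanzee_negative_paternal_intercept(self):
        spec = gc.SexSpecificRegressionSpec(
            species="chimp", units="per_genome",
            maternal_slope=0.0, paternal_slope=2.95,
            maternal_intercept=6.65, paternal_intercept=-23.8,
            accessible_haploid_size=2.36e9,
            puberty_age=14.0, generation_time=25.0,
        )
        dec = gc.standardize_sex_specific(spec)
        assert dec.mu_E == pytest.approx(5.11e-9, rel=1e-2)
        assert dec.mu_gam == pytest.approx(6.25e-10, rel=1e-3)

    def test_all_zero_gives_zero(self):
        dec = gc.standardize_sex_specific(
            human_spec(maternal_slope=0, paternal_slope=0,
                       maternal_intercept=0, paternal_intercept=0)
        )
        assert dec.mu_E == 0.0
        assert dec.mu_gam == 0.0

    def test_reference_ages_advance_intercepts(self):
        # intercepts at the puberty age itself need no slope correction
        dec_at_p = gc.standardize_sex_specific(
            human_spec(maternal_ref_age=13.0, paternal_ref_age=13.0)
        )
        expected = (3.61 + 6.05) / (2 * 2722501677)
        assert dec_at_p.mu_E == pytest.approx(expected, rel=1e-12)

    def test_missing_genome_size_is_config_error(self):
        with pytest.raises(StudySpecError, match="accessible_haploid_size"):
            human_spec(accessible_haploid_size=None)

    def test_negative_mu_E_warns_not_clamps(self):
        spec = human_spec(maternal_intercept=-100.0, paternal_intercept=-100.0)
        with pytest.warns(NegativeRateWarning):
            dec = gc.standardize_sex_specific(spec)
        assert dec.mu_E < 0  # reported as-is

    def test_bound_propagation_brackets_point(self):
        spec = human_spec(
            lower=dict(maternal_slope=0.30, paternal_slope=1.40,
                       maternal_intercept=3.0, paternal_intercept=5.0),
            upper=dict(maternal_slope=0.45, paternal_slope=1.60,
                       maternal_intercept=4.0, paternal_intercept=7.0),
        )
        dec = gc.standardize_sex_specific(spec)
        lo, hi = dec.mu_E_bounds
        assert lo <= dec.mu_E <= hi
        lo, hi = dec.mu_gam_bounds
        assert lo <= dec.mu_gam <= hi

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_unit_invariance(self, c):
        """Scaling per-genome counts and the genome size by c is a no-op."""
        base = gc.standardize_sex_specific(human_spec())
        scaled = gc.standardize_sex_specific(
            human_spec(
                maternal_slope=0.37 * c, paternal_slope=1.51 * c,
                maternal_intercept=3.61 * c, paternal_intercept=6.05 * c,
                accessible_haploid_size=2722501677 * c,
            )
        )
        assert scaled.mu_E == pytest.approx(base.mu_E, rel=1e-9)
        assert scaled.mu_gam == pytest.approx(base.mu_gam, rel=1e-9)


class TestSlopeIntercept:
    def test_owl_monkey(self):
        spec = gc.SlopeInterceptPerSiteSpec(
            species="owl_monkey", slope=6.62e-10, intercept=3.74e-9,
            intercept_offset_years=1.0, puberty_age=1.0, generation_time=6.6,
        )
        dec = gc.standardize_slope_intercept(spec)
        assert dec.mu_E == pytest.approx(4.40e-9, rel=1e-2)
        assert dec.mu_gam == pytest.approx(6.62e-10, rel=1e-12)

    def test_macaque_pass_through(self):
        spec = gc.SlopeInterceptPerSiteSpec(
            species="macaque", slope=4.3e-10, intercept=3.9e-9,
            intercept_offset_years=0.0, puberty_age=3.5, generation_time=8.0,
        )
        dec = gc.standardize_slope_intercept(spec)
        assert dec.mu_E == pytest.approx(3.9e-9, rel=1e-12)

    def test_zero_slope_identity(self):
        spec = gc.SlopeInterceptPerSiteSpec(
            species="x", slope=0.0, intercept=2.2e-9,
            intercept_offset_years=5.0, puberty_age=5.0, generation_time=9.0,
        )
        assert gc.standardize_slope_intercept(spec).mu_E == pytest.approx(2.2e-9)


class TestMeanRate:
    def test_cat(self):
        spec = gc.MeanRateSpanSpec(
            species="cat", rate_at_puberty=5.9e-9, mean_rate=8.6e-9,
            puberty_age=0.5, mean_reproductive_age=3.8,
        )
        dec = gc.standardize_mean_rate(spec)
        assert dec.mu_gam == pytest.approx(8.2e-10, rel=1e-2)
        assert dec.mu_E == pytest.approx(5.9e-9, rel=1e-12)

    def test_degenerate_equal_rates(self):
        spec = gc.MeanRateSpanSpec(
            species="x", rate_at_puberty=2e-9, mean_rate=2e-9,
            puberty_age=1.0, mean_reproductive_age=3.0,
        )
        assert gc.standardize_mean_rate(spec).mu_gam == 0.0

    def test_direct_arithmetic(self):
        spec = gc.MeanRateSpanSpec(
            species="x", rate_at_puberty=1e-9, mean_rate=2e-9,
            puberty_age=1.0, mean_reproductive_age=3.0,
        )
        assert gc.standardize_mean_rate(spec).mu_gam == pytest.approx(5e-10)

    def test_zero_span_is_error(self):
        with pytest.raises(StudySpecError):
            gc.MeanRateSpanSpec(
                species="x", rate_at_puberty=1e-9, mean_rate=2e-9,
                puberty_age=3.0, mean_reproductive_age=3.0,
            )


class TestTrioRegression:
    @staticmethod
    def exact_trios(mu_E, mu_gam, P, ages, sites=1e12):
        trios = []
        for a in ages:
            count = sites * (mu_E + (a - P) * mu_gam)
            assert abs(count - round(count)) < 1e-6
            trios.append(
                gc.TrioRecord(paternal_age=a, maternal_age=a,
                              dnm_count=int(round(count)),
                              callable_diploid_sites=sites)
            )
        return trios

    def test_noiseless_exact_recovery(self):
        # counts exactly on the line mu_E=3.75e-9, slope=1.64e-9 from puberty 0.15
        ages = [0.15 + d for d in (0.5, 1.0, 1.5, 2.0)]
        trios = self.exact_trios(3.75e-9, 1.64e-9, 0.15, ages)
        dec = gc.fit_trio_regression(trios, puberty_age=0.15)
        assert dec.mu_gam == pytest.approx(1.64e-9, rel=1e-9)
        assert dec.mu_E == pytest.approx(3.75e-9, rel=1e-9)

    def test_two_point_line_plus_midpoint(self):
        ages = [1.15, 2.15, 3.15]
        trios = self.exact_trios(2e-9, 1e-9, 0.15, ages)
        dec = gc.fit_trio_regression(trios, puberty_age=0.15)
        assert dec.mu_E == pytest.approx(2e-9, rel=1e-9)
        assert dec.mu_gam == pytest.approx(1e-9, rel=1e-9)

    def test_identical_ages_singular(self):
        trios = [
            gc.TrioRecord(paternal_age=20, maternal_age=20, dnm_count=50,
                          callable_diploid_sites=1e9)
            for _ in range(5)
        ]
        with pytest.raises(StudySpecError, match="singular"):
            gc.TrioRegressionModel(trios, 13.0)

    def test_poisson_roundtrip_within_bounds(self):
        truth = gc.RateDecomposition("t", 5e-9, 5e-10, 13.0, 30.0)
        cfg = gc.TrioSimConfig(truth=truth, n_trios=400, age_low=15, age_high=45,
                               callable_diploid_sites=5.4e9, seed=7)
        res = gc.TrioRegressionModel(gc.generate_trios(cfg), 13.0).fit()
        ci = res.conf_int()
        assert ci["mu_E"][0] <= truth.mu_E <= ci["mu_E"][1]
        assert ci["mu_gam"][0] <= truth.mu_gam <= ci["mu_gam"][1]


class TestStudyIO:
    def test_builtin_studies_load(self, builtin_table):
        assert len(builtin_table) == 8
        assert set(builtin_table["species"]) == {
            "human", "chimpanzee", "olive_baboon", "rhesus_macaque",
            "owl_monkey", "domestic_cat", "domestic_dog", "mouse",
        }

    def test_unknown_kind_rejected(self):
        with pytest.raises(StudySpecError, match="kind"):
            gc.load_study_spec({"kind": "nope", "species": "x"})

    def test_mouse_carries_published_bounds(self, builtin_decs):
        mouse = next(d for d in builtin_decs if d.species == "mouse")
        assert mouse.mu_E_bounds == (2.89e-9, 4.6e-9)
        assert mouse.mu_gam_bounds[0] == pytest.approx(4.10e-10)
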