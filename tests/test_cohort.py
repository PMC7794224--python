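import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pvscreen import (analytic_auc, default_spec, fit_lognormal_from_quantiles,
                      generate_cohort, generate_who_stratum, who_positive)
from pvscreen.cohort import (COHORT_COLUMNS, MARKERS, CohortSpec,
                             DegenerateSpecError, MarkerDistribution,
                             _draw_group)


class TestLognormalFit:
    @pytest.mark.parametrize("median,q25,q75,loc,scale", [
        # analytic inversion of the lognormal quantile function
        (324.0, 272.5, 489.0, 5.780744, 0.433456),
        (217.0, 183.0, 253.0, 5.379897, 0.240110),
        (1.0, np.exp(-0.6744897501960817), np.exp(0.6744897501960817), 0.0, 1.0),
    ])
    def test_known_fits(self, median, q25, q75, loc, scale):
        d = fit_lognormal_from_quantiles(median, q25, q75)
        assert d.family == "lognormal"
        assert d.location == pytest.approx(loc, abs=1e-5)
        assert d.scale == pytest.approx(scale, abs=1e-5)

    @pytest.mark.parametrize("median,q25,q75", [
        (1.0, 2.0, 3.0), (2.0, 1.0, 1.5), (0.0, -1.0, 1.0), (5.0, 5.0, 6.0),
    ])
    def test_unordered_quantiles_rejected(self, median, q25, q75):
        with pytest.raises(ValueError):
            fit_lognormal_from_quantiles(median, q25, q75)

    @given(st.floats(0.1, 1e4), st.floats(0.05, 0.95), st.floats(1.05, 20.0))
    @settings(max_examples=200, derandomize=True)
    def test_quantile_round_trip(self, median, lo_frac, hi_ratio):
        """The fitted distribution's analytic median and quartile ratio
        reproduce the inputs (median exactly, IQR in symmetrised log form)."""
        q25, q75 = median * lo_frac, median * hi_ratio
        d = fit_lognormal_from_quantiles(median, q25, q75)
        assert d.median == pytest.approx(median, rel=1e-12)
        frozen = sps.lognorm(s=d.scale, scale=np.exp(d.location))
        fitted_ratio = frozen.ppf(0.75) / frozen.ppf(0.25)
        assert np.log(fitted_ratio) == pytest.approx(np.log(q75 / q25), rel=1e-9)


class TestMarkerDistribution:
    def test_truncation_respected(self):
        d = MarkerDistribution("normal", 0.0, 10.0, truncation=(-1.0, 1.0))
        x = d.ppf(np.linspace(0.001, 0.999, 100))
        assert (x >= -1.0).all() and (x <= 1.0).all()

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            MarkerDistribution("normal", 0.0, 0.0)

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            MarkerDistribution("gamma", 1.0, 1.0)


class TestDefaultSpec:
    def test_positive_platelets_match_published_quartiles(self, spec):
        d = spec.markers[("positive", "male")]["platelets"]
        ref = fit_lognormal_from_quantiles(324, 272.5, 489)
        assert d.location == pytest.approx(ref.location)
        assert d.scale == pytest.approx(ref.scale)

    def test_positive_mcv(self, spec):
        d = spec.markers[("positive", "male")]["mcv"]
        assert (d.family, d.location, d.scale) == ("normal", 89.1, 4.7)

    def test_missingness_rates(self, spec):
        assert spec.dna_failure_rate == pytest.approx(270 / 1271)
        assert spec.known_mpn_fraction == pytest.approx(5 / 13)

    def test_invalid_correlation_rejected(self, spec):
        bad = spec.correlation.copy()
        bad.iloc[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError):
            spec.replace(correlation=bad)
        # an inconsistent 3-cycle (a~b, b~c strongly positive, a~c strongly
        # negative) makes the matrix indefinite
        bad2 = spec.correlation.copy()
        bad2.iloc[0, 1] = bad2.iloc[1, 0] = 0.9
        bad2.iloc[1, 2] = bad2.iloc[2, 1] = 0.9
        bad2.iloc[0, 2] = bad2.iloc[2, 0] = -0.9
        with pytest.raises(ValueError):
            spec.replace(correlation=bad2)


class TestGenerateCohort:
    def test_empty_cohort(self, spec):
        c = generate_cohort(spec.replace(n=0))
        assert len(c) == 0 and list(c.columns) == list(COHORT_COLUMNS)

    def test_zero_prevalence(self, spec):
        c = generate_cohort(spec.replace(n=500, jak2_prevalence=0.0), seed=1)
        assert not c["jak2_positive"].any()
        assert not c["known_mpn"].any()

    def test_determinism(self, spec):
        a = generate_cohort(spec.replace(n=800), seed=7)
        b = generate_cohort(spec.replace(n=800), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_record_invariants(self, small_cohort):
        c = small_cohort
        for m in MARKERS[1:]:  # all markers but age strictly positive
            assert (c[m] > 0).all()
        assert (c["age"] >= 0).all()
        assert (c["neutrophils"] <= c["wbc"]).all()
        assert c["htc"].between(0, 100, inclusive="neither").all()
        # a known MPN is by construction a carrier
        assert not (c["known_mpn"] & ~c["jak2_positive"]).any()

    def test_positives_conditioned_on_who(self, spec):
        c = generate_cohort(spec.replace(n=4000, jak2_prevalence=0.05), seed=5)
        pos = c[c["jak2_positive"]]
        assert len(pos) > 0
        assert who_positive(pos).all()

    def test_calibration_targets(self, spec):
        """~8-10% of the population meets the WHO criterion and ~0.8% of that
        stratum carries the mutation (Monte-Carlo check at n=1e5)."""
        c = generate_cohort(spec.replace(n=100_000), seed=11)
        who = who_positive(c)
        assert 0.068 <= who.mean() <= 0.119
        frac_pos = c.loc[who, "jak2_positive"].mean()
        assert abs(frac_pos - 0.008) <= 0.004

    def test_degenerate_spec_signalled(self, spec):
        # positive component far below the WHO thresholds can never pass step 1
        markers = {k: dict(v) for k, v in spec.markers.items()}
        for sex in ("male", "female"):
            markers[("positive", sex)] = dict(
                markers[("positive", sex)],
                hb=MarkerDistribution("normal", 8.0, 0.01, (4.1, 21.0)),
                htc=MarkerDistribution("normal", 25.0, 0.01, (12.3, 65.0)),
            )
        bad = spec.replace(markers=markers, jak2_prevalence=0.05, n=200)
        with pytest.raises(DegenerateSpecError):
            generate_cohort(bad, seed=3)


class TestCopula:
    def test_marginals_preserved_under_correlation(self, spec):
        """The Gaussian copula must not distort any marker's marginal (KS on
        1e5 draws below the alpha=0.01 critical value)."""
        rng = np.random.default_rng(123)
        dists = spec.markers[("negative", "male")]
        R = np.asarray(spec.correlation, dtype=float)
        df = _draw_group(dists, R, 100_000, rng)
        crit = 1.6276 / np.sqrt(len(df))  # alpha=0.01 asymptotic KS critical value
        for m in MARKERS:
            stat = sps.kstest(df[m], dists[m].cdf).statistic
            assert stat < crit, f"{m}: KS={stat:.4f} >= {crit:.4f}"

    def test_correlated_pairs_are_correlated(self, small_cohort):
        neg = small_cohort[~small_cohort["jak2_positive"]]
        assert neg["hb"].corr(neg["htc"]) > 0.85
        assert neg["wbc"].corr(neg["neutrophils"]) > 0.7
        assert neg["mcv"].corr(neg["mch"]) > 0.7

    def test_group_location_recovered(self, spec):
        """Empirical medians of a large cohort match the spec parameters."""
        rng = np.random.default_rng(99)
        for group, sex in [("positive", "male"), ("negative", "female")]:
            dists = spec.markers[(group, sex)]
            df = _draw_group(dists, np.asarray(spec.correlation, float),
                             200_000, rng)
            for m in ("platelets", "mcv", "rdw"):
                expect = dists[m].median
                se = df[m].std() / np.sqrt(len(df))
                assert abs(df[m].median() - expect) < max(4 * se, 0.02 * expect)


class TestAnalyticAUC:
    def test_equal_distributions(self, spec):
        markers = {k: dict(v) for k, v in spec.markers.items()}
        markers[("positive", "male")]["mcv"] = markers[("negative", "male")]["mcv"]
        s = spec.replace(markers=markers)
        assert analytic_auc(s, "mcv") == pytest.approx(0.5)

    def test_infinite_separation_limit(self, spec):
        markers = {k: dict(v) for k, v in spec.markers.items()}
        markers[("positive", "male")] = dict(
            markers[("positive", "male")],
            mcv=MarkerDistribution("normal", 1e6, 1.0))
        assert analytic_auc(spec.replace(markers=markers), "mcv") == pytest.approx(1.0)

    def test_mcv_closed_form(self, spec):
        # Phi(-3.5 / sqrt(4.7^2 + 4.6^2)) for the published MCV summaries
        expect = sps.norm.cdf(-3.5 / np.hypot(4.7, 4.6))
        assert analytic_auc(spec, "mcv") == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.297, abs=0.003)

    def test_mixed_families_rejected(self, spec):
        markers = {k: dict(v) for k, v in spec.markers.items()}
        markers[("positive", "male")] = dict(
            markers[("positive", "male")],
            platelets=MarkerDistribution("normal", 324.0, 100.0))
        with pytest.raises(ValueError):
            analytic_auc(spec.replace(markers=markers), "platelets")


class TestWhoStratum:
    def test_stratum_is_all_who_positive(self, spec):
        s = generate_who_stratum(spec, 2000, 0.1, seed=4)
        assert len(s) == 2000
        assert who_positive(s).all()
        assert 100 <= s["jak2_positive"].sum() <= 320
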