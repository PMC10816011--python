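"""Plating efficiency, surviving fractions, SHMT fitting, RBE and OER."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from radbiokit import (
    SHMTModel,
    SHMTResults,
    dose_at_survival,
    oer,
    plating_efficiency,
    rbe,
    shmt_survival,
    surviving_fractions,
)


def colony_df(rows):
    cols = ["oxygen", "quality", "plating", "dose_Gy", "seeded", "colonies", "replicate"]
    return pd.DataFrame(rows, columns=cols)


class TestShmtSurvival:
    def test_survival_at_zero_is_one(self):
        for d0, n in [(0.5, 0.3), (2.98, 1.07), (10, 5)]:
            assert shmt_survival(0.0, d0, n) == 1.0

    def test_single_target_closed_form(self):
        assert shmt_survival(2.98, 2.98, 1.0) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_published_parameter_evaluation(self):
        # X-ray/normoxia curve evaluated at its own D0
        assert shmt_survival(2.98, 2.98, 1.07) == pytest.approx(0.3878, abs=1e-4)

    @given(
        d0=st.floats(0.1, 10), n=st.floats(0.1, 10),
        d1=st.floats(0.0, 20), d2=st.floats(0.001, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing(self, d0, n, d1, d2):
        # strictness can saturate in float64 when S rounds to exactly 1
        s_hi, s_lo = shmt_survival(d1, d0, n), shmt_survival(d1 + d2, d0, n)
        assert s_lo <= s_hi
        if s_hi < 1.0 - 1e-9 and s_lo > 1e-12:
            assert s_lo < s_hi

    def test_final_slope_matches_d0_definition(self):
        """At high dose, log10 S falls with slope −1/(D0 ln10) and intercept log10 n."""
        d0, n = 2.0, 3.0
        d = np.array([30.0, 40.0])
        logs = np.log10(shmt_survival(d, d0, n))
        slope = (logs[1] - logs[0]) / (d[1] - d[0])
        intercept = logs[0] - slope * d[0]
        assert slope == pytest.approx(-1 / (d0 * np.log(10)), rel=1e-6)
        assert intercept == pytest.approx(np.log10(n), abs=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            shmt_survival(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            shmt_survival(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            shmt_survival(-1.0, 1.0, 1.0)


class TestDoseAtSurvival:
    def test_single_target_e_fold(self):
        assert dose_at_survival(2.5, 1.0, np.exp(-1)) == pytest.approx(2.5, rel=1e-12)

    def test_forward_consistency(self):
        d = dose_at_survival(2.0, 1.5, 0.1)
        assert d == pytest.approx(5.38149, abs=1e-4)  # recomputed closed form
        assert shmt_survival(d, 2.0, 1.5) == pytest.approx(0.1, abs=1e-9)

    def test_limit_target_to_one(self):
        assert dose_at_survival(2.0, 1.5, 1 - 1e-12) < 1e-3

    def test_domain(self):
        for t in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                dose_at_survival(2.0, 1.5, t)


class TestPlatingEfficiency:
    def test_constant_replicates(self):
        df = colony_df(
            [["normoxia", "xray", "immediate", 0.0, 100, 35, f"r{i}"] for i in range(3)]
        )
        pe = plating_efficiency(df)
        row = pe.loc[("normoxia", "xray", "immediate")]
        assert row.pe == pytest.approx(0.35)
        assert row.se_pe == 0.0

    def test_varying_replicates(self):
        df = colony_df(
            [["normoxia", "xray", "immediate", 0.0, 100, c, f"r{i}"]
             for i, c in enumerate([32, 35, 38])]
        )
        row = plating_efficiency(df).iloc[0]
        assert row.pe == pytest.approx(0.35)
        assert row.se_pe == pytest.approx(0.017, abs=5e-4)

    def test_single_replicate_has_no_se(self):
        df = colony_df([["hypoxia", "xray", "immediate", 0.0, 100, 25, "r1"]])
        row = plating_efficiency(df).iloc[0]
        assert row.pe == pytest.approx(0.25)
        assert np.isnan(row.se_pe)

    def test_all_zero_colonies_is_error(self):
        df = colony_df(
            [["normoxia", "xray", "immediate", 0.0, 100, 0, f"r{i}"] for i in range(3)]
        )
        with pytest.raises(ValueError, match="zero colonies"):
            plating_efficiency(df)

    def test_no_unirradiated_records_is_error(self):
        df = colony_df([["normoxia", "xray", "immediate", 2.0, 100, 10, "r1"]])
        with pytest.raises(ValueError, match="0 Gy"):
            plating_efficiency(df)


class TestSurvivingFractions:
    def base_df(self):
        return colony_df(
            [["normoxia", "xray", "immediate", 0.0, 100, 35, "r1"],
             ["normoxia", "xray", "immediate", 2.0, 100, 7, "r1"],
             ["normoxia", "xray", "immediate", 4.0, 100, 0, "r1"]]
        )

    def test_normalisation_by_pe(self):
        df = self.base_df()
        sf = surviving_fractions(df, plating_efficiency(df))
        two = sf[sf.dose_Gy == 2.0].iloc[0]
        assert two.sf == pytest.approx(0.2)

    def test_zero_colony_dish_excluded_and_flagged(self):
        df = self.base_df()
        sf = surviving_fractions(df, plating_efficiency(df))
        assert 4.0 not in sf.dose_Gy.values or sf[sf.dose_Gy == 4.0].empty
        # flagged dishes counted where the dose still has surviving replicates
        df2 = pd.concat(
            [df, colony_df([["normoxia", "xray", "immediate", 4.0, 100, 3, "r2"]])],
            ignore_index=True,
        )
        sf2 = surviving_fractions(df2, plating_efficiency(df2))
        four = sf2[sf2.dose_Gy == 4.0].iloc[0]
        assert four.n_zero_excluded == 1
        assert four.n_replicates == 1

    def test_missing_pe_condition_is_error(self):
        df = self.base_df()
        pe = plating_efficiency(df)
        other = colony_df([["hypoxia", "xray", "immediate", 2.0, 100, 5, "r1"]])
        with pytest.raises(ValueError, match="hypoxia"):
            surviving_fractions(other, pe)


class TestShmtFit:
    @pytest.mark.parametrize("d0, n", [(2.0, 1.5), (1.0, 1.0), (2.98, 1.07), (1.11, 0.64)])
    def test_noise_free_recovery(self, d0, n):
        """Fit on model-generated data returns the generating parameters."""
        doses = np.array([0.5, 1, 2, 4, 8])
        res = SHMTModel(doses, shmt_survival(doses, d0, n)).fit()
        assert res.d0_Gy == pytest.approx(d0, rel=1e-6)
        assert res.n_extrapolation == pytest.approx(n, rel=1e-6)

    def test_pure_exponential_special_case(self):
        doses = np.array([1.0, 2.0, 3.0, 5.0])
        res = SHMTModel(doses, np.exp(-doses / 1.0)).fit()
        assert res.n_extrapolation == pytest.approx(1.0, rel=1e-6)
        assert res.d0_Gy == pytest.approx(1.0, rel=1e-6)

    def test_zero_dose_points_are_dropped(self):
        doses = np.array([0.0, 0.5, 1, 2, 4])
        sf = shmt_survival(doses, 2.0, 1.5)
        model = SHMTModel(doses, sf)
        assert 0.0 not in model.dose

    def test_too_few_doses_is_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            SHMTModel([1.0, 2.0], [0.5, 0.2])

    def test_nonpositive_sf_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            SHMTModel([1.0, 2.0, 4.0], [0.5, 0.0, 0.1])

    def test_weighted_fit_and_summary(self):
        doses = np.array([0.5, 1, 2, 4])
        sf = shmt_survival(doses, 2.98, 1.07)
        res = SHMTModel(doses, sf, se_sf=0.05 * sf, label="normoxia/xray").fit()
        assert res.d0_Gy == pytest.approx(2.98, rel=1e-5)
        text = res.summary()
        assert "D0" in text and "normoxia/xray" in text

    def test_predict_and_inverse(self):
        doses = np.array([0.5, 1, 2, 4, 8])
        res = SHMTModel(doses, shmt_survival(doses, 2.0, 1.5)).fit()
        d10 = res.dose_at_survival(0.1)
        assert res.predict(d10) == pytest.approx(0.1, abs=1e-8)


class TestRatios:
    def fit(self, d0, se=np.nan, label=""):
        return SHMTResults.from_parameters(d0, se_d0=se, label=label)

    @pytest.mark.parametrize(
        "d0_x, d0_c, expected",
        [(2.98, 1.11, 2.68), (2.29, 0.90, 2.54)],
    )
    def test_rbe_published_pairs(self, d0_x, d0_c, expected):
        """Ratios of the published immediate/late-plating D0 pairs."""
        m = rbe(self.fit(d0_x), self.fit(d0_c))
        assert round(m.value, 2) == expected

    @pytest.mark.parametrize(
        "d0_h, d0_n, expected",
        [(1.68, 2.98, 0.564), (2.50, 2.29, 1.092)],
    )
    def test_oer_published_pairs(self, d0_h, d0_n, expected):
        m = oer(self.fit(d0_h), self.fit(d0_n))
        assert m.value == pytest.approx(expected, abs=5e-4)

    def test_self_ratio_is_one(self):
        a = self.fit(2.0, se=0.1)
        assert rbe(a, a).value == 1.0
        assert oer(a, a).value == 1.0

    def test_oer_reciprocity(self):
        a, b = self.fit(1.7), self.fit(2.9)
        assert oer(a, b).value * oer(b, a).value == pytest.approx(1.0, rel=1e-12)

    def test_delta_method_se(self):
        m = rbe(self.fit(2.98, se=0.20), self.fit(1.11, se=0.07))
        expected = (2.98 / 1.11) * np.sqrt((0.20 / 2.98) ** 2 + (0.07 / 1.11) ** 2)
        assert m.se == pytest.approx(expected, rel=1e-12)


def test_parameter_recovery_with_binomial_noise(rng):
    """Median recovered D0 within 5% over repeated noisy datasets."""
    d0_true, n_true, pe = 2.98, 1.07, 0.35
    doses = np.array([0.5, 1.0, 2.0, 4.0])
    est = []
    for _ in range(120):
        sf_mean = []
        for d in doses:
            p = pe * shmt_survival(d, d0_true, n_true)
            colonies = rng.binomial(200, p, size=3)
            sf_mean.append(np.mean(colonies / 200) / pe)
        sf_mean = np.array(sf_mean)
        if np.any(sf_mean <= 0):
            continue
        est.append(SHMTModel(doses, sf_mean).fit().d0_Gy)
    assert abs(np.median(est) - d0_true) / d0_true < 0.05
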