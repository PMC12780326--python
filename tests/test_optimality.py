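"""Tetens VPD, the Medlyn inversion/prediction pair, and exponent selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from wheatflux.core import GasExchangeRecord
from wheatflux.optimality import (
    MedlynOptimality,
    UndefinedOptimumError,
    air_vpd,
    estimate_g1,
    fit_optimality,
    predict_gs,
    saturation_vapour_pressure,
    wue_summary,
)


class TestVpd:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 0.61078), (27.0, 3.565), (37.0, 6.275)],
    )
    def test_tetens_saturation_pressure(self, t, expected):
        assert saturation_vapour_pressure(t) == pytest.approx(expected, abs=5e-4)

    def test_saturated_air_has_zero_deficit(self):
        assert air_vpd(27.0, 100.0) == pytest.approx(0.0)

    def test_reproduces_both_canopy_regimes_to_2dp(self):
        assert round(air_vpd(27.0, 60.0), 2) == 1.43
        assert round(air_vpd(37.0, 50.0), 2) == 3.14

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            saturation_vapour_pressure(80.0)
        with pytest.raises(ValueError):
            air_vpd(27.0, 105.0)


class TestG1Inversion:
    def test_symmetric_ratio_at_unit_vpd(self):
        for k in (0.2, 0.5, 0.8):
            assert estimate_g1(225.0, 450.0, 1.0, k) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "k, expected", [(0.5, 2.790), (0.8, 3.106)]
    )
    def test_hand_evaluated_values(self, k, expected):
        assert estimate_g1(0.7 * 450, 450.0, 1.43, k) == pytest.approx(
            expected, abs=1e-3
        )

    def test_closure_raises_undefined_optimum(self):
        with pytest.raises(UndefinedOptimumError):
            estimate_g1(460.0, 450.0, 1.43, 0.5)

    def test_exponent_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            estimate_g1(300.0, 450.0, 1.43, k=1.5)

    @given(
        r=st.floats(0.05, 0.95),
        d=st.floats(0.2, 5.0),
        k=st.floats(0.1, 1.0),
    )
    def test_strictly_increasing_in_ci_ca_and_d(self, r, d, k):
        ca = 450.0
        g = estimate_g1(r * ca, ca, d, k)
        assert estimate_g1(min(r * 1.01, 0.96) * ca, ca, d, k) > g
        assert estimate_g1(r * ca, ca, d * 1.01, k) > g


class TestPrediction:
    def test_zero_slope_gives_diffusive_floor(self):
        assert predict_gs(20.0, 450.0, 1.43, g1=0.0) == pytest.approx(
            1.6 * 20 / 450
        )

    def test_identity_with_estimated_g1(self):
        g1 = estimate_g1(315.0, 450.0, 1.43, 0.5)
        gs = predict_gs(20.0, 450.0, 1.43, g1, 0.5)
        assert gs == pytest.approx(1.6 * 20.0 / (450.0 - 315.0), abs=1e-12)
        assert gs == pytest.approx(0.2370, abs=5e-5)

    def test_vpd_doubling_scales_slope_term_by_inverse_sqrt(self):
        a, ca, g1, k = 20.0, 450.0, 3.0, 0.5
        excess = lambda d: predict_gs(a, ca, d, g1, k) * ca / (1.6 * a) - 1.0
        assert excess(2.86) / excess(1.43) == pytest.approx(1 / math.sqrt(2))

    @given(
        r=st.floats(0.05, 0.95),
        d=st.floats(0.2, 5.0),
        k=st.floats(0.1, 1.0),
        a=st.floats(1.0, 40.0),
        ca=st.floats(200.0, 1200.0),
    )
    def test_round_trip_identity(self, r, d, k, a, ca):
        """predict_gs(estimate_g1(...)) == 1.6*A/(Ca-Ci) exactly."""
        ci = r * ca
        gs = predict_gs(a, ca, d, estimate_g1(ci, ca, d, k), k)
        assert gs == pytest.approx(1.6 * a / (ca - ci), rel=1e-12)


def _eqn1_frame(n, k, g1, rng=None, noise=0.0, ci_noise=0.0):
    rng = rng or np.random.default_rng(42)
    d = rng.uniform(0.8, 3.5, n)
    ca = np.full(n, 450.0)
    r = g1 / (g1 + d**k)
    ci = r * ca * (1 + ci_noise * rng.standard_normal(n))
    a = rng.uniform(10.0, 25.0, n)
    gsw = predict_gs(a, ca, d, g1, k) * (1 + noise * rng.standard_normal(n))
    return pd.DataFrame({"A": a, "gsw": gsw, "Ca": ca, "Ci": ci, "D": d})


class TestFitOptimality:
    def test_noise_free_recovery_is_exact(self):
        df = _eqn1_frame(24, k=0.8, g1=3.0)
        est = MedlynOptimality().fit(df)
        assert est.k_ == 0.8
        assert est.g1_ == pytest.approx(3.0, abs=1e-9)
        assert est.r2_ == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_ten_percent(self):
        df = _eqn1_frame(40, k=0.8, g1=3.0, noise=0.05)
        fits, best_k = fit_optimality(df)
        assert abs(fits[best_k].g1 / 3.0 - 1.0) < 0.10

    def test_bias_shrinks_with_sample_size(self):
        # Ci measurement noise perturbs the per-observation g1 values; the
        # aggregated estimate tightens as n grows
        errs = []
        for n in (10, 40, 160):
            rng = np.random.default_rng(7)
            df = _eqn1_frame(n, k=0.5, g1=2.5, rng=rng, noise=0.05,
                             ci_noise=0.05)
            est = MedlynOptimality(k=0.5).fit(df)
            errs.append(abs(est.g1_ - 2.5))
        assert errs[-1] < errs[0]

    def test_too_few_records_rejected(self):
        df = _eqn1_frame(2, k=0.5, g1=3.0)
        with pytest.raises(ValueError, match="at least 4"):
            MedlynOptimality().fit(df)

    def test_records_failing_preconditions_are_excluded_with_warning(self):
        df = _eqn1_frame(10, k=0.5, g1=3.0)
        df.loc[3, "Ci"] = df.loc[3, "Ca"] + 10  # closure row
        with pytest.warns(UserWarning, match="excluded"):
            est = MedlynOptimality().fit(df)
        assert est.excluded_ == [3]
        assert est.n_ == 9

    def test_sklearn_params_round_trip_and_clone(self):
        est = MedlynOptimality(k=0.5, g1_method="mean")
        assert clone(est).get_params()["g1_method"] == "mean"
        est.set_params(g1_method="regression")
        df = _eqn1_frame(20, k=0.5, g1=3.0)
        est.fit(df)
        assert est.g1_ == pytest.approx(3.0, abs=1e-9)
        assert np.allclose(est.predict(df), df["gsw"])


class TestWueSummary:
    def test_arithmetic(self):
        rec = GasExchangeRecord(
            plant_id="p", surface="combined", gsw=0.4, E=5.0,
            A=20.0, Ca=450.0, Ci=315.0,
        )
        s = wue_summary(rec)
        assert s.iwue == pytest.approx(50.0)
        assert s.instantaneous_wue == pytest.approx(4.0)
        assert s.ci_ca == pytest.approx(0.7)
        assert not s.undefined

    def test_zero_assimilation_gives_zero_indices(self):
        rec = GasExchangeRecord(
            plant_id="p", surface="combined", gsw=0.4, E=5.0, A=0.0
        )
        s = wue_summary(rec)
        assert s.iwue == 0.0 and s.instantaneous_wue == 0.0

    def test_zero_denominator_flags_not_raises(self):
        rec = GasExchangeRecord(
            plant_id="p", surface="combined", gsw=0.0, E=0.0, A=5.0
        )
        s = wue_summary(rec)
        assert s.undefined and s.iwue is None
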