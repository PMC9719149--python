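"""Two-compartment dilution model: fixed arithmetic and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abratio.mixing import (
    DetectionMode,
    MixingParams,
    RoundingMode,
    detected_cns_fraction,
    predict_plasma_decrease,
    sensitivity_grid,
    worked_example,
)

DEFAULTS = dict(f_cns=0.30, f_ntx=0.30, r_csf=0.50)

fractions = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestDetectedCnsFraction:
    def test_agnostic_mode_returns_cns_fraction(self):
        p = MixingParams(**DEFAULTS, detection_mode="nterm_agnostic")
        assert detected_cns_fraction(p) == 0.30

    def test_asp1_two_decimal_rounding_gives_38_percent(self):
        p = MixingParams(**DEFAULTS, detection_mode="asp1_specific", rounding_mode="two_decimal")
        assert detected_cns_fraction(p) == 0.38

    def test_asp1_exact_is_030_over_079(self):
        p = MixingParams(**DEFAULTS, detection_mode="asp1_specific")
        assert detected_cns_fraction(p) == pytest.approx(0.30 / 0.79, abs=1e-12)

    def test_no_truncated_peripheral_species_is_a_noop(self):
        p = MixingParams(f_cns=0.30, f_ntx=0.0, detection_mode="asp1_specific")
        assert detected_cns_fraction(p) == 0.30

    @given(f_cns=fractions, f_ntx=fractions)
    @settings(derandomize=True, max_examples=200)
    def test_asp1_enrichment_never_below_agnostic(self, f_cns, f_ntx):
        agn = detected_cns_fraction(MixingParams(f_cns=f_cns, f_ntx=f_ntx))
        asp = detected_cns_fraction(
            MixingParams(f_cns=f_cns, f_ntx=f_ntx, detection_mode="asp1_specific")
        )
        assert asp >= agn - 1e-15
        assert asp <= 1.0 + 1e-15
        if f_ntx == 0 or f_cns in (0.0, 1.0):
            assert asp == pytest.approx(agn, abs=1e-15)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            MixingParams(f_cns=1.2)
        with pytest.raises(ValueError):
            MixingParams(f_ntx=-0.1)


class TestPredictPlasmaDecrease:
    def test_agnostic_prediction_is_15_percent(self):
        pred = predict_plasma_decrease(MixingParams(**DEFAULTS))
        assert pred.predicted_decrease_pct == pytest.approx(15.0)

    def test_asp1_two_decimal_prediction_is_19_percent(self):
        pred = predict_plasma_decrease(
            MixingParams(**DEFAULTS, detection_mode="asp1_specific", rounding_mode="two_decimal")
        )
        assert pred.predicted_decrease_pct == pytest.approx(19.0)

    def test_asp1_exact_prediction(self):
        pred = predict_plasma_decrease(MixingParams(**DEFAULTS, detection_mode="asp1_specific"))
        assert pred.predicted_decrease_pct == pytest.approx(100 * 0.30 / 0.79 * 0.5, abs=1e-9)
        assert round(pred.predicted_decrease_pct, 2) == 18.99

    def test_pure_cns_plasma_mirrors_csf(self):
        for f_ntx in (0.0, 0.3, 0.9):
            pred = predict_plasma_decrease(
                MixingParams(f_cns=1.0, f_ntx=f_ntx, r_csf=0.5, detection_mode="asp1_specific")
            )
            assert pred.predicted_decrease_pct == pytest.approx(50.0)

    @given(f_cns=fractions, f_ntx=fractions, r_csf=fractions)
    @settings(derandomize=True, max_examples=200)
    def test_bounded_by_csf_contrast(self, f_cns, f_ntx, r_csf):
        for mode in DetectionMode:
            pred = predict_plasma_decrease(
                MixingParams(f_cns=f_cns, f_ntx=f_ntx, r_csf=r_csf, detection_mode=mode)
            )
            assert -1e-9 <= pred.predicted_decrease_pct <= 100 * r_csf + 1e-9

    @given(
        f=st.tuples(fractions, fractions).map(sorted),
        f_ntx=fractions,
        r_csf=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_cns_fraction(self, f, f_ntx, r_csf):
        lo, hi = f
        p_lo = predict_plasma_decrease(
            MixingParams(f_cns=lo, f_ntx=f_ntx, r_csf=r_csf, detection_mode="asp1_specific")
        )
        p_hi = predict_plasma_decrease(
            MixingParams(f_cns=hi, f_ntx=f_ntx, r_csf=r_csf, detection_mode="asp1_specific")
        )
        assert p_hi.predicted_decrease_pct >= p_lo.predicted_decrease_pct - 1e-9


class TestWorkedExample:
    def test_100ng_mass_budget(self):
        ex = worked_example(100.0, MixingParams(**DEFAULTS, rounding_mode="two_decimal"))
        assert ex.peripheral_ng == pytest.approx(70.0)
        assert ex.nonasp1_ng == pytest.approx(21.0)
        assert ex.detected_ng == pytest.approx(79.0)
        assert ex.cns_ng == pytest.approx(30.0)
        assert ex.detected_cns_pct == pytest.approx(38.0)
        assert ex.predicted_decrease_pct == pytest.approx(19.0)

    def test_exact_mode_percentages(self):
        ex = worked_example(100.0, MixingParams(**DEFAULTS))
        assert ex.detected_cns_pct == pytest.approx(100 * 30 / 79, abs=1e-9)
        assert round(ex.detected_cns_pct, 2) == 37.97

    def test_nothing_excluded_when_all_peripheral_is_asp1(self):
        ex = worked_example(100.0, MixingParams(f_cns=0.30, f_ntx=0.0))
        assert ex.detected_ng == 100.0
        assert ex.nonasp1_ng == 0.0

    def test_mass_scale_invariance(self):
        p = MixingParams(**DEFAULTS)
        small, big = worked_example(100.0, p), worked_example(200.0, p)
        for field in ("total_ng", "cns_ng", "peripheral_ng", "nonasp1_ng", "detected_ng"):
            assert getattr(big, field) == pytest.approx(2 * getattr(small, field))
        assert big.detected_cns_pct == pytest.approx(small.detected_cns_pct)
        assert big.predicted_decrease_pct == pytest.approx(small.predicted_decrease_pct)

    @given(
        total=st.floats(min_value=1e-3, max_value=1e6),
        f_cns=fractions,
        f_ntx=fractions,
    )
    @settings(derandomize=True, max_examples=200)
    def test_mass_conservation(self, total, f_cns, f_ntx):
        ex = worked_example(total, MixingParams(f_cns=f_cns, f_ntx=f_ntx))
        assert ex.cns_ng + ex.peripheral_ng == pytest.approx(ex.total_ng)
        assert ex.detected_ng == pytest.approx(ex.total_ng - ex.nonasp1_ng)
        assert ex.nonasp1_ng == pytest.approx(f_ntx * ex.peripheral_ng)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            worked_example(0.0, MixingParams())


class TestSensitivityGrid:
    def test_single_point_matches_direct_prediction(self):
        grid = sensitivity_grid([0.30], [0.30], [0.50], detection_modes=["asp1_specific"])
        assert len(grid) == 1
        direct = predict_plasma_decrease(MixingParams(**DEFAULTS, detection_mode="asp1_specific"))
        assert grid["predicted_decrease_pct"].iloc[0] == pytest.approx(
            direct.predicted_decrease_pct
        )

    def test_prediction_nondecreasing_in_f_ntx(self):
        grid = sensitivity_grid([0.30], [0.0, 0.15, 0.30], [0.50], detection_modes=["asp1_specific"])
        decreases = grid.sort_values("f_ntx")["predicted_decrease_pct"].to_numpy()
        assert (decreases[1:] >= decreases[:-1]).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_grid([], [0.3], [0.5])
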