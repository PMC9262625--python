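"""Forward-model checks: propagation vs independent oracles, analytic limits,
monotonicity, and input validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpmgdisp.exchange import (
    CpmgSchedule,
    ExchangeParams,
    FieldContext,
    InvalidInputError,
    bm_r2eff,
    carver_richards_r2eff,
    dispersion_curve,
    rex_fast_limit,
)

from oracles import stepwise_bm_r2eff


def params_with(k_ex, p_B, dw_ppm, r20=15.0):
    return ExchangeParams(
        k_ex=k_ex, p_B=p_B, dw_ppm=dw_ppm,
        r20_by_field={"11.7T": r20, "18.8T": r20},
    )


class TestAgainstStepwiseOracle:
    """Production propagation vs brute-force echo-by-echo scipy.expm loop."""

    def test_regression_fixture(self, field_800, schedule):
        # value frozen from the step-wise matrix-exponential oracle
        p = ExchangeParams(k_ex=1640.0, p_B=0.042, dw_ppm=1.0,
                           r20_by_field={"18.8T": 15.0})
        assert bm_r2eff(p, field_800, schedule, 200.0) == pytest.approx(
            31.487488495669478, abs=1e-8
        )

    @pytest.mark.parametrize("k_ex,p_B,dw", [
        (200.0, 0.15, 2.0), (500.0, 0.01, 0.3), (1640.0, 0.042, 1.0),
        (4000.0, 0.05, 1.0), (800.0, 0.3, 0.5),
    ])
    def test_matches_oracle_across_regimes(self, k_ex, p_B, dw, fields, schedule):
        p = params_with(k_ex, p_B, dw)
        for f in fields.values():
            for nu in (100.0, 650.0, 3000.0, 6000.0):
                expected = stepwise_bm_r2eff(
                    k_ex, p_B, dw, 15.0, f.larmor_13c_mhz, schedule.t_relax, nu
                )
                assert bm_r2eff(p, f, schedule, nu) == pytest.approx(expected, abs=1e-8)


class TestClosedFormEquivalence:
    def test_oracle_grid(self, fields, schedule):
        """Exact closed form vs numerical propagation over the full regime grid."""
        nus = [200.0, 300.0, 500.0, 800.0, 1200.0, 1800.0, 2500.0, 3000.0]
        worst = 0.0
        for k_ex in (200.0, 500.0, 1600.0, 4000.0):
            for p_B in (0.01, 0.05, 0.15):
                for dw in (0.3, 1.0, 2.0):
                    p = params_with(k_ex, p_B, dw)
                    for f in fields.values():
                        for nu in nus:
                            diff = abs(
                                bm_r2eff(p, f, schedule, nu)
                                - carver_richards_r2eff(p, f, schedule, nu)
                            )
                            worst = max(worst, diff)
        assert worst < 0.1

    def test_cr72_close_in_fast_exchange(self, field_500, schedule):
        """The classic CR72 approximation holds when k_ex >> delta-omega."""
        p = params_with(8000.0, 0.03, 0.3)
        for nu in (100.0, 500.0, 2000.0):
            exact = carver_richards_r2eff(p, field_500, schedule, nu)
            approx = carver_richards_r2eff(p, field_500, schedule, nu, approx=True)
            assert approx == pytest.approx(exact, abs=0.05)


class TestAnalyticLimits:
    @pytest.mark.parametrize("p", [
        params_with(1000.0, 0.1, 0.0),   # no shift difference
        params_with(1000.0, 0.0, 1.0),   # no excited state
    ])
    def test_flat_when_exchange_invisible(self, p, fields, schedule):
        for f in fields.values():
            curve = dispersion_curve(p, f, schedule)
            assert np.allclose(curve, 15.0, atol=1e-12)
            assert carver_richards_r2eff(p, f, schedule, 200.0) == 15.0

    def test_fast_exchange_limit(self, field_500):
        """R2,eff(nu->0) - R2,0 approaches p_A p_B dw^2 / k_ex for fast exchange."""
        # long relaxation block reaches lower nu while keeping >= 2 pulses
        sched = CpmgSchedule(t_relax=0.08, nu_cpmg=(25.0,))
        for k_ex, dw in ((4000.0, 0.3), (8000.0, 0.3), (10000.0, 0.6)):
            p = params_with(k_ex, 0.05, dw)
            assert k_ex / field_500.dw_rad_s(dw) > 10
            rex_num = bm_r2eff(p, field_500, sched, 25.0) - 15.0
            rex_lim = rex_fast_limit(p, field_500)
            assert rex_num == pytest.approx(rex_lim, rel=0.05)

    def test_rex_fast_limit_arithmetic(self, field_800):
        # hand-computed: (1-0.042)*0.042*(2*pi*201.2)^2/1640
        p = params_with(1640.0, 0.042, 1.0)
        assert rex_fast_limit(p, field_800) == pytest.approx(39.209, abs=0.01)
        assert rex_fast_limit(params_with(1640.0, 0.0, 1.0), field_800) == 0.0

    def test_rex_limit_quadruples_with_doubled_field(self):
        p = params_with(1640.0, 0.042, 1.0)
        f1 = FieldContext("a", 9.4, 100.0)
        f2 = FieldContext("b", 18.8, 200.0)
        assert rex_fast_limit(p, f2) == pytest.approx(4 * rex_fast_limit(p, f1))


class TestDispersionCurve:
    def test_monotone_non_increasing(self, cluster1_params, fields, schedule):
        for f in fields.values():
            curve = dispersion_curve(cluster1_params, f, schedule)
            assert np.all(np.diff(curve) <= 1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ratio=st.floats(1.0, 20.0),
        p_B=st.floats(0.001, 0.45),
        dw=st.floats(0.05, 4.0),
    )
    def test_monotonicity_property(self, ratio, p_B, dw):
        """Non-increasing in nu whenever k_ex >= delta-omega (rad/s).

        In slower exchange with large shift differences the dispersion
        profile genuinely oscillates (coherence effects of the echo train),
        so the property is scoped to the intermediate-to-fast regime.
        """
        f = FieldContext("18.8T", 18.8, 201.2)
        sched = CpmgSchedule(0.02, (100, 200, 400, 800, 1600, 3200, 6000))
        k_ex = min(ratio * f.dw_rad_s(dw), 5.0e5)
        p = ExchangeParams(k_ex=k_ex, p_B=p_B, dw_ppm=dw,
                           r20_by_field={"18.8T": 10.0})
        curve = dispersion_curve(p, f, sched)
        assert np.all(np.diff(curve) <= 1e-6)

    def test_rex_larger_at_higher_field(self, cluster1_params, fields, schedule):
        """Delta-omega in rad/s grows with B0, so dispersion amplitude does too."""
        amp = {}
        for lbl, f in fields.items():
            curve = dispersion_curve(cluster1_params, f, schedule)
            amp[lbl] = curve[0] - curve[-1]
        assert amp["18.8T"] > amp["11.7T"] > 0

    def test_flat_above_3000_for_cluster1_rate(self, cluster1_params, field_800, schedule):
        """For k_ex ~ 1640 s^-1 the curve is flat between 3000 and 6000 s^-1."""
        r3000 = bm_r2eff(cluster1_params, field_800, schedule, 3000.0)
        r6000 = bm_r2eff(cluster1_params, field_800, schedule, 6000.0)
        assert r3000 - r6000 < 0.5  # s^-1; residual dispersion is negligible


class TestValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            ExchangeParams(k_ex=-1.0, p_B=0.1, dw_ppm=1.0)
        with pytest.raises(InvalidInputError):
            ExchangeParams(k_ex=100.0, p_B=0.6, dw_ppm=1.0)
        with pytest.raises(InvalidInputError):
            ExchangeParams(k_ex=100.0, p_B=0.1, dw_ppm=-0.5)

    def test_bad_schedule_rejected(self):
        with pytest.raises(InvalidInputError):
            CpmgSchedule(t_relax=-0.02, nu_cpmg=(100.0,))
        with pytest.raises(InvalidInputError):
            CpmgSchedule(t_relax=0.02, nu_cpmg=(0.0,))
        with pytest.raises(InvalidInputError):
            # nu implies fewer than 2 refocusing pulses
            CpmgSchedule(t_relax=0.02, nu_cpmg=(10.0,))

    def test_non_positive_nu_rejected(self, cluster1_params, field_800, schedule):
        with pytest.raises(InvalidInputError):
            bm_r2eff(cluster1_params, field_800, schedule, -5.0)

    def test_missing_field_r20_rejected(self, schedule):
        p = ExchangeParams(k_ex=100.0, p_B=0.1, dw_ppm=1.0, r20_by_field={"x": 10.0})
        f = FieldContext("18.8T", 18.8, 201.2)
        with pytest.raises(InvalidInputError):
            bm_r2eff(p, f, schedule, 200.0)
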