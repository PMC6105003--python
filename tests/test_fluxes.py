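"""Unit and property tests for the pure calcium flux terms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amyca import fluxes
from amyca.params import CoreParams

CORE = CoreParams()

conc = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)
level = st.floats(min_value=0.0, max_value=1.3, allow_nan=False)


class TestJIn:
    @pytest.mark.parametrize("p, a, expected", [
        (0.0, 0.0, 0.003),                    # basal leak alone
        (10.0, 0.0, 0.003 + 0.02 * 10.0),     # IP3-linear term
        (0.0, 1.0, 0.003 + 1.0 ** 4),         # amyloid pore term
    ])
    def test_values(self, p, a, expected):
        assert fluxes.j_in(p, a, CORE) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fluxes.j_in(-1.0, 0.0, CORE)
        with pytest.raises(ValueError):
            fluxes.j_in(0.0, -0.1, CORE)

    @given(p=conc, a=level, dp=st.floats(min_value=1e-2, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, p, a, dp):
        assert fluxes.j_in(p + dp, a, CORE) > fluxes.j_in(p, a, CORE)
        assert fluxes.j_in(p, a + dp, CORE) > fluxes.j_in(p, a, CORE)


class TestJPm:
    def test_zero_and_half_max_and_saturation(self):
        assert fluxes.j_pm(0.0, CORE) == 0.0
        assert fluxes.j_pm(CORE.K_pm, CORE) == pytest.approx(CORE.V_pm / 2)
        assert fluxes.j_pm(1e6, CORE) == pytest.approx(CORE.V_pm, rel=1e-6)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            fluxes.j_pm(-0.01, CORE)

    @given(c=conc, dc=st.floats(min_value=0, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_bounded(self, c, dc):
        lo, hi = fluxes.j_pm(c, CORE), fluxes.j_pm(c + dc, CORE)
        assert lo <= hi <= CORE.V_pm


class TestJSerca:
    def test_reversal_point(self):
        # zero exactly where c = K1 * c_e
        assert fluxes.j_serca(0.001, 10.0, CORE) == pytest.approx(0.0, abs=1e-15)

    def test_forward_value(self):
        # independent arithmetic: (0.05 - 1e-4*10)/(0.007 + 0.06*0.05
        #                          + 0.0014*10 + 0.007*0.05*10)
        expected = (0.05 - 1e-4 * 10) / (0.007 + 0.06 * 0.05
                                         + 0.0014 * 10 + 0.007 * 0.05 * 10)
        assert expected == pytest.approx(1.781818, rel=1e-6)
        assert fluxes.j_serca(0.05, 10.0, CORE) == pytest.approx(expected)

    def test_backward_below_reversal(self):
        assert fluxes.j_serca(0.0, 10.0, CORE) < 0.0

    @given(c=conc, ce=st.floats(min_value=0.0, max_value=1000.0))
    @settings(max_examples=100, deadline=None)
    def test_sign_matches_gradient(self, c, ce):
        val = fluxes.j_serca(c, ce, CORE)
        assert np.sign(val) == np.sign(c - CORE.K1 * ce)


class TestRyR:
    def test_rate_limits(self):
        assert fluxes.ryr_rate_k3(0.0, 0.0, CORE) == CORE.k1
        assert fluxes.ryr_rate_k3(1e9, 0.0, CORE) == pytest.approx(
            CORE.k1 + CORE.k2, rel=1e-9)

    def test_half_saturation_with_amyloid(self):
        for a in (0.0, 0.4, 1.0):
            c_half = CORE.k_d + CORE.k_alpha * a
            assert fluxes.ryr_rate_k3(c_half, a, CORE) == pytest.approx(
                CORE.k1 + CORE.k2 / 2)

    def test_flux_values(self):
        assert fluxes.j_ryr(1.0, 1.0, 0.0, CORE) == 0.0
        # frozen from independent arithmetic:
        # k3 = 0.013 + 0.18*0.05^3/(0.13^3 + 0.05^3); flux = k3 * 9.95
        k3 = 0.013 + 0.18 * 0.05 ** 3 / (0.13 ** 3 + 0.05 ** 3)
        assert k3 * 9.95 == pytest.approx(0.2257647, rel=1e-6)
        assert fluxes.j_ryr(0.05, 10.0, 0.0, CORE) == pytest.approx(k3 * 9.95)
        assert fluxes.j_ryr(0.05, 0.0, 0.0, CORE) < 0.0

    @given(c=conc, a=level)
    @settings(max_examples=100, deadline=None)
    def test_rate_within_band(self, c, a):
        k3 = fluxes.ryr_rate_k3(c, a, CORE)
        assert CORE.k1 <= k3 <= CORE.k1 + CORE.k2

    @given(c=st.floats(min_value=0.01, max_value=10.0),
           a=level, da=st.floats(min_value=1e-3, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_amyloid_lowers_rate_at_fixed_c(self, c, a, da):
        assert (fluxes.ryr_rate_k3(c, a + da, CORE)
                < fluxes.ryr_rate_k3(c, a, CORE))


class TestJIpr:
    def test_values(self):
        assert fluxes.j_ipr(0.3, 7.0, 0.0, CORE) == 0.0      # J_er = 0 default
        assert fluxes.j_ipr(0.0, 10.0, 1.0, CORE) == pytest.approx(9.8)
        assert fluxes.j_ipr(2.0, 2.0, 0.5, CORE) == 0.0

    def test_open_probability_validated(self):
        with pytest.raises(ValueError):
            fluxes.j_ipr(0.1, 1.0, 1.5, CORE)
        with pytest.raises(ValueError):
            fluxes.j_ipr(0.1, 1.0, -0.1, CORE)

    def test_explicit_er_leak(self):
        core = CoreParams(J_er=0.2)
        assert fluxes.j_ipr(0.0, 10.0, 0.0, core) == pytest.approx(2.0)


def test_no_amyloid_no_ip3_reductions():
    """With a = p = 0 every amyloid term vanishes: the leak is the basal a1
    and the RyR rate reduces to the unmodified CICR sigmoid."""
    assert fluxes.j_in(0.0, 0.0, CORE) == CORE.a1
    for c in (0.0, 0.05, 0.2, 1.0):
        plain = CORE.k1 + CORE.k2 * c ** 3 / (CORE.k_d ** 3 + c ** 3)
        assert fluxes.ryr_rate_k3(c, 0.0, CORE) == pytest.approx(plain)
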