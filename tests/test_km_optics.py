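"""Two-flux (Kubelka-Munk) forward model, its exact inversion, and the
Beer-Lambert attenuation link."""

import math

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from tissuelight import (
    InvalidMeasurementError,
    InvalidRegimeError,
    KMCoefficients,
    MeasurementSet,
    OpticalProperties,
    SemiInfiniteSampleError,
    assemble_properties,
    beer_lambert_mu_t,
    forward_measurements,
    invert_measurements,
    km_auxiliary,
    km_forward,
    km_invert_SA,
    sa_to_transport,
    transport_to_sa,
)

# frozen high-precision (mpmath, 30 digits) evaluations of the Kottler
# closed forms for the flux coefficients implied by the liver-635 row
LIVER635_S = 5.60584735
LIVER635_A = 2.8258
LIVER635_RD = 0.354063567762044
LIVER635_TD = 0.245521045220358


class TestAuxiliary:
    @pytest.mark.parametrize(
        "rd, td, a, b",
        [
            (0.5, 0.0, 1.25, 0.75),
            (0.2, 0.4, 2.2, math.sqrt(2.2**2 - 1)),
        ],
    )
    def test_direct_arithmetic(self, rd, td, a, b):
        got_a, got_b = km_auxiliary(rd, td)
        assert got_a == pytest.approx(a, rel=1e-12)
        assert got_b == pytest.approx(b, rel=1e-12)

    def test_rd_td_above_one_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            km_auxiliary(0.3, 0.8)  # a = 0.75 < 1

    def test_zero_rd_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            km_auxiliary(0.0, 0.3)


class TestForward:
    def test_zero_thickness_identity(self):
        rd, td = km_forward(KMCoefficients(s=3.0, a_cap=1.0), 0.0)
        assert rd == pytest.approx(0.0, abs=1e-12)
        assert td == pytest.approx(1.0, rel=1e-12)

    def test_pure_scattering_closed_form(self):
        # a_cap = 0: rd = Sd/(1+Sd), td = 1/(1+Sd)
        rd, td = km_forward(KMCoefficients(s=1.0, a_cap=0.0), 1.0)
        assert rd == pytest.approx(0.5, rel=1e-12)
        assert td == pytest.approx(0.5, rel=1e-12)

    def test_liver_values(self):
        rd, td = km_forward(KMCoefficients(s=LIVER635_S, a_cap=LIVER635_A), 0.2)
        assert rd == pytest.approx(LIVER635_RD, rel=1e-9)
        assert td == pytest.approx(LIVER635_TD, rel=1e-9)

    def test_b_limit_continuous(self):
        # tiny absorption must join the analytic pure-scattering limit smoothly
        rd0, td0 = km_forward(KMCoefficients(s=2.0, a_cap=0.0), 0.5)
        rd1, td1 = km_forward(KMCoefficients(s=2.0, a_cap=1e-7), 0.5)
        assert rd1 == pytest.approx(rd0, rel=1e-6)
        assert td1 == pytest.approx(td0, rel=1e-6)

    def test_semi_infinite_limit(self):
        coeff = KMCoefficients(s=5.0, a_cap=2.0)
        rd, td = km_forward(coeff, 50.0)
        assert td == pytest.approx(0.0, abs=1e-12)
        assert rd == pytest.approx(coeff.a - coeff.b, rel=1e-9)


class TestInvert:
    def test_pure_scattering_inverse(self):
        coeff = km_invert_SA(0.5, 0.5, 1.0)
        assert coeff.s == pytest.approx(1.0, rel=1e-9)
        assert coeff.a_cap == pytest.approx(0.0, abs=1e-9)

    def test_liver_inverse(self):
        coeff = km_invert_SA(LIVER635_RD, LIVER635_TD, 0.2)
        assert coeff.s == pytest.approx(LIVER635_S, rel=1e-9)
        assert coeff.a_cap == pytest.approx(LIVER635_A, rel=1e-9)

    def test_semi_infinite_error(self):
        with pytest.raises(SemiInfiniteSampleError):
            km_invert_SA(0.5, 0.0, 1.0)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        s=st.floats(0.5, 50.0),
        a_cap=st.floats(0.0, 60.0),
        d=st.floats(0.05, 0.3),
    )
    def test_round_trip_property(self, s, a_cap, d):
        """Inversion is the exact algebraic inverse of the forward map."""
        rd, td = km_forward(KMCoefficients(s=s, a_cap=a_cap), d)
        assume(td > 1e-250)
        coeff = km_invert_SA(rd, td, d)
        assert coeff.s == pytest.approx(s, rel=1e-9)
        assert coeff.a_cap == pytest.approx(a_cap, rel=1e-9, abs=1e-9)


class TestTransportLink:
    @pytest.mark.parametrize(
        "s, a_cap, mu_a, musp",
        [
            (3.0, 0.0, 0.0, 4.0),
            (1.0, 2.0, 1.0, 5.0 / 3.0),
            (5.6065, 2.8258, 1.4129, (4 * 5.6065 + 1.4129) / 3.0),
        ],
    )
    def test_sa_to_transport(self, s, a_cap, mu_a, musp):
        got_mu_a, got_musp = sa_to_transport(KMCoefficients(s=s, a_cap=a_cap))
        assert got_mu_a == pytest.approx(mu_a, abs=1e-12)
        assert got_musp == pytest.approx(musp, rel=1e-9)

    def test_transport_round_trip(self):
        coeff = transport_to_sa(1.4129, 7.9454298)
        mu_a, musp = sa_to_transport(coeff)
        assert mu_a == pytest.approx(1.4129, rel=1e-12)
        assert musp == pytest.approx(7.9454298, rel=1e-12)

    def test_outside_two_flux_regime(self):
        with pytest.raises(InvalidRegimeError):
            transport_to_sa(10.0, 1.0)  # S would be negative


class TestBeerLambert:
    @pytest.mark.parametrize(
        "tc, d, mu_t",
        [
            (1.0, 0.2, 0.0),
            (math.exp(-1.0), 1.0, 1.0),
            (math.exp(-26.1959 * 0.2), 0.2, 26.1959),
        ],
    )
    def test_values(self, tc, d, mu_t):
        assert beer_lambert_mu_t(tc, d) == pytest.approx(mu_t, rel=1e-9, abs=1e-12)

    def test_nonpositive_tc(self):
        with pytest.raises(InvalidMeasurementError):
            beer_lambert_mu_t(0.0, 0.2)


class TestAssemble:
    @pytest.mark.parametrize(
        "mu_a, musp, mu_t, mu_s, g",
        [
            (1.4129, 7.9456, 26.1959, 24.783, 0.6794),
            (8.5873, 4.7826, 29.9573, 21.370, 0.7762),
        ],
    )
    def test_liver_rows(self, mu_a, musp, mu_t, mu_s, g):
        props = assemble_properties(mu_a, musp, mu_t, 0.2)
        assert props.mu_s == pytest.approx(mu_s, rel=1e-4)
        assert props.g == pytest.approx(g, rel=1e-3)

    def test_infeasible_combination(self):
        with pytest.raises(InvalidRegimeError):
            assemble_properties(2.0, 5.0, 4.0, 0.1)  # mu_s = 2 < mu_s'

    def test_no_scattering(self):
        with pytest.raises(InvalidRegimeError):
            assemble_properties(5.0, 1.0, 4.0, 0.1)


class TestFullChain:
    @pytest.mark.parametrize(
        "mu_a, mu_s, g, d",
        [(1.4129, 24.783, 0.6794, 0.2), (0.5, 10.0, 0.9, 0.1)],
    )
    def test_round_trip(self, mu_a, mu_s, g, d):
        truth = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, thickness=d)
        rec = invert_measurements(forward_measurements(truth))
        assert rec.mu_a == pytest.approx(mu_a, rel=1e-6)
        assert rec.mu_s == pytest.approx(mu_s, rel=1e-6)
        assert rec.g == pytest.approx(g, rel=1e-6)

    def test_invalid_triple_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            MeasurementSet(rd=0.6, td=0.5, tc=0.1, thickness=0.1)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        mu_a=st.floats(0.1, 30.0),
        mu_s=st.floats(5.0, 60.0),
        g=st.floats(0.3, 0.95),
        d=st.floats(0.05, 0.3),
    )
    def test_full_envelope_recovery(self, mu_a, mu_s, g, d):
        """Noiseless inversion is the identity across the tissue envelope."""
        assume(0.75 * mu_s * (1 - g) - 0.25 * mu_a > 0.05)
        truth = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, thickness=d)
        m = forward_measurements(truth)
        assume(m.td > 1e-250 and m.tc > 1e-250)
        rec = invert_measurements(m)
        assert rec.mu_a == pytest.approx(mu_a, rel=1e-6)
        assert rec.mu_s == pytest.approx(mu_s, rel=1e-6)
        assert rec.g == pytest.approx(g, rel=1e-6)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        s=st.floats(0.5, 30.0),
        a_cap=st.floats(0.0, 40.0),
        d1=st.floats(0.02, 0.2),
        d2=st.floats(0.0, 0.2),
    )
    def test_monotonicity_and_energy_bound(self, s, a_cap, d1, d2):
        """rd grows and td shrinks with thickness; rd + td never exceeds 1."""
        rd1, td1 = km_forward(KMCoefficients(s=s, a_cap=a_cap), d1)
        rd2, td2 = km_forward(KMCoefficients(s=s, a_cap=a_cap), d1 + d2)
        assert rd2 >= rd1 - 1e-12
        if d2 > 1e-9 and td1 > 1e-280:
            assert td2 < td1
        assert rd1 + td1 <= 1.0 + 1e-12
        if a_cap > 1e-6:
            assert rd1 + td1 < 1.0
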