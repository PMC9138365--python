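"""Forward relaxation physics: constants, spectral densities, rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinrelax.physics import (
    DiffusionTensor,
    FieldParameters,
    InvalidParameterError,
    NHOrientation,
    ResidueDynamics,
    forward_rates,
    interaction_constants,
    spectral_density,
)

# Frozen from an independent constants script (CODATA mu0/hbar, standard
# gyromagnetic ratios) at 600.13 MHz, r_NH = 1.02 A, CSA = -160 ppm.
ORACLE_D = -72114.269702778
ORACLE_C = 35319.17182452594


class TestInteractionConstants:
    def test_values_match_independent_constants_script(self, field):
        d, c = interaction_constants(field)
        assert d == pytest.approx(ORACLE_D, rel=1e-12)
        assert c == pytest.approx(ORACLE_C, rel=1e-12)

    def test_dipolar_constant_follows_inverse_cube_of_bond_length(self, field):
        d1, _ = interaction_constants(field)
        d2, _ = interaction_constants(FieldParameters(r_nh=2 * field.r_nh))
        assert abs(d2 / d1) == pytest.approx(1 / 8, rel=1e-12)

    def test_zero_csa_gives_zero_csa_constant(self):
        _, c = interaction_constants(FieldParameters(csa=0.0))
        assert c == 0.0

    def test_nitrogen_to_proton_frequency_ratio_equals_gamma_ratio(self, field):
        assert abs(field.omega_n / field.omega_h) == pytest.approx(
            abs(field.gamma_n / field.gamma_h), rel=1e-12
        )

    @pytest.mark.parametrize("kwargs", [dict(r_nh=-1.0), dict(proton_frequency=0.0)])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            FieldParameters(**kwargs)


def _oracle_j_axial(s2, tau_e, tensor, alpha, omega, s2f=1.0):
    """Independent direct summation of the three-exponential form."""
    ca2, sa2 = math.cos(alpha) ** 2, math.sin(alpha) ** 2
    amps = [(1.5 * ca2 - 0.5) ** 2, 3 * sa2 * ca2, 0.75 * sa2**2]
    dpe, dpa = tensor.d_perp, tensor.d_par
    total = 0.0
    for a_k, rate in zip(amps, [6 * dpe, 5 * dpe + dpa, 2 * dpe + 4 * dpa]):
        tk = 1.0 / rate
        total += a_k * s2 * tk / (1 + (omega * tk) ** 2)
        if tau_e > 0:
            tkp = 1.0 / (rate + 1.0 / tau_e)
            total += a_k * (s2f - s2) * tkp / (1 + (omega * tkp) ** 2)
    return 0.4 * total


class TestSpectralDensity:
    def test_rigid_isotropic_j0_is_two_fifths_tau_m(self):
        tensor = DiffusionTensor(tau_m=13.9e-9)
        j0 = spectral_density(ResidueDynamics(1, 1, s2=1.0), tensor, None, 0.0)
        assert j0 == pytest.approx(0.4 * 13.9e-9, rel=1e-14)

    def test_fully_disordered_fast_limit_vanishes(self):
        # S2 = 0 with tau_e -> 0: J is bounded by (2/5) tau_e and vanishes
        tensor = DiffusionTensor(tau_m=10e-9)
        last = np.inf
        for tau_e in (1e-13, 1e-15, 1e-17):
            dyn = ResidueDynamics(1, 2, s2=0.0, tau_e=tau_e)
            j = spectral_density(dyn, tensor, None, 1e9)
            assert 0 <= j <= 0.4 * tau_e * (1 + 1e-9)
            assert j < last
            last = j

    def test_matches_independent_summation_oracle(self, field):
        tensor = DiffusionTensor(
            tau_m=13.9e-9, anisotropy_ratio=1.19, axis_theta=0.0, axis_phi=0.0
        )
        alpha = math.radians(30)
        orient = NHOrientation(1, np.array([math.sin(alpha), 0, math.cos(alpha)]))
        dyn = ResidueDynamics(1, 2, s2=0.85, tau_e=50e-12)
        w = abs(field.omega_n)
        expected = _oracle_j_axial(0.85, 50e-12, tensor, alpha, w)
        assert spectral_density(dyn, tensor, orient, w) == pytest.approx(
            expected, rel=1e-10
        )

    @pytest.mark.parametrize("alpha_deg", [0, 17, 45, 90])
    def test_isotropic_limit_equals_single_lorentzian_for_any_angle(self, alpha_deg):
        tau_m, s2, tau_e = 9e-9, 0.7, 200e-12
        tensor = DiffusionTensor(tau_m=tau_m, anisotropy_ratio=1.0)
        a = math.radians(alpha_deg)
        orient = NHOrientation(1, np.array([math.sin(a), 0.0, math.cos(a)]))
        dyn = ResidueDynamics(1, 2, s2=s2, tau_e=tau_e)
        tau_p = tau_m * tau_e / (tau_m + tau_e)
        for w in (0.0, 1e8, 5e8, 4e9):
            expected = 0.4 * (
                s2 * tau_m / (1 + (w * tau_m) ** 2)
                + (1 - s2) * tau_p / (1 + (w * tau_p) ** 2)
            )
            assert spectral_density(dyn, tensor, orient, w) == pytest.approx(
                expected, rel=1e-12
            )

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(
        tau_m_ns=st.floats(2.0, 25.0),
        ratio=st.floats(0.6, 1.8),
        alpha=st.floats(0.0, math.pi / 2),
    )
    def test_rigid_j_monotonically_non_increasing_in_frequency(
        self, tau_m_ns, ratio, alpha
    ):
        tensor = DiffusionTensor(tau_m=tau_m_ns * 1e-9, anisotropy_ratio=ratio)
        orient = NHOrientation(1, np.array([math.sin(alpha), 0.0, math.cos(alpha)]))
        dyn = ResidueDynamics(1, 1, s2=1.0)
        w = np.linspace(0, 5e9, 50)
        j = spectral_density(dyn, tensor, orient, w)
        assert np.all(np.diff(j) <= 1e-30)

    def test_extended_model_reduces_to_simple_when_s2f_is_one(self):
        tensor = DiffusionTensor(tau_m=12e-9)
        d5 = ResidueDynamics(1, 5, s2=0.6, tau_e=1e-9, s2f=1.0)
        d2 = ResidueDynamics(1, 2, s2=0.6, tau_e=1e-9)
        for w in (0.0, 4e8, 3.8e9):
            assert spectral_density(d5, tensor, None, w) == pytest.approx(
                spectral_density(d2, tensor, None, w), rel=1e-14
            )


def _oracle_rates(jfunc, field, rex=0.0):
    """Independent transcription of the 15N dipolar/CSA rate expressions."""
    d = (
        4e-7
        * math.pi
        * 1.054571817e-34
        * field.gamma_h
        * field.gamma_n
        / (4 * math.pi * (field.r_nh * 1e-10) ** 3)
    )
    c = field.omega_n * field.csa * 1e-6 / math.sqrt(3)
    wh, wn = field.omega_h, abs(field.omega_n)
    r1 = (d**2 / 4) * (
        jfunc(wh - wn) + 3 * jfunc(wn) + 6 * jfunc(wh + wn)
    ) + c**2 * jfunc(wn)
    r2 = (
        (d**2 / 8)
        * (4 * jfunc(0) + jfunc(wh - wn) + 3 * jfunc(wn) + 6 * jfunc(wh) + 6 * jfunc(wh + wn))
        + (c**2 / 6) * (4 * jfunc(0) + 3 * jfunc(wn))
        + rex
    )
    noe = 1 + (field.gamma_h / field.gamma_n) * (d**2 / 4) * (
        6 * jfunc(wh + wn) - jfunc(wh - wn)
    ) / r1
    return r1, r2, noe


class TestForwardRates:
    def test_rates_match_independent_oracle(self, field, apo_tensor, orientation):
        dyn = ResidueDynamics(1, 2, s2=0.78, tau_e=300e-12)
        got = forward_rates(dyn, apo_tensor, orientation, field)
        jf = lambda w: spectral_density(dyn, apo_tensor, orientation, w)
        expected = _oracle_rates(jf, field)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_rex_adds_to_r2_only(self, field, apo_tensor, orientation):
        base = forward_rates(
            ResidueDynamics(1, 3, s2=0.85, rex=0.0), apo_tensor, orientation, field
        )
        with_rex = forward_rates(
            ResidueDynamics(1, 3, s2=0.85, rex=5.0), apo_tensor, orientation, field
        )
        assert with_rex[0] == pytest.approx(base[0], rel=1e-14)
        assert with_rex[1] - base[1] == pytest.approx(5.0, abs=1e-12)
        assert with_rex[2] == pytest.approx(base[2], rel=1e-14)

    def test_consistent_with_published_mean_rates_for_rigid_backbone(
        self, field, apo_tensor
    ):
        """Rigid-limit predictions under the fitted apo tensor land within
        15% of the published mean R1/R2 (0.983 and 16.941 1/s) at a typical
        rigid-backbone order parameter."""
        dyn = ResidueDynamics(1, 1, s2=0.90)
        orient = NHOrientation(1, np.array([0.0, 0.0, 1.0]))
        r1, r2, _ = forward_rates(dyn, apo_tensor, orient, field)
        assert r1 == pytest.approx(0.983, rel=0.15)
        assert r2 == pytest.approx(16.941, rel=0.15)

    def test_r2_over_r1_increases_with_tumbling_time(self, field):
        ratios = []
        for tm in np.linspace(1e-9, 30e-9, 15):
            r1, r2, _ = forward_rates(
                ResidueDynamics(1, 1, s2=1.0), DiffusionTensor(tau_m=tm), None, field
            )
            ratios.append(r2 / r1)
        assert np.all(np.diff(ratios) > 0)

    def test_noe_below_one_and_negative_for_fast_disordered_motion(self, field):
        rigid = forward_rates(
            ResidueDynamics(1, 1, s2=0.9), DiffusionTensor(tau_m=14e-9), None, field
        )
        assert rigid[2] < 1.0
        floppy = forward_rates(
            ResidueDynamics(1, 2, s2=0.05, tau_e=30e-12),
            DiffusionTensor(tau_m=2e-9),
            None,
            field,
        )
        assert floppy[2] < 0.0


class TestDomainTypes:
    def test_model5_requires_s2_below_s2f(self):
        with pytest.raises(InvalidParameterError):
            ResidueDynamics(1, 5, s2=0.9, tau_e=1e-9, s2f=0.8)

    def test_order_parameter_bounds_enforced(self):
        with pytest.raises(InvalidParameterError):
            ResidueDynamics(1, 1, s2=1.2)

    def test_nh_vector_must_be_unit_length(self):
        with pytest.raises(InvalidParameterError):
            NHOrientation(1, np.array([1.0, 1.0, 0.0]))

    def test_tensor_diso_definition(self):
        t = DiffusionTensor(tau_m=10e-9, anisotropy_ratio=1.3)
        assert (t.d_par + 2 * t.d_perp) / 3 == pytest.approx(
            1 / (6 * t.tau_m), rel=1e-12
        )
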