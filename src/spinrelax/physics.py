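"""Forward Lipari-Szabo relaxation physics for backbone amide 15N spins.

Spectral density functions under isotropic and axially symmetric rotational
diffusion, and the standard dipolar/CSA expressions that predict the
longitudinal rate R1, the transverse rate R2 and the steady-state
{1H}-15N heteronuclear NOE from them.

Unit conventions
----------------
All correlation times are seconds and all angular frequencies rad/s
internally.  User-facing constructors accept the field in MHz, the N-H bond
length in Angstrom and the 15N CSA in ppm, which is how these quantities are
quoted in practice.  The 15N gyromagnetic ratio is negative; the sign is kept
and enters the NOE expression through gamma_H/gamma_N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "MU_0",
    "HBAR",
    "GAMMA_H",
    "GAMMA_N",
    "FieldParameters",
    "ResidueDynamics",
    "DiffusionTensor",
    "NHOrientation",
    "interaction_constants",
    "spectral_density",
    "forward_rates",
    "rates_from_spectral_density",
]

MU_0 = 4.0e-7 * math.pi          # vacuum permeability, T^2 m^3 / J
HBAR = 1.054571817e-34           # reduced Planck constant, J s

# Gyromagnetic ratios, rad s^-1 T^-1 (15N is negative).
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126e7


class InvalidParameterError(ValueError):
    """Raised when physical parameters violate their domain."""


@dataclass(frozen=True)
class FieldParameters:
    """Spectrometer field and spin-interaction constants.

    Parameters
    ----------
    proton_frequency : float
        1H Larmor frequency in MHz (600.13 for a standard 600 MHz magnet).
    r_nh : float
        N-H bond length in Angstrom.
    csa : float
        15N chemical shift anisotropy in ppm.
    gamma_h, gamma_n : float
        Gyromagnetic ratios in rad s^-1 T^-1; gamma_n must be negative.
    """

    proton_frequency: float = 600.13
    r_nh: float = 1.02
    csa: float = -160.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N

    def __post_init__(self) -> None:
        if self.proton_frequency <= 0:
            raise InvalidParameterError("proton frequency must be positive")
        if self.r_nh <= 0:
            raise InvalidParameterError("N-H bond length must be positive")
        if self.gamma_n >= 0 or self.gamma_h <= 0:
            raise InvalidParameterError(
                "expected gamma_h > 0 and gamma_n < 0 for the 1H/15N pair"
            )

    @property
    def omega_h(self) -> float:
        """1H angular frequency, rad/s (positive)."""
        return 2.0 * math.pi * self.proton_frequency * 1e6

    @property
    def omega_n(self) -> float:
        """15N angular frequency, rad/s (signed, negative)."""
        return self.omega_h * self.gamma_n / self.gamma_h

    @property
    def d(self) -> float:
        """Dipolar interaction constant mu0*hbar*gH*gN/(4 pi r^3), rad/s."""
        r = self.r_nh * 1e-10
        return MU_0 * HBAR * self.gamma_h * self.gamma_n / (4.0 * math.pi * r**3)

    @property
    def c(self) -> float:
        """CSA interaction constant omega_N * delta_sigma / sqrt(3), rad/s."""
        return self.omega_n * self.csa * 1e-6 / math.sqrt(3.0)


def interaction_constants(field: FieldParameters) -> tuple[float, float]:
    """Return the dipolar and CSA interaction constants (d, c) in rad/s.

    ``d = mu0 hbar gH gN / (4 pi r_NH^3)`` and ``c = omega_N * CSA / sqrt(3)``.
    Both enter the relaxation rates squared, so their signs are irrelevant
    everywhere except the NOE, where gamma_H/gamma_N appears explicitly.
    """
    return field.d, field.c


@dataclass(frozen=True)
class ResidueDynamics:
    """Lipari-Szabo internal-motion parameters of one backbone amide.

    ``model_id`` selects the parameterization:

    1. {S2}
    2. {S2, tau_e}
    3. {S2, Rex}
    4. {S2, tau_e, Rex}
    5. {S2f, S2, tau_s} - extended two-timescale form with the fast internal
       correlation time taken as zero; ``tau_e`` then holds the slow internal
       time tau_s and ``s2`` the product S2f*S2s.

    Times are seconds; Rex is s^-1.
    """

    residue_id: int
    model_id: int = 1
    s2: float = 1.0
    tau_e: float = 0.0
    rex: float = 0.0
    s2f: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4, 5):
            raise InvalidParameterError(f"unknown model id {self.model_id}")
        if not 0.0 <= self.s2 <= 1.0:
            raise InvalidParameterError("S2 must lie in [0, 1]")
        if self.model_id == 5 and not self.s2 <= self.s2f <= 1.0:
            raise InvalidParameterError("model 5 requires 0 <= S2 <= S2f <= 1")
        if self.tau_e < 0 or self.rex < 0:
            raise InvalidParameterError("tau_e and Rex must be non-negative")


@dataclass(frozen=True)
class DiffusionTensor:
    """Axially symmetric rotational diffusion tensor.

    ``tau_m`` is the isotropic correlation time 1/(6 D_iso) in seconds;
    ``anisotropy_ratio`` is D_parallel / D_perp (1 = isotropic, > 1 prolate);
    ``axis_theta``/``axis_phi`` orient the unique axis in the structure frame
    (polar/azimuthal angles, radians).  ``chi2`` carries the fit residual when
    the tensor was estimated from data.
    """

    tau_m: float
    anisotropy_ratio: float = 1.0
    axis_theta: float = 0.0
    axis_phi: float = 0.0
    chi2: float = float("nan")

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise InvalidParameterError("tau_m must be positive")
        if self.anisotropy_ratio <= 0:
            raise InvalidParameterError("anisotropy ratio must be positive")

    @property
    def d_iso(self) -> float:
        return 1.0 / (6.0 * self.tau_m)

    @property
    def d_perp(self) -> float:
        return 3.0 * self.d_iso / (self.anisotropy_ratio + 2.0)

    @property
    def d_par(self) -> float:
        return self.anisotropy_ratio * self.d_perp

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the unique diffusion axis in the structure frame."""
        st, ct = math.sin(self.axis_theta), math.cos(self.axis_theta)
        sp, cp = math.sin(self.axis_phi), math.cos(self.axis_phi)
        return np.array([st * cp, st * sp, ct])


@dataclass(frozen=True)
class NHOrientation:
    """Unit N-H bond vector of one residue in the structure frame."""

    residue_id: int
    vector: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        n = float(np.linalg.norm(v))
        if not math.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise InvalidParameterError("N-H vector must be unit length")
        object.__setattr__(self, "vector", v)

    def angle_to(self, axis: np.ndarray) -> float:
        """Angle (rad) between the N-H vector and a given unit axis."""
        c = float(np.clip(np.dot(self.vector, axis), -1.0, 1.0))
        return math.acos(c)


def _axial_weights_times(
    tensor: DiffusionTensor, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes A_k and correlation times tau_k of the three-exponential
    correlation function for axially symmetric tumbling, for an interaction
    vector at angle ``alpha`` to the unique axis.  Sum(A_k) == 1."""
    ca2 = math.cos(alpha) ** 2
    sa2 = 1.0 - ca2
    amps = np.array(
        [
            (1.5 * ca2 - 0.5) ** 2,
            3.0 * sa2 * ca2,
            0.75 * sa2 * sa2,
        ]
    )
    dpe, dpa = tensor.d_perp, tensor.d_par
    rates = np.array([6.0 * dpe, 5.0 * dpe + dpa, 2.0 * dpe + 4.0 * dpa])
    return amps, 1.0 / rates


def spectral_density(
    dyn: ResidueDynamics,
    tensor: DiffusionTensor,
    orient: NHOrientation | None = None,
    omega: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Lipari-Szabo spectral density J(omega) in s/rad.

    Axially symmetric form::

        J(w) = (2/5) sum_k A_k [ S2 tau_k / (1 + (w tau_k)^2)
                                 + (S2f - S2) tau'_k / (1 + (w tau'_k)^2) ]

    with 1/tau'_k = 1/tau_k + 1/tau_e and S2f = 1 for models 1-4.  In the
    isotropic limit (ratio 1) the three tau_k collapse to tau_m and the
    orientation is irrelevant.  ``omega`` may be a scalar or array (rad/s);
    J is even, so the absolute value is used.
    """
    if orient is None or tensor.anisotropy_ratio == 1.0:
        alpha = 0.0 if orient is None else orient.angle_to(tensor.axis)
    else:
        alpha = orient.angle_to(tensor.axis)
    amps, taus = _axial_weights_times(tensor, alpha)

    s2 = dyn.s2
    s2f = dyn.s2f if dyn.model_id == 5 else 1.0
    w = np.atleast_1d(np.abs(np.asarray(omega, dtype=float)))

    j = np.zeros_like(w)
    for a_k, t_k in zip(amps, taus):
        j += a_k * s2 * t_k / (1.0 + (w * t_k) ** 2)
        if s2f - s2 != 0.0 and dyn.tau_e > 0.0:
            tp = t_k * dyn.tau_e / (t_k + dyn.tau_e)
            j += a_k * (s2f - s2) * tp / (1.0 + (w * tp) ** 2)
    j *= 0.4
    if np.isscalar(omega) or np.ndim(omega) == 0:
        return float(j[0])
    return j


def rates_from_spectral_density(
    jfunc,
    field: FieldParameters,
    rex: float = 0.0,
) -> tuple[float, float, float]:
    """R1, R2 and NOE from an arbitrary spectral density function.

    ``jfunc`` maps an angular frequency (rad/s, >= 0) to J in s/rad.  This is
    the single point where the dipolar/CSA rate expressions live; both the
    Lipari-Szabo forward model and the reduced spectral density inversion go
    through it, which keeps the two internally consistent by construction.
    """
    d, c = interaction_constants(field)
    d2_4 = 0.25 * d * d
    c2 = c * c
    wh = field.omega_h
    wn = abs(field.omega_n)

    j0 = jfunc(0.0)
    jn = jfunc(wn)
    jmh = jfunc(wh - wn)
    jh = jfunc(wh)
    jph = jfunc(wh + wn)

    r1 = d2_4 * (jmh + 3.0 * jn + 6.0 * jph) + c2 * jn
    r2 = (
        0.5 * d2_4 * (4.0 * j0 + jmh + 3.0 * jn + 6.0 * jh + 6.0 * jph)
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn)
        + rex
    )
    if r1 <= 0.0:
        raise InvalidParameterError("non-positive R1; cannot form the NOE")
    sigma_nh = d2_4 * (6.0 * jph - jmh)
    noe = 1.0 + (field.gamma_h / field.gamma_n) * sigma_nh / r1
    return float(r1), float(r2), float(noe)


def forward_rates(
    dyn: ResidueDynamics,
    tensor: DiffusionTensor,
    orient: NHOrientation | None,
    field: FieldParameters,
) -> tuple[float, float, float]:
    """Predict (R1 s^-1, R2 s^-1, NOE) for one residue.

    Standard single-field 15N expressions; Rex enters R2 additively and
    touches neither R1 nor the NOE.
    """
    return rates_from_spectral_density(
        lambda w: spectral_density(dyn, tensor, orient, w), field, rex=dyn.rex
    )
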