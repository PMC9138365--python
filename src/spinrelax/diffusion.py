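"""Global rotational diffusion tensor from rigid-residue R2/R1 ratios.

The R2/R1 ratio of a rigid backbone amide depends only on the overall
tumbling (and, for anisotropic tumbling, on the angle between the N-H bond
and the unique axis): the order parameter cancels and internal motion is
negligible once flexible and exchange-broadened residues are removed.  The
fit therefore proceeds in three steps: select rigid residues, solve the
isotropic correlation time from the mean ratio, then refine an axially
symmetric tensor (tau_m, D_par/D_perp, axis) against the per-residue ratios.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.optimize import brentq, least_squares

from .physics import (
    DiffusionTensor,
    FieldParameters,
    NHOrientation,
    ResidueDynamics,
    forward_rates,
)
from .decay import RelaxationRecord

__all__ = [
    "select_rigid_residues",
    "fit_isotropic_tm",
    "fit_axially_symmetric",
    "rigid_ratio",
]

log = logging.getLogger(__name__)

NOE_CUTOFF = 0.65          # flexible residues fall below this
TRIM_SD_FACTOR = 1.5       # one-pass trim of |ratio - median| > 1.5 SD
MIN_RIGID_RESIDUES = 10


class TensorFitError(RuntimeError):
    pass


def _rigid_dyn(residue_id: int = 0) -> ResidueDynamics:
    return ResidueDynamics(residue_id, model_id=1, s2=1.0)


def rigid_ratio(
    tensor: DiffusionTensor,
    field: FieldParameters,
    orient: NHOrientation | None = None,
) -> float:
    """R2/R1 of a rigid residue (S2=1, tau_e=0, Rex=0) under ``tensor``."""
    r1, r2, _ = forward_rates(_rigid_dyn(), tensor, orient, field)
    return r2 / r1


def select_rigid_residues(
    records: list[RelaxationRecord],
    noe_cutoff: float = NOE_CUTOFF,
    trim_sd: float = TRIM_SD_FACTOR,
) -> list[RelaxationRecord]:
    """Keep residues suitable for the tensor fit.

    NOE >= cutoff discards ps-ns flexible residues; a single trimming pass on
    |R2/R1 - median| > trim_sd * SD then discards exchange-inflated (large
    Rex) and remaining flexible outliers.
    """
    usable = [r for r in records if not r.flagged]
    if len(usable) < MIN_RIGID_RESIDUES:
        raise TensorFitError("fewer than 10 usable records")
    kept = [r for r in usable if r.noe >= noe_cutoff]
    ratios = np.array([r.r2 / r.r1 for r in kept])
    if len(kept) >= MIN_RIGID_RESIDUES:
        med, sd = np.median(ratios), np.std(ratios)
        if sd > 0:
            kept = [
                r for r, rho in zip(kept, ratios) if abs(rho - med) <= trim_sd * sd
            ]
    if len(kept) < MIN_RIGID_RESIDUES:
        raise TensorFitError(
            f"only {len(kept)} rigid residues survive selection; relax the "
            f"NOE cutoff ({noe_cutoff}) or trimming factor"
        )
    log.info("rigid-residue selection kept %d of %d records", len(kept), len(records))
    return kept


def fit_isotropic_tm(
    subset: list[RelaxationRecord],
    field: FieldParameters,
    bracket_ns: tuple[float, float] = (1.0, 50.0),
) -> float:
    """Isotropic tau_m (seconds) solving mean R2/R1 = rigid-limit ratio(tau_m).

    The rigid-limit ratio increases strictly with tau_m over the bracket, so
    bracketed root finding is well posed.
    """
    if not subset:
        raise TensorFitError("empty rigid subset")
    target = float(np.mean([r.r2 / r.r1 for r in subset]))

    def f(tm_ns: float) -> float:
        return rigid_ratio(DiffusionTensor(tau_m=tm_ns * 1e-9), field) - target

    lo, hi = bracket_ns
    if f(lo) > 0 or f(hi) < 0:
        raise TensorFitError(
            f"mean R2/R1 = {target:.2f} outside the achievable range for "
            f"tau_m in [{lo}, {hi}] ns"
        )
    return brentq(f, lo, hi, xtol=1e-10) * 1e-9


def _sphere_grid(n: int) -> np.ndarray:
    """Fibonacci grid of n axis seeds on the upper hemisphere."""
    i = np.arange(n)
    phi = (1 + math.sqrt(5)) / 2
    z = (i + 0.5) / n                      # upper hemisphere only
    theta = np.arccos(z)
    az = 2 * math.pi * i / phi
    return np.stack([theta, az % (2 * math.pi)], axis=1)


def _ratio_model(
    params: np.ndarray, nh_vectors: np.ndarray, field: FieldParameters
) -> np.ndarray:
    """Vectorized rigid R2/R1 for all residues given (tm_ns, ratio, theta, phi)."""
    tm_ns, ratio, theta, phi = params
    tensor = DiffusionTensor(
        tau_m=tm_ns * 1e-9, anisotropy_ratio=ratio, axis_theta=theta, axis_phi=phi
    )
    axis = tensor.axis
    cos_a = np.clip(nh_vectors @ axis, -1.0, 1.0)
    ca2 = cos_a**2
    sa2 = 1.0 - ca2
    amps = np.stack(
        [(1.5 * ca2 - 0.5) ** 2, 3.0 * sa2 * ca2, 0.75 * sa2 * sa2], axis=1
    )
    dpe, dpa = tensor.d_perp, tensor.d_par
    taus = 1.0 / np.array([6 * dpe, 5 * dpe + dpa, 2 * dpe + 4 * dpa])

    wh, wn = field.omega_h, abs(field.omega_n)
    freqs = np.array([0.0, wn, wh - wn, wh, wh + wn])
    # J[residue, frequency] = (2/5) sum_k A_k tau_k / (1 + (w tau_k)^2)
    lor = taus[:, None] / (1.0 + (freqs[None, :] * taus[:, None]) ** 2)  # (3, 5)
    j = 0.4 * amps @ lor                                                 # (n, 5)

    d, c = field.d, field.c
    d2_4, c2 = 0.25 * d * d, c * c
    j0, jn, jmh, jh, jph = j.T
    r1 = d2_4 * (jmh + 3 * jn + 6 * jph) + c2 * jn
    r2 = 0.5 * d2_4 * (4 * j0 + jmh + 3 * jn + 6 * jh + 6 * jph) + (c2 / 6) * (
        4 * j0 + 3 * jn
    )
    return r2 / r1


def fit_axially_symmetric(
    subset: list[RelaxationRecord],
    orientations: dict[int, NHOrientation],
    field: FieldParameters,
    n_axis_starts: int = 12,
) -> DiffusionTensor:
    """Fit (tau_m, D_par/D_perp, axis) to rigid-residue R2/R1 ratios.

    Minimizes chi^2 = sum [(rho_obs - rho_calc)/sigma_rho]^2 with sigma_rho
    from first-order propagation of the rate uncertainties.  Multi-start over
    a hemisphere grid of axis seeds, tau_m seeded from the isotropic fit.
    The antipodal degeneracy is folded to theta in [0, pi/2]; prolate/oblate
    chi^2 ties are reported as the prolate (ratio >= 1) solution.
    """
    missing = [r.residue_id for r in subset if r.residue_id not in orientations]
    if missing:
        raise TensorFitError(f"missing N-H orientations for residues {missing}")
    nh = np.array([orientations[r.residue_id].vector for r in subset])
    rho = np.array([r.r2 / r.r1 for r in subset])
    sigma = np.array(
        [
            (r.r2 / r.r1)
            * math.sqrt((r.r1_err / r.r1) ** 2 + (r.r2_err / r.r2) ** 2)
            for r in subset
        ]
    )
    sigma = np.where(sigma > 0, sigma, np.median(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0)

    tm0 = fit_isotropic_tm(subset, field) * 1e9

    def residuals(p: np.ndarray) -> np.ndarray:
        return (_ratio_model(p, nh, field) - rho) / sigma

    best = None
    lb = [1.0, 0.5, 0.0, -2 * math.pi]
    ub = [50.0, 2.5, math.pi, 4 * math.pi]
    for theta0, phi0 in _sphere_grid(n_axis_starts):
        for ratio0 in (1.1,):
            try:
                sol = least_squares(
                    residuals,
                    x0=[tm0, ratio0, theta0, phi0],
                    bounds=(lb, ub),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise TensorFitError("axially symmetric fit failed from every start")

    tm_ns, ratio, theta, phi = best.x
    chi2 = float(2.0 * best.cost)

    # prefer the prolate representation when an oblate fit is chi^2-equivalent
    if ratio < 1.0:
        sol_pro = None
        for theta0, phi0 in _sphere_grid(n_axis_starts):
            sol = least_squares(
                residuals, x0=[tm_ns, 1.0 + (1.0 - ratio), theta0, phi0],
                bounds=([1.0, 1.0, 0.0, -2 * math.pi], ub),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if sol_pro is None or sol.cost < sol_pro.cost:
                sol_pro = sol
        if sol_pro is not None and 2 * sol_pro.cost <= chi2 * (1 + 1e-6) + 1e-9:
            tm_ns, ratio, theta, phi = sol_pro.x
            chi2 = float(2.0 * sol_pro.cost)

    # fold the axis: antipodal symmetry, report theta in [0, pi/2]
    theta = theta % math.pi
    phi = phi % (2 * math.pi)
    if theta > math.pi / 2:
        theta = math.pi - theta
        phi = (phi + math.pi) % (2 * math.pi)

    return DiffusionTensor(
        tau_m=tm_ns * 1e-9, anisotropy_ratio=ratio,
        axis_theta=theta, axis_phi=phi, chi2=chi2,
    )
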