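"""Reduced spectral density mapping.

Each residue's (R1, R2, NOE) triple is converted, without any motional
model, into the spectral density sampled at three frequencies: J(0),
J(omega_N) and J(0.87 omega_H).  The reduction rests on the high-frequency
approximation J(omega_H - omega_N) ~ J(omega_H) ~ J(omega_H + omega_N) ~
J(0.87 omega_H), which holds because the spectral density is nearly flat
around the 1H frequency.

The inversion is obtained by numerically inverting the forward linear map
from (J0, JN, J087) to (R1, R2, sigma_NH) built from the same rate
expressions as the Lipari-Szabo forward model, so forward and inverse share
one set of interaction constants by construction and round-trip exactly.
Exchange contributions to R2 are not separated: Rex shows up as inflated
apparent J(0), which is precisely what makes J(0) a reporter of us-ms
motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import RelaxationRecord
from .physics import FieldParameters, rates_from_spectral_density

__all__ = [
    "SpectralDensityTriple",
    "reduction_matrix",
    "reduced_spectral_densities",
    "rates_from_triple",
    "fragment_average",
]

log = logging.getLogger(__name__)

HIGH_FREQ_COEFF = 0.87


@dataclass
class SpectralDensityTriple:
    """J(0), J(omega_N), J(0.87 omega_H) of one residue, s/rad, with errors."""

    residue_id: int
    j0: float
    j0_err: float
    j_wn: float
    j_wn_err: float
    j_wh: float
    j_wh_err: float


def _reduced_jfunc(triple: np.ndarray, field: FieldParameters):
    """Spectral density function of the reduced three-point basis."""
    j0, jn, jh = triple
    wn = abs(field.omega_n)

    def jfunc(w: float) -> float:
        if w == 0.0:
            return j0
        if w <= 2.0 * wn:
            return jn
        return jh

    return jfunc


def reduction_matrix(field: FieldParameters) -> np.ndarray:
    """Linear map M with (R1, R2, sigma_NH) = M @ (J0, J(wN), J(0.87 wH)).

    Columns are the forward rates evaluated on the unit basis triples, using
    the identical dipolar/CSA expressions as the forward relaxation model.
    sigma_NH is the 1H->15N cross-relaxation rate R1*(NOE-1)*gamma_N/gamma_H.
    """
    cols = []
    for basis in np.eye(3):
        jf = _reduced_jfunc(basis, field)
        d, c = field.d, field.c
        d2_4, c2 = 0.25 * d * d, c * c
        wh, wn = field.omega_h, abs(field.omega_n)
        j0, jn = jf(0.0), jf(wn)
        jmh, jh, jph = jf(wh - wn), jf(wh), jf(wh + wn)
        r1 = d2_4 * (jmh + 3 * jn + 6 * jph) + c2 * jn
        r2 = 0.5 * d2_4 * (4 * j0 + jmh + 3 * jn + 6 * jh + 6 * jph) + (c2 / 6) * (
            4 * j0 + 3 * jn
        )
        sigma_nh = d2_4 * (6 * jph - jmh)
        cols.append([r1, r2, sigma_nh])
    return np.array(cols).T


def rates_from_triple(
    triple: np.ndarray | tuple[float, float, float], field: FieldParameters
) -> tuple[float, float, float]:
    """(R1, R2, NOE) of an arbitrary positive reduced J-triple (s/rad)."""
    return rates_from_spectral_density(
        _reduced_jfunc(np.asarray(triple, dtype=float), field), field
    )


def reduced_spectral_densities(
    record: RelaxationRecord, field: FieldParameters
) -> SpectralDensityTriple:
    """Map one relaxation record to its reduced spectral density triple.

    Solves the linear system M @ (J0, JN, J087) = (R1, R2, sigma_NH) where
    sigma_NH = R1 (NOE - 1) gamma_N / gamma_H.  Uncertainties follow by
    first-order propagation through the same linear map (the Jacobian of the
    observable vector with respect to (R1, R2, NOE) is explicit).
    """
    if record.r1 <= 0:
        raise ValueError("R1 must be positive")
    g = field.gamma_n / field.gamma_h
    m_inv = np.linalg.inv(reduction_matrix(field))

    v = np.array(
        [record.r1, record.r2, record.r1 * (record.noe - 1.0) * g]
    )
    j = m_inv @ v

    # Jacobian of v = (R1, R2, sigma_NH) w.r.t. (R1, R2, NOE)
    jac_v = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [(record.noe - 1.0) * g, 0.0, record.r1 * g],
        ]
    )
    cov_obs = np.diag([record.r1_err**2, record.r2_err**2, record.noe_err**2])
    cov_j = m_inv @ jac_v @ cov_obs @ jac_v.T @ m_inv.T
    err = np.sqrt(np.clip(np.diag(cov_j), 0.0, None))

    return SpectralDensityTriple(
        record.residue_id, j[0], err[0], j[1], err[1], j[2], err[2]
    )


def fragment_average(
    triples: list[SpectralDensityTriple],
    ranges: dict[str, tuple[int, int]],
) -> pd.DataFrame:
    """Mean and SD of each J over the residues present in each named range.

    Residues missing from a range are skipped with a log line; an empty
    range is an error.  Returns one row per fragment with columns
    fragment, n, J0_mean, J0_sd, JwN_mean, JwN_sd, JwH_mean, JwH_sd.
    """
    by_res = {t.residue_id: t for t in triples}
    rows = []
    for name, (lo, hi) in ranges.items():
        present = [by_res[r] for r in range(lo, hi + 1) if r in by_res]
        missing = [r for r in range(lo, hi + 1) if r not in by_res]
        if missing:
            log.info("fragment %s: %d residues absent, skipped", name, len(missing))
        if not present:
            raise ValueError(f"fragment {name} ({lo}-{hi}) contains no residues")
        j0 = np.array([t.j0 for t in present])
        jn = np.array([t.j_wn for t in present])
        jh = np.array([t.j_wh for t in present])
        rows.append(
            dict(
                fragment=name, n=len(present),
                J0_mean=j0.mean(), J0_sd=j0.std(),
                JwN_mean=jn.mean(), JwN_sd=jn.std(),
                JwH_mean=jh.mean(), JwH_sd=jh.std(),
            )
        )
    return pd.DataFrame(rows)


def map_records(
    records: list[RelaxationRecord], field: FieldParameters
) -> list[SpectralDensityTriple]:
    """Reduced mapping of every unflagged record."""
    return [
        reduced_spectral_densities(r, field) for r in records if not r.flagged
    ]
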