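"""Mono-exponential decay fitting and NOE ratios for 15N relaxation series.

Peak-intensity decay tables (one intensity per relaxation delay, with the
two longest delays acquired twice) are turned into R1/R2 rates with
uncertainties; saturated/unsaturated intensity pairs become heteronuclear
NOE values.  The intensity uncertainty is estimated from the duplicated
delays, pooled across residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecaySeries",
    "RelaxationRecord",
    "estimate_intensity_error",
    "fit_monoexponential",
    "compute_noe",
    "fit_relaxation_table",
    "read_decay_table",
    "write_relaxation_table",
    "read_relaxation_table",
]

log = logging.getLogger(__name__)

#: records with sigma_R / R above this, or non-positive R, are flagged and
#: excluded from the tensor and model-free stages
MAX_RELATIVE_RATE_ERROR = 0.5


class NoDuplicateDelaysError(ValueError):
    """No duplicated delays: supply the intensity uncertainty explicitly."""


@dataclass
class DecaySeries:
    """Intensity decay of one residue: delays (s), intensities, duplicate flags."""

    residue_id: int
    delays: np.ndarray
    intensities: np.ndarray
    duplicate: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.duplicate = np.asarray(self.duplicate, dtype=bool)
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if len(np.unique(self.delays)) < 3:
            raise ValueError("need at least 3 distinct delays")


@dataclass
class RelaxationRecord:
    """Measured (or simulated) relaxation observables of one residue."""

    residue_id: int
    r1: float
    r1_err: float
    r2: float
    r2_err: float
    noe: float
    noe_err: float
    flagged: bool = False


def _duplicate_pair_diffs(series: DecaySeries) -> list[float]:
    diffs = []
    for t in np.unique(series.delays[series.duplicate]):
        vals = series.intensities[series.delays == t]
        # consecutive non-overlapping pairs at this delay (normally one pair)
        for a, b in zip(vals[0::2], vals[1::2]):
            diffs.append(float(a - b))
    return diffs


def estimate_intensity_error(series_list: list[DecaySeries] | DecaySeries) -> float:
    """Pooled intensity uncertainty from duplicated delays.

    sigma_I = RMS(paired differences) / sqrt(2): each difference of two
    equal-mean measurements has variance 2 sigma_I^2.  Differences are pooled
    across residues, since a single residue contributes only two pairs.
    """
    if isinstance(series_list, DecaySeries):
        series_list = [series_list]
    diffs: list[float] = []
    for s in series_list:
        diffs.extend(_duplicate_pair_diffs(s))
    if not diffs:
        raise NoDuplicateDelaysError(
            "no duplicated delays found; supply sigma_I in the configuration"
        )
    return float(np.sqrt(np.mean(np.square(diffs)) / 2.0))


def fit_monoexponential(
    series: DecaySeries, sigma_i: float | None = None
) -> tuple[float, float]:
    """Weighted least-squares fit of I(t) = I0 exp(-R t); returns (R, sigma_R).

    Initialized from a log-linear regression on the positive intensities.
    Duplicated delays enter as independent points.  Returns (nan, nan) on
    non-convergence; callers flag and exclude such residues.
    """
    t = series.delays
    y = series.intensities
    if np.allclose(y, y[0]):
        raise ValueError("intensities are all equal; no decay to fit")

    # canonical row order and intensity scale: the fit is then exactly
    # invariant to row permutation and uniform rescaling of the series
    order = np.lexsort((y, t))
    t, y = t[order], y[order]
    scale = float(np.max(np.abs(y)))
    y = y / scale
    if sigma_i is not None:
        sigma_i = sigma_i / scale

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), max(-slope, 1e-6))
    else:
        p0 = (float(np.max(np.abs(y))), 1.0)

    sigma = None
    if sigma_i is not None and sigma_i > 0:
        sigma = np.full_like(y, sigma_i)
    try:
        popt, _ = curve_fit(
            lambda tt, i0, r: i0 * np.exp(-r * tt),
            t,
            y,
            p0=p0,
            sigma=sigma,
            absolute_sigma=sigma is not None,
            maxfev=10000,
        )
    except RuntimeError:
        log.warning("residue %s: decay fit did not converge", series.residue_id)
        return float("nan"), float("nan")

    popt, pcov = _gauss_newton_polish(t, y, sigma, popt)
    r = float(popt[1])
    r_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return r, r_err


def _gauss_newton_polish(t, y, sigma, p0, max_iter=50):
    """Drive the two-parameter fit to machine precision.

    The trust-region solver stops within its termination slack; a few exact
    Gauss-Newton steps from there make the result reproducible to ~1e-13,
    so permutation/rescaling invariance holds at tight tolerance.  Returns
    the polished parameters and their covariance (absolute when sigma is
    given, residual-scaled otherwise).
    """
    w = 1.0 / sigma if sigma is not None else np.ones_like(y)
    i0, r = p0
    for _ in range(max_iter):
        e = np.exp(-r * t)
        resid = (i0 * e - y) * w
        jac = np.column_stack([e * w, -i0 * t * e * w])
        try:
            step, *_ = np.linalg.lstsq(jac, -resid, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        i0, r = i0 + step[0], r + step[1]
        if max(abs(step[0]) / max(abs(i0), 1e-300),
               abs(step[1]) / max(abs(r), 1e-300)) < 1e-14:
            break
    e = np.exp(-r * t)
    jac = np.column_stack([e * w, -i0 * t * e * w])
    jtj_inv = np.linalg.inv(jac.T @ jac)
    if sigma is None:
        resid = (i0 * e - y) * w
        dof = max(len(y) - 2, 1)
        jtj_inv = jtj_inv * float(resid @ resid) / dof
    return (i0, r), jtj_inv


def compute_noe(
    i_sat: float, i_unsat: float, sigma_i: float
) -> tuple[float, float]:
    """Heteronuclear NOE = I_sat / I_unsat with first-order error propagation.

    sigma_NOE = |NOE| sqrt((sigma_I/I_sat)^2 + (sigma_I/I_unsat)^2).  The sign
    of the ratio is preserved: highly flexible residues give negative NOEs.
    """
    if i_unsat == 0:
        raise ValueError("unsaturated intensity is zero")
    noe = i_sat / i_unsat
    if i_sat == 0:
        sigma_noe = abs(sigma_i / i_unsat)
    else:
        sigma_noe = abs(noe) * math.sqrt(
            (sigma_i / i_sat) ** 2 + (sigma_i / i_unsat) ** 2
        )
    return noe, sigma_noe


# ---------------------------------------------------------------------------
# Table-level drivers and TSV I/O

def _series_from_table(table: pd.DataFrame) -> list[DecaySeries]:
    out = []
    for rid, grp in table.groupby("residue"):
        out.append(
            DecaySeries(
                int(rid),
                grp["delay_s"].to_numpy(),
                grp["intensity"].to_numpy(),
                grp["duplicate"].to_numpy(),
            )
        )
    return out


def fit_relaxation_table(
    t1_table: pd.DataFrame,
    t2_table: pd.DataFrame,
    noe_table: pd.DataFrame,
    sigma_i: float | None = None,
) -> pd.DataFrame:
    """Fit every residue's R1, R2 and NOE; returns the relaxation table.

    Columns: residue, R1, R1_err, R2, R2_err, NOE, NOE_err, flagged.
    ``sigma_i`` overrides the duplicate-based pooled intensity error (it is
    required when the tables carry no duplicated delays).  Records with
    relative rate error above MAX_RELATIVE_RATE_ERROR or a non-positive rate
    are flagged.
    """
    t1_series = _series_from_table(t1_table)
    t2_series = _series_from_table(t2_table)
    try:
        sig1 = sigma_i if sigma_i is not None else estimate_intensity_error(t1_series)
        sig2 = sigma_i if sigma_i is not None else estimate_intensity_error(t2_series)
    except NoDuplicateDelaysError:
        raise
    # NOE intensity error: reuse the pooled T1 estimate scaled to the NOE
    # reference intensity; both experiments share the detection scheme.
    sig_noe_i = sigma_i if sigma_i is not None else sig1

    rows = []
    noe_by_res = noe_table.set_index("residue")
    for s1 in t1_series:
        rid = s1.residue_id
        r1, r1e = fit_monoexponential(s1, sig1)
        s2 = next((s for s in t2_series if s.residue_id == rid), None)
        if s2 is None or rid not in noe_by_res.index:
            log.info("residue %d: incomplete data, skipped", rid)
            continue
        r2, r2e = fit_monoexponential(s2, sig2)
        noe, noee = compute_noe(
            float(noe_by_res.loc[rid, "intensity_sat"]),
            float(noe_by_res.loc[rid, "intensity_unsat"]),
            sig_noe_i,
        )
        flagged = (
            not np.isfinite(r1)
            or not np.isfinite(r2)
            or r1 <= 0
            or r2 <= 0
            or (np.isfinite(r1e) and r1 > 0 and r1e / r1 > MAX_RELATIVE_RATE_ERROR)
            or (np.isfinite(r2e) and r2 > 0 and r2e / r2 > MAX_RELATIVE_RATE_ERROR)
        )
        rows.append(
            dict(
                residue=rid, R1=r1, R1_err=r1e, R2=r2, R2_err=r2e,
                NOE=noe, NOE_err=noee, flagged=flagged,
            )
        )
    return pd.DataFrame(rows)


def records_from_table(table: pd.DataFrame) -> list[RelaxationRecord]:
    return [
        RelaxationRecord(
            int(r.residue), r.R1, r.R1_err, r.R2, r.R2_err, r.NOE, r.NOE_err,
            bool(getattr(r, "flagged", False)),
        )
        for r in table.itertuples(index=False)
    ]


def read_decay_table(path) -> pd.DataFrame:
    """Read a decay TSV: residue, delay_s, intensity, duplicate."""
    df = pd.read_csv(path, sep="\t")
    df["duplicate"] = df["duplicate"].astype(bool)
    return df


def write_relaxation_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_relaxation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
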