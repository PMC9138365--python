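"""Per-residue Lipari-Szabo model-free fitting with F-test model selection.

Five nested parameterizations of internal motion are fitted to each
residue's (R1, R2, NOE) triple with the global diffusion tensor held fixed:

====== ==================== =======================================
model  parameters           motion described
====== ==================== =======================================
M1     S2                   rigid on the ps-ns timescale
M2     S2, tau_e            ps-ns motion with an internal time
M3     S2, Rex              exchange contribution to R2
M4     S2, tau_e, Rex       both
M5     S2f, S2, tau_s       extended two-timescale internal motion
====== ==================== =======================================

With a single field there are three observables per residue, so model
selection must be parsimonious: complexity is accepted only when an F-test
between nested fits rejects the simpler model (or, for the three-parameter
models whose F denominator has zero degrees of freedom, when the simpler
candidate is statistically inadequate and the complex model fits the triple
essentially exactly).  Parameter uncertainties come from Monte-Carlo
resampling of the observables under their quoted errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .decay import RelaxationRecord
from .physics import (
    DiffusionTensor,
    FieldParameters,
    NHOrientation,
    ResidueDynamics,
    forward_rates,
)

__all__ = ["ModelFit", "fit_model", "select_model", "run_modelfree", "MODEL_PARAMS"]

log = logging.getLogger(__name__)

MODEL_PARAMS: dict[int, tuple[str, ...]] = {
    1: ("s2",),
    2: ("s2", "tau_e"),
    3: ("s2", "rex"),
    4: ("s2", "tau_e", "rex"),
    5: ("s2f", "s2s", "tau_s"),
}

REX_MAX = 50.0           # s^-1, upper bound for the exchange term
EXACT_FIT_CHI2 = 0.05    # three-parameter models must fit the triple this well
F_TEST_ALPHA = 0.05

#: coarse multi-start grid (S2 x tau_e) prescribed for the bounded fits
S2_GRID = (0.3, 0.6, 0.9)
TAU_GRID_S = (10e-12, 200e-12, 1e-9)


@dataclass
class ModelFit:
    residue_id: int
    model_id: int
    dynamics: ResidueDynamics
    chi2: float
    n_params: int
    param_errors: dict[str, float] = dc_field(default_factory=dict)


def _dyn_from_params(residue_id: int, model_id: int, x: np.ndarray) -> ResidueDynamics:
    if model_id == 1:
        return ResidueDynamics(residue_id, 1, s2=x[0])
    if model_id == 2:
        return ResidueDynamics(residue_id, 2, s2=x[0], tau_e=x[1])
    if model_id == 3:
        return ResidueDynamics(residue_id, 3, s2=x[0], rex=x[1])
    if model_id == 4:
        return ResidueDynamics(residue_id, 4, s2=x[0], tau_e=x[1], rex=x[2])
    # model 5: parameterized as (S2f, S2s, tau_s); S2 = S2f * S2s
    s2f, s2s, tau_s = x
    return ResidueDynamics(residue_id, 5, s2=s2f * s2s, tau_e=tau_s, s2f=s2f)


def _precompute(
    tensor: DiffusionTensor, orient: NHOrientation | None, field: FieldParameters
) -> tuple:
    """Constants reused across every model fit of one residue."""
    from .physics import _axial_weights_times

    alpha = 0.0 if orient is None else orient.angle_to(tensor.axis)
    amps, taus = _axial_weights_times(tensor, alpha)
    wh, wn = field.omega_h, abs(field.omega_n)
    freqs = np.array([0.0, wn, wh - wn, wh, wh + wn])
    d, c = field.d, field.c
    return amps, taus, freqs, 0.25 * d * d, c * c, field.gamma_h / field.gamma_n


def _rates_fast(
    s2: float, tau_e: float, rex: float, s2f: float, pre: tuple
) -> tuple[float, float, float]:
    """forward_rates specialized to precomputed tensor/orientation factors."""
    amps, taus, freqs, d2_4, c2, g = pre
    lor = taus[:, None] / (1.0 + (freqs[None, :] * taus[:, None]) ** 2)
    j = s2 * (amps @ lor)
    if s2f != s2 and tau_e > 0.0:
        tp = taus * tau_e / (taus + tau_e)
        lorp = tp[:, None] / (1.0 + (freqs[None, :] * tp[:, None]) ** 2)
        j = j + (s2f - s2) * (amps @ lorp)
    j0, jn, jmh, jh, jph = 0.4 * j
    r1 = d2_4 * (jmh + 3 * jn + 6 * jph) + c2 * jn
    r2 = (
        0.5 * d2_4 * (4 * j0 + jmh + 3 * jn + 6 * jh + 6 * jph)
        + (c2 / 6.0) * (4 * j0 + 3 * jn)
        + rex
    )
    noe = 1.0 + g * d2_4 * (6 * jph - jmh) / r1
    return r1, r2, noe


def _unpack(model_id: int, x: np.ndarray) -> tuple[float, float, float, float]:
    """(s2, tau_e, rex, s2f) from the fit vector of a model."""
    if model_id == 1:
        return x[0], 0.0, 0.0, 1.0
    if model_id == 2:
        return x[0], x[1], 0.0, 1.0
    if model_id == 3:
        return x[0], 0.0, x[1], 1.0
    if model_id == 4:
        return x[0], x[1], x[2], 1.0
    s2f, s2s, tau_s = x
    return s2f * s2s, tau_s, 0.0, s2f


def _pack(fit: "ModelFit") -> np.ndarray:
    """Fit vector of a ModelFit (inverse of _dyn_from_params)."""
    d = fit.dynamics
    if fit.model_id == 1:
        return np.array([d.s2])
    if fit.model_id == 2:
        return np.array([d.s2, d.tau_e])
    if fit.model_id == 3:
        return np.array([d.s2, d.rex])
    if fit.model_id == 4:
        return np.array([d.s2, d.tau_e, d.rex])
    s2s = d.s2 / d.s2f if d.s2f > 0 else 0.0
    return np.array([d.s2f, s2s, d.tau_e])


def _residuals(
    x: np.ndarray,
    model_id: int,
    record: RelaxationRecord,
    pre: tuple,
) -> np.ndarray:
    s2, tau_e, rex, s2f = _unpack(model_id, np.clip(x, 0.0, None))
    r1, r2, noe = _rates_fast(s2, tau_e, rex, s2f, pre)
    return np.array(
        [
            (r1 - record.r1) / record.r1_err,
            (r2 - record.r2) / record.r2_err,
            (noe - record.noe) / record.noe_err,
        ]
    )


def _starts(model_id: int, tensor: DiffusionTensor) -> list[np.ndarray]:
    tau_grid = [t for t in TAU_GRID_S if t < tensor.tau_m]
    if model_id == 1:
        return [np.array([s]) for s in S2_GRID]
    if model_id == 2:
        return [np.array([s, t]) for s in S2_GRID for t in tau_grid]
    if model_id == 3:
        return [np.array([s, rex]) for s in S2_GRID for rex in (1.0, 5.0, 15.0)]
    if model_id == 4:
        return [
            np.array([s, t, rex])
            for s in S2_GRID
            for t in tau_grid
            for rex in (1.0, 8.0)
        ]
    return [np.array([sf, ss, t]) for sf in (0.6, 0.9) for ss in S2_GRID for t in tau_grid]


def _bounds(model_id: int, tensor: DiffusionTensor) -> tuple[list, list]:
    tau_max = tensor.tau_m
    if model_id == 1:
        return [0.0], [1.0]
    if model_id == 2:
        return [0.0, 0.0], [1.0, tau_max]
    if model_id == 3:
        return [0.0, 0.0], [1.0, REX_MAX]
    if model_id == 4:
        return [0.0, 0.0, 0.0], [1.0, tau_max, REX_MAX]
    return [0.0, 0.0, 0.0], [1.0, 1.0, tau_max]


def _x_scale(model_id: int) -> list[float]:
    # characteristic parameter magnitudes: order parameters ~1, internal
    # times ~100 ps (in seconds), exchange rates ~ a few 1/s
    return {
        1: [1.0],
        2: [1.0, 1e-10],
        3: [1.0, 1.0],
        4: [1.0, 1e-10, 1.0],
        5: [1.0, 1.0, 1e-10],
    }[model_id]


def fit_model(
    record: RelaxationRecord,
    model_id: int,
    tensor: DiffusionTensor,
    orient: NHOrientation | None,
    field: FieldParameters,
    x0: np.ndarray | None = None,
) -> ModelFit:
    """Bounded least-squares fit of one model to one residue's rate triple.

    chi^2 = sum over (R1, R2, NOE) of ((obs - calc)/sigma)^2, minimized by
    trust-region least squares from a coarse multi-start grid (S2 in
    {0.3, 0.6, 0.9} crossed with tau_e in {10 ps, 200 ps, 1 ns}).  Bounds:
    S2 and S2f in [0, 1], internal times in [0, tau_m], Rex in [0, 50] s^-1.
    Non-convergence from every start yields a flagged fit with chi^2 = inf.
    """
    if model_id not in MODEL_PARAMS:
        raise ValueError(f"unknown model id {model_id}")
    lb, ub = _bounds(model_id, tensor)
    pre = _precompute(tensor, orient, field)

    if x0 is not None:
        ranked = [np.clip(np.asarray(x0, dtype=float), lb, ub)]
    else:
        # rank the coarse grid by chi^2, polish only the most promising starts
        starts = [np.clip(s, lb, ub) for s in _starts(model_id, tensor)]
        grid_cost = [
            float(np.sum(_residuals(s, model_id, record, pre) ** 2)) for s in starts
        ]
        ranked = [starts[i] for i in np.argsort(grid_cost)[:3]]

    best = None
    for xs in ranked:
        try:
            sol = least_squares(
                _residuals,
                x0=xs,
                bounds=(lb, ub),
                args=(model_id, record, pre),
                x_scale=_x_scale(model_id),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        log.warning(
            "residue %d: model %d failed from every start", record.residue_id, model_id
        )
        return ModelFit(
            record.residue_id, model_id,
            ResidueDynamics(record.residue_id, 1, s2=1.0),
            float("inf"), len(MODEL_PARAMS[model_id]),
        )
    dyn = _dyn_from_params(record.residue_id, model_id, best.x)
    return ModelFit(
        record.residue_id, model_id, dyn, float(2.0 * best.cost),
        len(MODEL_PARAMS[model_id]),
    )


def _f_test_p(chi2_simple: float, chi2_complex: float, dp: int, dof_complex: int) -> float:
    """p-value of the nested F-test; dof_complex = n_obs - p_complex."""
    if dof_complex <= 0:
        raise ValueError("F-test undefined with zero denominator d.o.f.")
    if chi2_simple <= 1e-12:
        # the simple model already fits to numerical precision; any further
        # improvement is round-off, not evidence
        return 1.0
    if chi2_complex <= 0:
        return 0.0
    f = ((chi2_simple - chi2_complex) / dp) / (chi2_complex / dof_complex)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, dp, dof_complex))


def select_model(
    fits: dict[int, ModelFit],
    alpha: float = F_TEST_ALPHA,
    n_obs: int = 3,
) -> ModelFit:
    """Parsimonious step-up selection among the five model-free fits.

    Starting from M1, the two-parameter extensions M2 and M3 are accepted
    only if the nested F-test (dp = 1, denominator d.o.f. = n_obs - 2)
    rejects M1 at ``alpha``; between M2 and M3 the lower chi^2 wins.  The
    three-parameter models M4/M5 leave zero denominator degrees of freedom
    with three observables, so they are accepted only when the current
    candidate is statistically inadequate (chi^2 above the chi-square
    critical value for its residual d.o.f. at ``alpha``) and the best
    three-parameter fit reproduces the triple essentially exactly
    (chi^2 < EXACT_FIT_CHI2); between M4 and M5 the lower chi^2 wins.
    """
    if set(fits) != {1, 2, 3, 4, 5}:
        raise ValueError("all five model fits are required")
    candidate = fits[1]

    two_param = min((fits[2], fits[3]), key=lambda f: f.chi2)
    dof2 = n_obs - 2
    if dof2 > 0:
        p = _f_test_p(fits[1].chi2, two_param.chi2, 1, dof2)
        if p < alpha:
            candidate = two_param

    three_param = min((fits[4], fits[5]), key=lambda f: f.chi2)
    dof_cand = n_obs - candidate.n_params
    if three_param.n_params >= n_obs:
        inadequate = (
            dof_cand > 0
            and candidate.chi2 > stats.chi2.ppf(1.0 - alpha, dof_cand)
        )
        if inadequate and three_param.chi2 < EXACT_FIT_CHI2:
            candidate = three_param
    else:  # more observables than parameters: a regular F-test applies
        p = _f_test_p(
            candidate.chi2, three_param.chi2,
            three_param.n_params - candidate.n_params, n_obs - three_param.n_params,
        )
        if p < alpha:
            candidate = three_param
    return candidate


def run_modelfree(
    records: list[RelaxationRecord],
    tensor: DiffusionTensor,
    orientations: dict[int, NHOrientation],
    field: FieldParameters,
    mc_reps: int = 500,
    seed: int | None = None,
    alpha: float = F_TEST_ALPHA,
) -> pd.DataFrame:
    """Fit and select a model for every residue; Monte-Carlo parameter errors.

    Returns a table with columns residue, model, S2, S2_err, tau_e_ps,
    tau_e_err_ps, Rex, Rex_err, S2f, chi2, flagged.  ``mc_reps`` resamples of
    (R1, R2, NOE) under their Gaussian uncertainties are refitted with the
    selected model; the parameter standard deviations are the reported
    errors.  ``mc_reps=0`` skips error estimation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        if rec.flagged:
            rows.append(_row(rec.residue_id, None, flagged=True))
            continue
        orient = orientations.get(rec.residue_id)
        fits = {m: fit_model(rec, m, tensor, orient, field) for m in MODEL_PARAMS}
        sel = select_model(fits, alpha=alpha)

        errors: dict[str, list[float]] = {p: [] for p in ("s2", "tau_e", "rex")}
        for _ in range(mc_reps):
            pert = RelaxationRecord(
                rec.residue_id,
                rng.normal(rec.r1, rec.r1_err), rec.r1_err,
                rng.normal(rec.r2, rec.r2_err), rec.r2_err,
                rng.normal(rec.noe, rec.noe_err), rec.noe_err,
            )
            refit = fit_model(pert, sel.model_id, tensor, orient, field, x0=_pack(sel))
            errors["s2"].append(refit.dynamics.s2)
            errors["tau_e"].append(refit.dynamics.tau_e)
            errors["rex"].append(refit.dynamics.rex)
        sel.param_errors = {
            k: float(np.std(v)) if v else float("nan") for k, v in errors.items()
        }
        rows.append(_row(rec.residue_id, sel))
    return pd.DataFrame(rows)


def _row(residue_id: int, sel: ModelFit | None, flagged: bool = False) -> dict:
    if sel is None:
        return dict(
            residue=residue_id, model=0, S2=np.nan, S2_err=np.nan,
            tau_e_ps=np.nan, tau_e_err_ps=np.nan, Rex=np.nan, Rex_err=np.nan,
            S2f=np.nan, chi2=np.nan, flagged=True,
        )
    d = sel.dynamics
    err = sel.param_errors
    return dict(
        residue=residue_id,
        model=sel.model_id,
        S2=d.s2,
        S2_err=err.get("s2", np.nan),
        tau_e_ps=d.tau_e * 1e12,
        tau_e_err_ps=err.get("tau_e", np.nan) * 1e12 if err else np.nan,
        Rex=d.rex,
        Rex_err=err.get("rex", np.nan),
        S2f=d.s2f,
        chi2=sel.chi2,
        flagged=flagged,
    )
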