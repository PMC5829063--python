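"""Compensatory-ability sensitivity analysis of the ejection fraction.

Remodeling is formalized as a trajectory through the parameter space
u = {c̃₁, Ca50, p_a, z, PCa, DCa, u_geom, u_fiber}; the compensatory ability
of a parameter is the dimensionless sensitivity

    S[EF, u] = ∂EF/∂u · (u_AB − u_SHAM) / EF(u),

the EF response to a perturbation scaled by the SHAM→AB span of that
parameter.  ∂EF/∂u is a central difference of full limit-cycle simulations
with step ``step_fraction·|span|``; the free parameters are *not* refitted
inside the derivative (S is a partial derivative), but *are* refitted at
each intermediate state of a trajectory scan, where the phenotype targets
are interpolated linearly between the endpoints.

S is signed (e.g. the AB−SHAM span of PCa is negative while EF increases
with PCa, so S[EF, PCa] < 0); compensatory-ability comparisons of the
wall-thickness sweep use the magnitudes |S|.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circulation import LVModel, simulate_cycle, phenotypes_from_loop
from .errors import (
    EquilibriumFailureError,
    ConvergenceFailureError,
    FitNonConvergenceError,
    InvalidParameterError,
    SensitivityFailureError,
)
from .fitting import PhenotypeTarget, FittedParams, fit_model
from .geometry import interpolate_configuration

__all__ = [
    "SensitivityReport",
    "TrajectoryEndpoint",
    "DEFAULT_SPANS",
    "central_sensitivity",
    "ef_sensitivity",
    "trajectory_scan",
    "lvwt_sweep",
]

#: Default SHAM→AB spans for the sweep sensitivities, anchored to the study's
#: measured/fitted endpoint differences: wall thickness grows by ~1 mm, the
#: transient peak falls 1.53 → 0.93 µM, and the fitted calcium sensitivity
#: falls from 1.56 µM to a ~0.85 µM AB average.
DEFAULT_SPANS = {"LVWT": 1.0, "PCa": -0.6, "Ca50": -0.71}

_SENSITIVITY_PARAMS = ("c1_tilde", "Ca50", "p_a", "z", "PCa", "DCa",
                      "u_geom", "u_fiber")


@dataclass(frozen=True)
class SensitivityReport:
    """S[EF, u] values at one evaluation point."""

    point: dict              # coordinates of the evaluation point
    EF: float
    S: dict                  # parameter -> signed sensitivity (None if failed)
    spans: dict
    steps: dict
    diagnostics: dict


@dataclass(frozen=True)
class TrajectoryEndpoint:
    """A fitted heart model anchoring one end of a remodeling trajectory."""

    fit: FittedParams
    target: PhenotypeTarget

    @property
    def model(self) -> LVModel:
        return self.fit.model


def central_sensitivity(ef_at, u: float, span: float,
                        step_fraction: float = 0.01,
                        max_halvings: int = 3) -> float:
    """Central-difference S = [dEF/du]·span/EF(u) for a scalar EF function.

    ``ef_at(x)`` returns EF at parameter value x (raising on failure).  A
    zero span short-circuits to exactly 0.  Failures at a perturbed point
    first halve the step, then fall back to a one-sided difference; only
    when both sides fail is :class:`SensitivityFailureError` raised.
    """
    if span == 0.0:
        return 0.0
    ef0 = ef_at(u)
    if ef0 == 0.0:
        raise SensitivityFailureError("EF at the evaluation point is zero")
    step = step_fraction * abs(span)
    last_exc = None
    for _ in range(max_halvings + 1):
        try:
            ef_p = ef_at(u + step)
        except (EquilibriumFailureError, ConvergenceFailureError) as exc:
            ef_p, last_exc = None, exc
        try:
            ef_m = ef_at(u - step)
        except (EquilibriumFailureError, ConvergenceFailureError) as exc:
            ef_m, last_exc = None, exc
        if ef_p is not None and ef_m is not None:
            deriv = (ef_p - ef_m) / (2.0 * step)
            return deriv * span / ef0
        if ef_p is not None:
            return (ef_p - ef0) / step * span / ef0
        if ef_m is not None:
            return (ef0 - ef_m) / step * span / ef0
        step *= 0.5
    raise SensitivityFailureError(
        f"both perturbed simulations failed (last: {last_exc})")


def _model_at(model: LVModel, name: str, value: float,
              config_pair=None, u_point=None) -> LVModel:
    """Model with one parameter-space coordinate set to ``value``."""
    if name == "c1_tilde":
        return model.updated(material=model.material.with_c1(
            value * model.material.p_ed))
    if name == "Ca50":
        return model.updated(binding=model.binding.with_ca50(value))
    if name == "p_a":
        return model.updated(windkessel=model.windkessel.with_pa(value))
    if name == "z":
        return model.updated(windkessel=replace(model.windkessel, z=value))
    if name == "PCa":
        tr = model.transient
        return model.updated(transient=tr.with_levels(tr.DCa, value))
    if name == "DCa":
        tr = model.transient
        return model.updated(transient=tr.with_levels(value, tr.PCa))
    if name == "LVWT":
        return model.updated(geometry=model.geometry.with_wall_thickness(value))
    if name in ("u_geom", "u_fiber"):
        if config_pair is None:
            raise InvalidParameterError(
                f"{name} perturbations require a (SHAM, AB) configuration pair")
        u = dict(u_point or {"u_geom": 0.0, "u_fiber": 0.0})
        u[name] = value
        geom, fib = interpolate_configuration(
            config_pair[0], config_pair[1], u["u_geom"], u["u_fiber"])
        return model.updated(geometry=geom, fibers=fib)
    raise InvalidParameterError(f"unknown sensitivity parameter {name!r}")


def _current_value(model: LVModel, name: str, u_point=None) -> float:
    if name == "c1_tilde":
        return model.material.c1_tilde
    if name == "Ca50":
        return model.binding.Ca50
    if name == "p_a":
        return model.windkessel.p_a
    if name == "z":
        return model.windkessel.z
    if name == "PCa":
        return model.transient.PCa
    if name == "DCa":
        return model.transient.DCa
    if name == "LVWT":
        return model.geometry.LVWT
    if name in ("u_geom", "u_fiber"):
        return (u_point or {}).get(name, 0.0)
    raise InvalidParameterError(f"unknown sensitivity parameter {name!r}")


def ef_sensitivity(model: LVModel, name: str, span: float,
                   step_fraction: float = 0.01,
                   config_pair=None, u_point=None,
                   ef0: float | None = None) -> float:
    """S[EF, u] for one parameter of a (typically fitted) model.

    ``span`` is the SHAM→AB difference of the parameter; the derivative step
    is ``step_fraction·|span|``.  No refitting happens at the perturbed
    points.  For ``u_geom``/``u_fiber`` supply the (SHAM, AB) configuration
    pair and the current interpolation coordinates.
    """
    if span == 0.0:
        return 0.0
    u0 = _current_value(model, name, u_point)
    cache = {}
    if ef0 is not None:
        cache[u0] = ef0

    def ef_at(x):
        if x in cache:
            return cache[x]
        m = _model_at(model, name, x, config_pair, u_point)
        loop = simulate_cycle(m)
        if loop.stalled:
            raise EquilibriumFailureError("ejection stalled at perturbed point")
        ef = phenotypes_from_loop(loop, m).EF
        cache[x] = ef
        return ef

    return central_sensitivity(ef_at, u0, span, step_fraction)


def evaluate_report(model: LVModel, spans: dict, config_pair=None,
                    u_point=None, step_fraction: float = 0.01) -> SensitivityReport:
    """All-parameter sensitivity report at one model state."""
    loop = simulate_cycle(model)
    ph = phenotypes_from_loop(loop, model)
    s_vals, steps, diags = {}, {}, {}
    for name, span in spans.items():
        steps[name] = step_fraction * abs(span)
        try:
            s_vals[name] = ef_sensitivity(model, name, span, step_fraction,
                                          config_pair, u_point, ef0=ph.EF)
        except SensitivityFailureError as exc:
            s_vals[name] = None
            diags[name] = str(exc)
    return SensitivityReport(
        point=dict(u_point or {}), EF=ph.EF, S=s_vals, spans=dict(spans),
        steps=steps, diagnostics=diags)


def trajectory_scan(
    sham: TrajectoryEndpoint,
    ab: TrajectoryEndpoint,
    grid=(0.0, 0.5, 1.0),
    refit: bool = True,
    step_fraction: float = 0.01,
    params=None,
) -> list:
    """Sensitivity reports along a SHAM→AB remodeling trajectory.

    At each interior coordinate u the geometry/fibers are interpolated, the
    circulation/calcium coordinates are interpolated linearly, the phenotype
    targets are interpolated linearly and the three free parameters refitted;
    the endpoints (u = 0, 1) evaluate the fitted endpoint models directly.
    All eight parameter sensitivities are evaluated with the endpoint spans.
    A refit failure at an interior point is recorded as a missing entry and
    the scan continues.  ``params`` restricts the evaluated sensitivities to
    a subset of the eight coordinates (all by default).
    """
    pair = ((sham.model.geometry, sham.model.fibers),
            (ab.model.geometry, ab.model.fibers))
    spans = {
        "c1_tilde": ab.fit.c1_tilde - sham.fit.c1_tilde,
        "Ca50": ab.fit.Ca50 - sham.fit.Ca50,
        "p_a": ab.fit.p_a - sham.fit.p_a,
        "z": ab.model.windkessel.z - sham.model.windkessel.z,
        "PCa": ab.model.transient.PCa - sham.model.transient.PCa,
        "DCa": ab.model.transient.DCa - sham.model.transient.DCa,
        "u_geom": 1.0,
        "u_fiber": 1.0,
    }
    if params is not None:
        spans = {k: v for k, v in spans.items() if k in params}
    reports = []
    for u in grid:
        u_point = {"u_geom": float(u), "u_fiber": float(u)}
        try:
            if u == 0.0:
                model = sham.model
            elif u == 1.0:
                model = ab.model
            else:
                geom, fib = interpolate_configuration(pair[0], pair[1], u, u)
                lerp = lambda a, b: (1.0 - u) * a + u * b
                tr_sham, tr_ab = sham.model.transient, ab.model.transient
                transient = tr_sham.with_levels(
                    lerp(tr_sham.DCa, tr_ab.DCa), lerp(tr_sham.PCa, tr_ab.PCa))
                template = sham.model.updated(
                    geometry=geom, fibers=fib, transient=transient,
                    windkessel=replace(
                        sham.model.windkessel,
                        z=lerp(sham.model.windkessel.z, ab.model.windkessel.z)),
                )
                target = PhenotypeTarget(
                    LVEDD=lerp(sham.target.LVEDD, ab.target.LVEDD),
                    p_max=lerp(sham.target.p_max, ab.target.p_max),
                    EF=lerp(sham.target.EF, ab.target.EF),
                )
                if refit:
                    guess = tuple(np.exp(
                        (1.0 - u) * np.log([sham.fit.c1_tilde * 1.0,
                                            sham.fit.p_a, sham.fit.Ca50])
                        + u * np.log([ab.fit.c1_tilde * 1.0,
                                      ab.fit.p_a, ab.fit.Ca50])))
                    fitted = fit_model(target, template, guess=guess)
                    model = fitted.model
                else:
                    model = template
            reports.append(evaluate_report(model, spans, pair, u_point,
                                           step_fraction))
        except (FitNonConvergenceError, EquilibriumFailureError,
                ConvergenceFailureError) as exc:
            reports.append(SensitivityReport(
                point=u_point, EF=float("nan"), S={}, spans=dict(spans),
                steps={}, diagnostics={"refit": str(exc)}))
    return reports


def lvwt_sweep(
    target: PhenotypeTarget,
    lvwt_grid=(1.0, 1.5, 2.0, 2.5, 3.0),
    alpha_endo: float = 50.0,
    alpha_epi: float = -50.0,
    spans: dict | None = None,
    step_fraction: float = 0.01,
    template_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Canonical wall-thickness sweep at a fixed phenotype target.

    For each LVWT a canonical semi-ellipsoid (cavity length 10 mm, reference
    diameter 3 mm) is built with the given linear fiber profile, (c1, p_a,
    Ca50) are refitted to the target triple, and the three headline
    sensitivities are evaluated: S[EF, LVWT] with LVWT as the geometric
    coordinate, S[EF, PCa] and S[EF, Ca50].  Unattainable targets are
    recorded as rows of NaNs (the sweep continues).

    Returns a tidy frame with columns (LVWT_mm, c1_kPa, pa_kPa, Ca50_uM,
    S_LVWT, S_PCa, S_Ca50, fit_residual).
    """
    spans = dict(DEFAULT_SPANS if spans is None else spans)
    rows = []
    for lvwt in lvwt_grid:
        template = LVModel.canonical(LVWT=float(lvwt), alpha_endo=alpha_endo,
                                     alpha_epi=alpha_epi,
                                     **(template_kwargs or {}))
        row = {"LVWT_mm": float(lvwt)}
        try:
            fit = fit_model(target, template)
            model = fit.model
            row.update(c1_kPa=fit.c1_tilde * model.material.p_ed,
                       pa_kPa=fit.p_a, Ca50_uM=fit.Ca50,
                       fit_residual=max(abs(v) for v in fit.residuals.values()))
            ef0 = fit.phenotypes.EF
            row["S_LVWT"] = ef_sensitivity(model, "LVWT", spans["LVWT"],
                                           step_fraction, ef0=ef0)
            row["S_PCa"] = ef_sensitivity(model, "PCa", spans["PCa"],
                                          step_fraction, ef0=ef0)
            row["S_Ca50"] = ef_sensitivity(model, "Ca50", spans["Ca50"],
                                           step_fraction, ef0=ef0)
        except (FitNonConvergenceError, EquilibriumFailureError,
                ConvergenceFailureError, SensitivityFailureError) as exc:
            for col in ("c1_kPa", "pa_kPa", "Ca50_uM", "S_LVWT", "S_PCa",
                        "S_Ca50", "fit_residual"):
                row.setdefault(col, float("nan"))
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
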