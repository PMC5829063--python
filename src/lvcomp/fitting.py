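"""Newton fitting of (c̃₁, p_a, [Ca²⁺]₅₀) to a measured phenotype triple.

Each rat (or hypothetical heart) is characterized by three phenotypes —
end-diastolic diameter LVEDD, maximum ejection pressure p_max, and ejection
fraction EF — and the model has three matching free parameters: the passive
stiffness prefactor c̃₁ (which predominantly sets LVEDD), the aortic
valve-opening pressure p_a, and the calcium sensitivity Ca50 (which
predominantly sets EF and, in this tension-capacity-driven reduced model,
carries most of the p_max response as well).  A damped Newton iteration on
the 3→3 map drives the relative phenotype residuals below tolerance.

The iteration runs on the logarithms of the parameters: all three are
positive by definition, and c̃₁ spans many orders of magnitude on canonical
geometries (the exponential passive law pins LVEDD almost logarithmically in
c̃₁), so log-space steps are the natural relative steps.  The Jacobian is a
forward difference with relative log-step 0.05 — wide enough to dominate the
simulator's event-timing noise floor; steps are halved (up to 8 times)
whenever the residual norm would increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circulation import LVModel, SimPhenotypes, phenotypes_from_loop, simulate_cycle
from .errors import (
    ConvergenceFailureError,
    DegenerateFitError,
    EquilibriumFailureError,
    FitNonConvergenceError,
    InvalidParameterError,
)
from .tissue import ReducedLVMechanics

__all__ = ["PhenotypeTarget", "FittedParams", "fit_model", "initial_guess",
           "simulate_phenotypes"]


@dataclass(frozen=True)
class PhenotypeTarget:
    """Measured phenotype triple (mm, kPa, dimensionless)."""

    LVEDD: float
    p_max: float
    EF: float

    def __post_init__(self):
        if min(self.LVEDD, self.p_max, self.EF) <= 0:
            raise InvalidParameterError("phenotypes must be positive")
        if not (0.0 < self.EF < 1.0):
            raise InvalidParameterError("EF must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.LVEDD, self.p_max, self.EF])


@dataclass(frozen=True)
class FittedParams:
    """Converged fit result.

    ``residuals`` are the relative phenotype mismatches of the converged
    model; ``model`` is the fitted :class:`LVModel` and ``phenotypes`` its
    simulated triple.
    """

    c1_tilde: float    # kPa per kPa of filling pressure
    p_a: float         # kPa
    Ca50: float        # µM
    residuals: dict
    iterations: int
    converged: bool
    model: LVModel
    phenotypes: SimPhenotypes


def _apply_params(template: LVModel, c1: float, p_a: float, ca50: float) -> LVModel:
    return template.updated(
        material=template.material.with_c1(c1),
        windkessel=template.windkessel.with_pa(p_a),
        binding=template.binding.with_ca50(ca50),
    )


def simulate_phenotypes(model: LVModel) -> SimPhenotypes:
    """Converged limit-cycle phenotypes of a model (convenience wrapper)."""
    loop = simulate_cycle(model)
    return phenotypes_from_loop(loop, model)


def initial_guess(target: PhenotypeTarget, template: LVModel):
    """Physics-guided starting point for the Newton fit.

    The passive pressure of the tissue model is exactly proportional to c1,
    so the stiffness start is solved directly from the passive inflation that
    reaches the target LVEDD at p_ed.  The aortic-pressure start is a fixed
    fraction of the target p_max (ejection raises LV pressure well above the
    valve-opening point), and the calcium-sensitivity start comes from a
    short simulated activation pre-scan (see :func:`_bracket_ca50`).
    """
    mech = ReducedLVMechanics(template.geometry, template.fibers,
                              template.material.with_c1(1.0))
    from scipy.optimize import brentq

    cache = {"shp": None}

    def diameter_mismatch(V):
        cache["shp"] = mech.solve_shape(V, None, cache["shp"])
        return 2.0 * mech.endo_radius(V, cache["shp"]) - target.LVEDD

    # continuation bracket walk: the equilibrium shape is tracked warm so
    # extreme trial volumes are never evaluated cold
    v_lo = template.geometry.cavity_volume * 1.01
    v_hi = v_lo
    for _ in range(200):
        v_hi *= 1.3
        if diameter_mismatch(v_hi) > 0:
            break
        v_lo = v_hi
    V = brentq(diameter_mismatch, v_lo, v_hi, xtol=1e-9)
    shp = mech.solve_shape(V, None, cache["shp"])
    p_per_c1 = mech.pressure_at(V, shp)
    c1_0 = template.protocol.p_ed / p_per_c1
    p_a0 = 0.45 * target.p_max
    ca50_0 = _bracket_ca50(target, template, c1_0, p_a0)
    return c1_0, p_a0, ca50_0


def _bracket_ca50(target: PhenotypeTarget, template: LVModel,
                  c1_0: float, p_a0: float) -> float:
    """Coarse activation pre-scan for the Ca50 start.

    The EF response to Ca50 shifts strongly with wall thickness (a thick
    wall needs far less calcium sensitivity), so the start is located by
    simulating a short geometric ladder of Ca50 values and log-interpolating
    to the target EF.  Stalled or volume-floored beats are kept only as
    ordering information.
    """
    def ef_probe(ca50):
        model = _apply_params(template, c1_0, p_a0, ca50)
        try:
            loop = simulate_cycle(model)
            return phenotypes_from_loop(loop, model).EF
        except (EquilibriumFailureError, ConvergenceFailureError):
            return None

    probes = []
    for ca50 in (0.3, 0.6, 1.2, 2.4):
        ef = ef_probe(ca50)
        if ef is not None:
            probes.append((ca50, ef))

    def usable(pairs):
        return [(c, e) for c, e in pairs if 0.02 < e < 0.895]

    # at thick walls the EF transition can be so steep that every coarse
    # probe sits on a floor or ceiling: log-bisect between the adjacent
    # above/below pair until a probe lands inside the smooth range
    if not usable(probes):
        above = [c for c, e in probes if e >= target.EF]
        below = [c for c, e in probes if e < target.EF]
        if above and below:
            lo, hi = max(above), min(below)
            for _ in range(4):
                mid = float(np.sqrt(lo * hi))
                ef = ef_probe(mid)
                if ef is not None:
                    probes.append((mid, ef))
                    if 0.02 < ef < 0.895:
                        break
                if ef is None or ef < target.EF:
                    hi = mid
                else:
                    lo = mid
            probes.sort()

    pool = usable(probes)
    # EF decreases with Ca50: bracket the target and log-interpolate
    for (c_lo, e_lo), (c_hi, e_hi) in zip(probes[:-1], probes[1:]):
        if e_lo >= target.EF >= e_hi and e_lo > e_hi:
            w = (e_lo - target.EF) / (e_lo - e_hi)
            return float(np.exp((1 - w) * np.log(c_lo) + w * np.log(c_hi)))
    if pool:
        best = min(pool, key=lambda ce: abs(ce[1] - target.EF))
        return best[0]
    return float(np.clip(template.transient.PCa
                         * (1.15 - target.EF) / 1.15, 0.05, 5.0))


def fit_model(
    target: PhenotypeTarget,
    template: LVModel,
    guess: tuple | None = None,
    tol: float = 1e-2,
    max_iter: int = 12,
    jac_step: float = 0.05,
) -> FittedParams:
    """Fit (c̃₁, p_a, Ca50) so the simulated phenotypes match ``target``.

    Converges when the largest relative phenotype residual is below ``tol``
    (default 1%).  Raises :class:`DegenerateFitError` on a numerically
    singular Jacobian and :class:`FitNonConvergenceError` (carrying the
    residual-norm trace) if the iteration cap is exceeded.
    """
    if guess is None:
        guess = initial_guess(target, template)
    if min(guess) <= 0:
        raise InvalidParameterError("initial guess must be positive")
    x = np.log(np.asarray(guess, dtype=float))
    tgt = target.as_array()

    def residual(xv):
        model = _apply_params(template, *np.exp(xv))
        ph = simulate_phenotypes(model)
        sim = np.array([ph.LVEDD, ph.p_max, ph.EF])
        return (sim - tgt) / tgt, model, ph

    r, model, ph = residual(x)
    trace = [float(np.max(np.abs(r)))]
    iters = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(r)) < tol:
            break
        # forward-difference Jacobian in log-parameter space
        jac = np.empty((3, 3))
        for j in range(3):
            xp = x.copy()
            xp[j] += jac_step
            try:
                rp, _, _ = residual(xp)
            except (EquilibriumFailureError, ConvergenceFailureError):
                xp[j] -= 2.0 * jac_step
                rp, _, _ = residual(xp)
                jac[:, j] = (r - rp) / jac_step
                continue
            jac[:, j] = (rp - r) / jac_step
        if not np.all(np.isfinite(jac)) or np.linalg.cond(jac) > 1e12:
            raise DegenerateFitError(
                f"singular phenotype Jacobian at iteration {it}")
        step = np.linalg.solve(jac, -r)
        # keep individual log-steps bounded; then damp by halving
        step = np.clip(step, -1.5, 1.5)
        accepted = False
        for _ in range(8):
            try:
                r_new, model_new, ph_new = residual(x + step)
            except (EquilibriumFailureError, ConvergenceFailureError):
                step *= 0.5
                continue
            if np.linalg.norm(r_new) < np.linalg.norm(r) or \
                    np.max(np.abs(r_new)) < tol:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            trace.append(float(np.max(np.abs(r))))
            break
        x = x + step
        r, model, ph = r_new, model_new, ph_new
        iters = it
        trace.append(float(np.max(np.abs(r))))

    converged = bool(np.max(np.abs(r)) < tol)
    if not converged:
        raise FitNonConvergenceError(
            f"Newton fit not converged after {iters} iterations "
            f"(max residual {np.max(np.abs(r)):.3g})", residual_trace=trace)
    c1, p_a, ca50 = np.exp(x)
    return FittedParams(
        c1_tilde=float(c1 / template.material.p_ed),
        p_a=float(p_a),
        Ca50=float(ca50),
        residuals={"LVEDD": float(r[0]), "p_max": float(r[1]), "EF": float(r[2])},
        iterations=iters,
        converged=converged,
        model=model,
        phenotypes=ph,
    )
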