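"""Passive tissue law and reduced-kinematics LV equilibrium.

Passive myocardium follows the transverse-isotropic exponential strain-energy
law in fiber–sheet–normal axes,

    W = (c1/2)·(e^Q − 1),
    Q  = c2·E11² + c3·(E22² + E33² + 2·E23²) + 2·c4·(E12² + E13²),

with anisotropy constants c2 = 8.0, c3 = 2.0, c4 = 3.7 and the stiffness
prefactor c1 free.  The (e^Q − 1) convention makes the reference state
stress-free with zero energy.

The organ-level equilibrium replaces a full 3-D finite-element solve with an
axisymmetric reduced-kinematics (Rayleigh–Ritz) family.  The generalized
coordinates are the cavity volume V and two shape coordinates: the
endocardial apex–base extension ratio a (exposed as λ_z) and a transmural
axial-slope coordinate b (an optional twist coordinate exists but is
disabled by default).  Each transmural shell of the reference
semi-ellipsoid maps to a semi-ellipsoidal shell with axial semi-axis
a·L + b·ξ·LVWT and equatorial radius fixed by exact conservation of the
tissue volume enclosed between shells; material points additionally slide
in the meridional angle so that the volume between any two material cones
is conserved, making the map pointwise incompressible (λ_c·λ_m·λ_t = 1).
Strain energy and active virtual work are integrated by midpoint quadrature
over the (layer × segment) grid.  Active tension enters as a fiber-aligned
Cauchy stress T_a·(f⊗f), whose virtual work is ∫ (T_a/λ_f)·δλ_f dV0.

Units: mm, µl (= mm³), kPa, ms; energies are in kPa·µl (µJ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EquilibriumFailureError, InvalidParameterError
from .geometry import FiberField, LVGeometry
from ._kernels import eval_state

__all__ = [
    "MaterialParams",
    "StrainState",
    "DeformationState",
    "strain_energy",
    "passive_stress",
    "ReducedLVMechanics",
    "equilibrium_state",
    "inflate_to_ed",
]

_Q_CLIP = 600.0  # exponent guard: e^600 is finite in float64, e^710 is not


@dataclass(frozen=True)
class MaterialParams:
    """Transverse-isotropic passive-law constants (kPa for c1)."""

    c1: float = 0.68
    c2: float = 8.0
    c3: float = 2.0
    c4: float = 3.7
    p_ed: float = 1.0   # assumed end-diastolic pressure, kPa

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3, self.c4, self.p_ed) <= 0:
            raise InvalidParameterError("material constants must be positive")
        if not self.c2 > self.c3:
            raise InvalidParameterError("fiber-dominant anisotropy requires c2 > c3")

    @property
    def c1_tilde(self) -> float:
        """Effective stiffness c̃₁ = c1/p_ed (kPa per kPa of filling pressure)."""
        return self.c1 / self.p_ed

    def with_c1(self, c1: float) -> "MaterialParams":
        return MaterialParams(c1=c1, c2=self.c2, c3=self.c3, c4=self.c4,
                              p_ed=self.p_ed)


@dataclass(frozen=True)
class StrainState:
    """Lagrangian strain components in fiber–sheet–normal axes."""

    E11: float = 0.0
    E22: float = 0.0
    E33: float = 0.0
    E12: float = 0.0
    E13: float = 0.0
    E23: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.E11, self.E22, self.E33,
                         self.E12, self.E13, self.E23])


@dataclass(frozen=True)
class DeformationState:
    """Equilibrium state of the reduced kinematic family."""

    cavity_volume: float        # µl
    lambda_z: float             # apex–base extension ratio (endocardial)
    pressure: float             # conjugate cavity pressure, kPa
    axial_slope: float = 1.0    # transmural axial-slope shape coordinate
    twist_rate: float = 0.0     # deg/mm (disabled by default)

    @property
    def shape(self) -> tuple:
        return (self.lambda_z, self.axial_slope)

    @property
    def V(self) -> float:
        return self.cavity_volume


def _exponent(E11, E22, E33, E12, E13, E23, m: MaterialParams):
    q = (m.c2 * E11**2
         + m.c3 * (E22**2 + E33**2 + 2.0 * E23**2)
         + 2.0 * m.c4 * (E12**2 + E13**2))
    return np.minimum(q, _Q_CLIP)


def strain_energy(E: StrainState, m: MaterialParams) -> float:
    """W(E) = (c1/2)(e^Q − 1) ≥ 0, zero at the reference state."""
    q = _exponent(E.E11, E.E22, E.E33, E.E12, E.E13, E.E23, m)
    return float(0.5 * m.c1 * (np.exp(q) - 1.0))


def passive_stress(E: StrainState, m: MaterialParams) -> StrainState:
    """Second Piola–Kirchhoff stress S_ij = ∂W/∂E_ij (component-wise).

    The six strain components are treated as the independent arguments of W,
    matching a finite-difference derivative of :func:`strain_energy` in each.
    """
    q = _exponent(E.E11, E.E22, E.E33, E.E12, E.E13, E.E23, m)
    pref = 0.5 * m.c1 * np.exp(q)
    return StrainState(
        E11=float(pref * 2.0 * m.c2 * E.E11),
        E22=float(pref * 2.0 * m.c3 * E.E22),
        E33=float(pref * 2.0 * m.c3 * E.E33),
        E12=float(pref * 4.0 * m.c4 * E.E12),
        E13=float(pref * 4.0 * m.c4 * E.E13),
        E23=float(pref * 4.0 * m.c3 * E.E23),
    )


class ReducedLVMechanics:
    """Axisymmetric reduced-kinematics equilibrium of a semi-ellipsoidal LV."""

    #: default solver settings
    MAX_ITER = 100
    GRAD_TOL = 1e-8           # residual tolerance, kPa·µl per unit coordinate
    BRACKET_A = (0.45, 3.2)    # endocardial apex-base extension ratio
    BRACKET_B = (0.02, 3.2)    # transmural axial-slope coordinate (the wall
                               # thins strongly along the axis at large
                               # inflation, so b can be far below one)

    def __init__(self, geom: LVGeometry, fibers: FiberField,
                 material: MaterialParams, twist: bool = False):
        self.geom = geom
        self.fibers = fibers
        self.material = material
        self.twist = twist  # present but inert: torsion showed no trend
        xi, phi, dV0 = geom.grid()
        self.xi = xi
        self.phi = phi
        self.dV0 = dV0
        self.l0 = geom.cavity_length + xi * geom.LVWT
        self.r0 = geom.cavity_radius + xi * geom.LVWT
        self.v0_enc = 2.0 / 3.0 * np.pi * self.l0 * self.r0**2
        self.V0 = geom.cavity_volume
        alpha = fibers.alpha_rad(xi)[:, None]
        self.cos2a = np.cos(alpha) ** 2
        self.sin2a = np.sin(alpha) ** 2
        self.sincosa = np.sin(alpha) * np.cos(alpha)
        self.sin_phi = np.sin(phi)[None, :]
        self.cos_phi = np.cos(phi)[None, :]
        # reference meridional metric per point
        self.ds0 = np.sqrt((self.r0[:, None] * self.cos_phi) ** 2
                           + (self.l0[:, None] * self.sin_phi) ** 2)
        # reference shell-slope coefficients for the meridional volume map:
        # beta1 = l·r·r', beta2 = l'·r²; the cumulative apex-to-phi enclosed
        # shell volume is proportional to P(c) = (b1−b2)c³ − 3·b1·c + b2+2·b1
        # with c = cos(phi), and their sum A = b2 + 2·b1 is conserved per
        # shell by incompressibility.
        w_t = geom.LVWT
        self._b1_ref = self.l0 * self.r0 * w_t
        self._b2_ref = w_t * self.r0**2
        c = self.cos_phi
        self._P_ref = ((self._b1_ref - self._b2_ref)[:, None] * c**3
                       - 3.0 * self._b1_ref[:, None] * c
                       + (self._b2_ref + 2.0 * self._b1_ref)[:, None])
        self._dPref_dc = (3.0 * (self._b1_ref - self._b2_ref)[:, None] * c**2
                          - 3.0 * self._b1_ref[:, None])
        self._cache_key = None
        self._cache_val = None
        self._cpr_warm = None   # warm start for the meridional-remap solve

    # -- core state evaluation ------------------------------------------------
    def _eval(self, V: float, a: float, b: float) -> dict:
        """Energy, analytic gradients and fiber-stretch sensitivities.

        Kinematic family: each reference shell maps to a semi-ellipsoidal
        shell whose equatorial radius is fixed by exact conservation of the
        enclosed tissue volume, and whose axial semi-axis is
        l(ξ) = a·L + b·ξ·LVWT — ``a`` is the apex–base extension ratio of
        the endocardial shell and ``b`` a transmural axial-slope coordinate
        (a = b = 1 at the reference).  Material points slide in the
        meridional angle so the volume between any two material cones is
        conserved: the map is pointwise incompressible (λ_c·λ_m·λ_t = 1 with
        λ_t the true thickness stretch), and for a spherical reference the
        family contains the exact incompressible-inflation field in the
        thin-wall limit.  The remapped angle solves a monotone cubic per
        material point; its derivatives follow by implicit differentiation,
        giving the full analytic energy gradient in one vectorized pass.
        Results are memoized for the most recent state.
        """
        key = (V, a, b)
        if self._cache_key == key:
            return self._cache_val
        if V <= 0 or a <= 0 or b <= 0:
            raise InvalidParameterError("V, a and b must be positive")
        m = self.material
        if self._cpr_warm is None:
            self._cpr_warm = np.broadcast_to(
                self.cos_phi, self._P_ref.shape).copy()
        ok, U, dU3, lam_f, dlf, lam_c, lam_m, lam_t, cpr = eval_state(
            V, a, b,
            self.xi, self.l0, self.r0, self.v0_enc, self.V0,
            self.geom.cavity_length, self.geom.LVWT,
            self._b1_ref, self._b2_ref, self._P_ref, self._dPref_dc,
            self.sin_phi[0], self.ds0, self.dV0,
            self.cos2a[:, 0], self.sin2a[:, 0], self.sincosa[:, 0],
            m.c1, m.c2, m.c3, m.c4, _Q_CLIP,
            self._cpr_warm,
        )
        if not ok:
            raise EquilibriumFailureError(
                "shell inversion: deformed radius not increasing transmurally")
        self._cpr_warm = cpr
        out = {
            "U": float(U),
            "dU_dV": float(dU3[0]), "dU_da": float(dU3[1]),
            "dU_db": float(dU3[2]),
            "lam_f": lam_f,
            "dlf_dV": dlf[0], "dlf_da": dlf[1], "dlf_db": dlf[2],
            "stretches": (lam_c, lam_m, lam_t),
        }
        self._cache_key = key
        self._cache_val = out
        return out

    # -- kinematics -----------------------------------------------------------
    def stretches(self, V: float, a: float, b: float | None = None):
        """Principal stretches (λ_c, λ_m, λ_t) on the grid for a state."""
        if b is None:
            b = a
        return self._eval(V, a, b)["stretches"]

    def fiber_stretch(self, V: float, shape) -> np.ndarray:
        a, b = shape
        return self._eval(V, a, b)["lam_f"]

    def endo_radius(self, V: float, a) -> float:
        """Deformed endocardial equatorial radius (mm).

        Only the endocardial axial stretch matters; ``a`` may be the scalar
        coordinate or the (a, b) shape tuple.
        """
        if np.ndim(a) > 0:
            a = a[0]
        return float(np.sqrt(3.0 * V / (2.0 * np.pi * a
                                        * self.geom.cavity_length)))

    def deformed_wall_volume(self, V: float) -> float:
        """Wall volume of the deformed state (conserved by construction)."""
        return self.geom.wall_volume

    # -- energies -------------------------------------------------------------
    def passive_energy(self, V: float, shape) -> float:
        """Stored passive strain energy over the wall (kPa·µl)."""
        a, b = _as_shape(shape)
        return self._eval(V, a, b)["U"]

    # -- generalized forces ---------------------------------------------------
    @staticmethod
    def _ta_field(Ta, lam_f):
        """Active fiber tension on the grid.

        ``Ta`` may be a fixed array, or a callable of the fiber-stretch field
        — the callable form lets the solver see the active length dependence
        h(λ), whose negative slope under shortening is what stabilizes the
        equilibrium at high activation.
        """
        return Ta(lam_f) if callable(Ta) else Ta

    def shape_residual(self, V: float, shape, Ta=None) -> np.ndarray:
        """Generalized active+passive force on the shape coordinates (a, b);
        zero at equilibrium."""
        a, b = _as_shape(shape)
        st = self._eval(V, a, b)
        g = np.array([st["dU_da"], st["dU_db"]])
        if Ta is not None:
            lf = st["lam_f"]
            ta = self._ta_field(Ta, lf)
            g[0] += float(np.sum(ta / lf * st["dlf_da"] * self.dV0))
            g[1] += float(np.sum(ta / lf * st["dlf_db"] * self.dV0))
        return g

    def pressure_at(self, V: float, shape, Ta=None) -> float:
        """Cavity pressure p = ∂(total energy)/∂V at the given state (kPa)."""
        a, b = _as_shape(shape)
        st = self._eval(V, a, b)
        p = st["dU_dV"]
        if Ta is not None:
            lf = st["lam_f"]
            ta = self._ta_field(Ta, lf)
            p += float(np.sum(ta / lf * st["dlf_dV"] * self.dV0))
        return p

    def _total_potential(self, V: float, shape, Ta=None) -> float:
        """Passive energy plus an activation pseudo-potential.

        For a fixed tension field Σ T_a·ln(λ_f)·dV0 has exactly the active
        virtual work as its shape-gradient; for a length-dependent field the
        same expression (tension evaluated at the state) still ranks
        coexisting equilibria for the cold-start scan.
        """
        a, b = _as_shape(shape)
        st = self._eval(V, a, b)
        u = st["U"]
        if Ta is not None:
            lf = st["lam_f"]
            u += float(np.sum(self._ta_field(Ta, lf) * np.log(lf) * self.dV0))
        return u

    def _scan_shape(self, V: float, Ta=None):
        """Coarse global search over (a, b), then Newton polish."""
        best, best_u = None, np.inf
        for a in np.geomspace(*self.BRACKET_A, 15):
            for b in np.geomspace(*self.BRACKET_B, 13):
                try:
                    u = self._total_potential(V, (a, b), Ta)
                except EquilibriumFailureError:
                    continue
                if u < best_u:
                    best, best_u = (a, b), u
        if best is None:
            raise EquilibriumFailureError(
                f"no feasible shape for V={V:.4g}")
        sol = self._newton_shape(V, best, Ta)
        if sol is None:
            sol = self._minimize_shape(V, best, Ta)
        if sol is None:
            raise EquilibriumFailureError(
                f"shape equilibrium did not converge at V={V:.4g}")
        return sol

    def _minimize_shape(self, V: float, shape0, Ta=None):
        """Bounded quasi-Newton minimization of the total potential;
        robust fallback when the damped Newton stalls.  Returns the Newton-
        polished minimizer, or None."""
        from scipy.optimize import minimize

        big = 1e280

        def fun(x):
            try:
                st = self._eval(V, x[0], x[1])
            except EquilibriumFailureError:
                return big, np.zeros(2)
            u = st["U"]
            g = np.array([st["dU_da"], st["dU_db"]])
            if Ta is not None:
                lf = st["lam_f"]
                ta = self._ta_field(Ta, lf)
                u += float(np.sum(ta * np.log(lf) * self.dV0))
                g[0] += float(np.sum(ta / lf * st["dlf_da"] * self.dV0))
                g[1] += float(np.sum(ta / lf * st["dlf_db"] * self.dV0))
            return u, g

        res = minimize(fun, np.asarray(_as_shape(shape0)), jac=True,
                       method="L-BFGS-B",
                       bounds=[self.BRACKET_A, self.BRACKET_B],
                       options={"maxiter": 300, "ftol": 1e-18,
                                "gtol": 1e-12})
        if not np.all(np.isfinite(res.x)):
            return None
        sol = self._newton_shape(V, tuple(res.x), Ta)
        if sol is not None:
            return sol
        # accept the bounded minimizer if its gradient is small or a bound
        # is active (constrained equilibrium)
        g = self.shape_residual(V, tuple(res.x), Ta)
        scale = max(1.0, 1e-3 * abs(self._total_potential(V, res.x, Ta)))
        at_bound = (np.isclose(res.x[0], self.BRACKET_A).any()
                    or np.isclose(res.x[1], self.BRACKET_B).any())
        if np.max(np.abs(g)) < 1e4 * self.GRAD_TOL * scale or at_bound:
            return (float(res.x[0]), float(res.x[1]))
        return None

    def _newton_shape(self, V: float, shape0, Ta=None):
        """Damped Newton on the 2-D shape gradient; None on failure."""
        x = np.array(_as_shape(shape0), dtype=float)
        lob = np.array([self.BRACKET_A[0], self.BRACKET_B[0]])
        hib = np.array([self.BRACKET_A[1], self.BRACKET_B[1]])
        x = np.clip(x, lob, hib)
        try:
            g = self.shape_residual(V, x, Ta)
        except EquilibriumFailureError:
            return None
        scale = max(1.0, 1e-3 * abs(self._total_potential(V, x, Ta)))
        tol = self.GRAD_TOL * scale
        h = 1e-7
        jac = None   # refreshed on demand: a frozen Jacobian usually serves
        fresh = False

        def refresh():
            j = np.empty((2, 2))
            for k in range(2):
                xp = x.copy()
                xp[k] += h
                j[:, k] = (self.shape_residual(V, xp, Ta) - g) / h
            return j

        for _ in range(self.MAX_ITER):
            gn = np.max(np.abs(g))
            if gn < tol:
                return (float(x[0]), float(x[1]))
            if jac is None:
                try:
                    jac = refresh()
                except EquilibriumFailureError:
                    return None
                fresh = True
                # resolve the shape coordinates to ~1e-6: tighter residuals
                # only chase noise against the local stiffness
                tol = max(tol, 1e-6 * np.max(np.abs(jac)))
                if gn < tol:
                    return (float(x[0]), float(x[1]))
            try:
                step = np.linalg.solve(jac, -g)
            except np.linalg.LinAlgError:
                return None
            nrm = np.max(np.abs(step))
            if nrm > 0.25:
                step *= 0.25 / nrm
            accepted = False
            for _ in range(6):
                xn = np.clip(x + step, lob, hib)
                try:
                    g_new = self.shape_residual(V, xn, Ta)
                except EquilibriumFailureError:
                    step *= 0.5
                    continue
                if np.max(np.abs(g_new)) < gn or np.max(np.abs(g_new)) < tol:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                if fresh:
                    return None
                jac = None   # stale Jacobian: recompute and retry
                continue
            if np.max(np.abs(xn - x)) < 1e-12 * np.max(np.abs(x)):
                return (float(xn[0]), float(xn[1]))
            # refresh the Jacobian whenever progress is less than quadratic
            if np.max(np.abs(g_new)) > 0.2 * gn:
                jac = None
            x, g = xn, g_new
            fresh = False
        return None

    def solve_shape(self, V: float, Ta=None, shape0=None):
        """Equilibrium shape coordinates (a, b) at fixed cavity volume.

        With a warm start a damped Newton iteration tracks the current
        solution branch; cold starts — or a failed Newton — fall back to a
        coarse global scan that selects the minimum-potential equilibrium.
        """
        if shape0 is not None:
            sol = self._newton_shape(V, shape0, Ta)
            if sol is not None:
                return sol
        return self._scan_shape(V, Ta)

    def solve_volume(self, p_target: float, Ta=None, V0_guess=None,
                     shape0=None):
        """Cavity volume at imposed pressure (nested over the shape solve).

        Returns (V, (a, b)).  With a warm start a damped Newton iteration on
        V is tried first; cold starts (and Newton failures) fall back to a
        bracket walk with Brent's method on the monotone branch.
        """
        if shape0 is not None and V0_guess is not None:
            sol = self._solve_volume_newton(p_target, Ta, V0_guess, shape0)
            if sol is not None:
                return sol
        return self._solve_volume_bracket(p_target, Ta, V0_guess, shape0)

    def _solve_volume_newton(self, p_target, Ta, V0_guess, shape0):
        V, shp = float(V0_guess), shape0
        tol = 1e-8 * max(1.0, abs(p_target))
        err_prev = None
        for _ in range(40):
            try:
                shp = self.solve_shape(V, Ta, shp)
            except EquilibriumFailureError:
                return None
            err = self.pressure_at(V, shp, Ta) - p_target
            if abs(err) < tol:
                return V, shp
            if err_prev is not None and abs(err) > 0.9 * abs(err_prev):
                return None   # not contracting; use the bracket solver
            dV = max(1e-7 * V, 1e-9)
            try:
                shp2 = self.solve_shape(V + dV, Ta, shp)
            except EquilibriumFailureError:
                return None
            dpdV = (self.pressure_at(V + dV, shp2, Ta)
                    - (err + p_target)) / dV
            if not np.isfinite(dpdV) or dpdV <= 0.0:
                return None
            step = float(np.clip(-err / dpdV, -0.25 * V, 0.5 * V))
            if V + step <= 0.02 * self.V0:
                return None
            V += step
            err_prev = err
        return None

    def _solve_volume_bracket(self, p_target: float, Ta=None, V0_guess=None,
                              shape0=None):
        cache = {"shp": shape0}

        def p_of_v(V):
            cache["shp"] = self.solve_shape(V, Ta, cache["shp"])
            return self.pressure_at(V, cache["shp"], Ta)

        V_ref = self.V0
        if p_target <= 0 and Ta is None:
            shp = self.solve_shape(V_ref, None, shape0)
            return V_ref, shp
        V_min = 0.02 * V_ref
        lo = max(V0_guess if V0_guess is not None else V_ref, V_min)
        p_lo = p_of_v(lo)
        if p_lo == p_target:
            return float(lo), cache["shp"]
        if p_lo < p_target:
            hi = lo
            for _ in range(400):
                hi *= 1.15
                if p_of_v(hi) >= p_target:
                    break
                lo = hi
            else:
                raise EquilibriumFailureError(
                    f"could not bracket V upward for p={p_target} kPa")
        else:
            hi = lo
            for _ in range(400):
                lo = max(lo / 1.15, V_min)
                if p_of_v(lo) <= p_target:
                    break
                hi = lo
                if lo <= V_min:
                    raise EquilibriumFailureError(
                        f"could not bracket V downward for p={p_target} kPa")
            else:
                raise EquilibriumFailureError(
                    f"could not bracket V downward for p={p_target} kPa")
        # manual bisection: p_of_v is warm-started (slightly path-dependent),
        # which Brent's method does not tolerate
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if hi - lo < 1e-9 * V_ref:
                break
            if p_of_v(mid) < p_target:
                lo = mid
            else:
                hi = mid
        V = 0.5 * (lo + hi)
        shp = self.solve_shape(V, Ta, cache["shp"])
        return float(V), shp


def _as_shape(shape):
    """Normalize a shape argument to the (a, b) coordinate pair."""
    if np.ndim(shape) == 0:
        return float(shape), float(shape)
    a, b = shape
    return float(a), float(b)


def equilibrium_state(
    geom: LVGeometry,
    fibers: FiberField,
    material: MaterialParams,
    activation=None,
    volume: float | None = None,
    pressure: float | None = None,
    twist: bool = False,
) -> DeformationState:
    """Solve reduced-kinematics equilibrium at an imposed volume or pressure.

    ``activation`` is a per-point active fiber tension array (kPa) on the
    (n_layers × n_segments) grid, or None for the passive problem.  Exactly
    one of ``volume`` / ``pressure`` must be given; the conjugate quantity is
    returned on the :class:`DeformationState`.
    """
    if (volume is None) == (pressure is None):
        raise InvalidParameterError("specify exactly one of volume or pressure")
    if activation is not None:
        activation = np.asarray(activation, dtype=float)
        if activation.shape != (geom.n_layers, geom.n_segments):
            raise InvalidParameterError("activation grid does not match geometry")
        if np.any(activation < 0):
            raise InvalidParameterError("activation must be non-negative")
    mech = ReducedLVMechanics(geom, fibers, material, twist=twist)
    if volume is not None:
        shp = mech.solve_shape(volume, activation)
        p = mech.pressure_at(volume, shp, activation)
        return DeformationState(cavity_volume=float(volume), lambda_z=shp[0],
                                axial_slope=shp[1], pressure=float(p))
    V, shp = mech.solve_volume(pressure, activation)
    return DeformationState(cavity_volume=V, lambda_z=shp[0],
                            axial_slope=shp[1], pressure=float(pressure))


def inflate_to_ed(
    geom: LVGeometry,
    fibers: FiberField,
    material: MaterialParams,
    p_ed: float = 1.0,
) -> tuple[DeformationState, float]:
    """Passive inflation to the end-diastolic pressure.

    Returns the end-diastolic :class:`DeformationState` and the mean
    end-diastolic inner diameter LVEDD (mm).  Since the passive pressure is
    strictly proportional to c1, doubling c1 and p_ed together leaves this
    state unchanged.
    """
    mech = ReducedLVMechanics(geom, fibers, material)
    if p_ed == 0.0:
        shp = mech.solve_shape(geom.cavity_volume, None)
        state = DeformationState(cavity_volume=geom.cavity_volume,
                                 lambda_z=shp[0], axial_slope=shp[1],
                                 pressure=0.0)
    else:
        V, shp = mech.solve_volume(p_ed, None)
        state = DeformationState(cavity_volume=V, lambda_z=shp[0],
                                 axial_slope=shp[1], pressure=p_ed)
    lvedd = 2.0 * mech.endo_radius(state.cavity_volume, state.lambda_z)
    return state, lvedd
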