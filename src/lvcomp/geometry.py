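"""Parametric left-ventricular geometry and fiber architecture.

The LV is idealized as a thick-walled semi-ellipsoid of revolution: the
endocardial surface has axial semi-axis ``cavity_length`` and equatorial
semi-axis ``cavity_radius``; the epicardial surface offsets both semi-axes by
the wall thickness ``LVWT``.  Material points are laid out on a
(transmural ξ × meridional φ) grid, with ξ ∈ [0, 1] from endo- to epicardium
and φ ∈ [0, π/2] from apex to base; the base plane is flat and perpendicular
to the apex–base axis.

Myofibers lie in the local wall-tangent plane at an elevation angle α from the
circumferential direction, varying linearly across the wall (α_endo at ξ=0 to
α_epi at ξ=1).  The imbrication angle β is fixed at zero, as observed.

Interfaces use degrees and mm; angles are converted to radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ShapeMismatchError

__all__ = [
    "LVGeometry",
    "FiberField",
    "build_semi_ellipsoid",
    "assign_fibers",
    "interpolate_configuration",
    "half_ellipsoid_volume",
]


def half_ellipsoid_volume(length: float, radius: float) -> float:
    """Volume of a half ellipsoid of revolution: (2/3)·π·length·radius²."""
    return 2.0 / 3.0 * np.pi * length * radius**2


@dataclass(frozen=True)
class LVGeometry:
    """Thick-walled semi-ellipsoidal LV reference geometry (mm)."""

    cavity_length: float
    cavity_radius: float
    LVWT: float
    n_layers: int = 4
    n_segments: int = 24

    def __post_init__(self):
        if min(self.cavity_length, self.cavity_radius, self.LVWT) <= 0:
            raise InvalidParameterError("all geometric dimensions must be positive")
        if self.n_layers < 2 or self.n_segments < 4:
            raise InvalidParameterError("need n_layers >= 2 and n_segments >= 4")

    # -- closed-form volumes (µl == mm³) -------------------------------------
    @property
    def cavity_volume(self) -> float:
        return half_ellipsoid_volume(self.cavity_length, self.cavity_radius)

    @property
    def outer_volume(self) -> float:
        return half_ellipsoid_volume(self.cavity_length + self.LVWT,
                                     self.cavity_radius + self.LVWT)

    @property
    def wall_volume(self) -> float:
        return self.outer_volume - self.cavity_volume

    # -- discretization -------------------------------------------------------
    def grid(self):
        """Midpoint grid (ξ_i, φ_j) and reference volume weights dV0_ij.

        Returns (xi[n_layers], phi[n_segments], dV0[n_layers, n_segments])
        where dV0 sums to the wall volume as the grid refines (midpoint
        quadrature of the exact ellipsoidal volume element).
        """
        nl, ns = self.n_layers, self.n_segments
        dxi = 1.0 / nl
        dphi = (np.pi / 2.0) / ns
        xi = (np.arange(nl) + 0.5) * dxi
        phi = (np.arange(ns) + 0.5) * dphi
        l0 = self.cavity_length + xi * self.LVWT       # axial semi-axis per layer
        r0 = self.cavity_radius + xi * self.LVWT       # equatorial semi-axis
        dl, dr = self.LVWT, self.LVWT                  # d(l0)/dξ, d(r0)/dξ
        s, c = np.sin(phi), np.cos(phi)
        # |det ∂(x,y,z)/∂(ξ,φ,θ)| integrated over θ (axisymmetric): 2π·sinφ·
        # (l0'·r0²·cos²φ + l0·r0·r0'·sin²φ)
        jac = 2.0 * np.pi * s[None, :] * (
            dl * (r0**2)[:, None] * (c**2)[None, :]
            + (l0 * r0)[:, None] * dr * (s**2)[None, :]
        )
        dV0 = jac * dxi * dphi
        return xi, phi, dV0

    def wall_volume_discretized(self) -> float:
        """Wall volume by midpoint quadrature (converges to wall_volume)."""
        return float(self.grid()[2].sum())

    def with_wall_thickness(self, LVWT: float) -> "LVGeometry":
        return replace(self, LVWT=LVWT)


@dataclass(frozen=True)
class FiberField:
    """Transmural fiber elevation-angle field (degrees at the interface).

    alpha(ξ) varies linearly from ``alpha_endo`` at the endocardium (ξ=0) to
    ``alpha_epi`` at the epicardium (ξ=1); the imbrication angle β is zero.
    """

    alpha_endo: float
    alpha_epi: float
    beta: float = 0.0

    def __post_init__(self):
        for name, a in (("alpha_endo", self.alpha_endo),
                        ("alpha_epi", self.alpha_epi)):
            if not (-90.0 < a < 90.0):
                raise InvalidParameterError(f"{name} must lie in (-90, 90) deg")
        if self.beta != 0.0:
            raise InvalidParameterError("imbrication angle beta is fixed at 0")

    def alpha(self, xi) -> np.ndarray:
        """Elevation angle in degrees at transmural coordinate ξ ∈ [0, 1]."""
        xi = np.asarray(xi, dtype=float)
        return self.alpha_endo + xi * (self.alpha_epi - self.alpha_endo)

    def alpha_rad(self, xi) -> np.ndarray:
        return np.deg2rad(self.alpha(xi))


def build_semi_ellipsoid(
    cavity_length: float,
    reference_diameter: float,
    LVWT: float,
    n_layers: int = 4,
    n_segments: int = 24,
) -> LVGeometry:
    """Build the canonical semi-ellipsoidal LV reference geometry.

    ``reference_diameter`` is the endocardial equatorial diameter (mm); the
    canonical configuration of the wall-thickness sweep uses a cavity length
    of 10 mm and a reference diameter of 3 mm.
    """
    if reference_diameter <= 0:
        raise InvalidParameterError("reference_diameter must be positive")
    return LVGeometry(
        cavity_length=cavity_length,
        cavity_radius=reference_diameter / 2.0,
        LVWT=LVWT,
        n_layers=n_layers,
        n_segments=n_segments,
    )


def assign_fibers(geom: LVGeometry, alpha_endo: float, alpha_epi: float) -> FiberField:
    """Linear transmural fiber elevation-angle profile for ``geom``."""
    del geom  # the profile depends only on the normalized wall coordinate
    return FiberField(alpha_endo=alpha_endo, alpha_epi=alpha_epi)


def interpolate_configuration(
    a: tuple[LVGeometry, FiberField],
    b: tuple[LVGeometry, FiberField],
    u_geom: float,
    u_fiber: float,
) -> tuple[LVGeometry, FiberField]:
    """Interpolate between two (geometry, fibers) configurations.

    Every geometric scalar is blended with weight ``u_geom`` and every fiber
    angle with ``u_fiber``; u = 0 reproduces configuration ``a`` and u = 1
    configuration ``b``.  The weights act independently, mirroring the
    generalized remodeling coordinates u_geom and u_fiber.  Values slightly
    outside [0, 1] are permitted (the family is affine), which the sensitivity
    module uses for central differences at the endpoints.
    """
    geom_a, fib_a = a
    geom_b, fib_b = b
    if (geom_a.n_layers, geom_a.n_segments) != (geom_b.n_layers, geom_b.n_segments):
        raise ShapeMismatchError("configurations must share discretization counts")

    def mix(x, y, w):
        return (1.0 - w) * x + w * y

    geom = LVGeometry(
        cavity_length=mix(geom_a.cavity_length, geom_b.cavity_length, u_geom),
        cavity_radius=mix(geom_a.cavity_radius, geom_b.cavity_radius, u_geom),
        LVWT=mix(geom_a.LVWT, geom_b.LVWT, u_geom),
        n_layers=geom_a.n_layers,
        n_segments=geom_a.n_segments,
    )
    fib = FiberField(
        alpha_endo=mix(fib_a.alpha_endo, fib_b.alpha_endo, u_fiber),
        alpha_epi=mix(fib_a.alpha_epi, fib_b.alpha_epi, u_fiber),
    )
    return geom, fib


def material_point_table(geom: LVGeometry, fibers: FiberField) -> pd.DataFrame:
    """Tidy table of the material-point grid (ξ, φ, α, volume weight)."""
    xi, phi, dV0 = geom.grid()
    xi_g, phi_g = np.meshgrid(xi, phi, indexing="ij")
    return pd.DataFrame({
        "xi": xi_g.ravel(),
        "phi_rad": phi_g.ravel(),
        "alpha_deg": fibers.alpha(xi_g.ravel()),
        "dV0_ul": dV0.ravel(),
    })
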