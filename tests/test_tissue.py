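"""Passive law, stress derivatives and reduced-kinematics equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvcomp.errors import InvalidParameterError
from lvcomp.geometry import FiberField, assign_fibers, build_semi_ellipsoid
from lvcomp.tissue import (
    MaterialParams,
    ReducedLVMechanics,
    StrainState,
    equilibrium_state,
    inflate_to_ed,
    passive_stress,
    strain_energy,
)

M = MaterialParams(c1=0.68)


class TestStrainEnergy:
    def test_reference_state_has_zero_energy(self):
        assert strain_energy(StrainState(), M) == 0.0

    def test_uniaxial_fiber_strain_closed_form(self):
        # E11 = 0.1 only: W = (0.68/2)·(e^{8·0.01} − 1)
        w = strain_energy(StrainState(E11=0.1), M)
        assert w == pytest.approx(0.34 * (np.exp(0.08) - 1.0), rel=1e-12)

    def test_fiber_direction_stiffer_than_transverse(self):
        s = 0.12
        assert strain_energy(StrainState(E11=s), M) > \
            strain_energy(StrainState(E22=s), M)

    def test_anisotropy_ordering_requires_c2_gt_c3(self):
        with pytest.raises(InvalidParameterError):
            MaterialParams(c1=0.68, c2=2.0, c3=8.0)


class TestPassiveStress:
    def test_reference_state_stress_free(self):
        s = passive_stress(StrainState(), M)
        assert np.all(s.as_array() == 0.0)

    def test_uniaxial_hand_derivative(self):
        e = StrainState(E11=0.1)
        s = passive_stress(e, M)
        expected = M.c1 * M.c2 * 0.1 * np.exp(M.c2 * 0.01)
        assert s.E11 == pytest.approx(expected, rel=1e-12)
        assert s.E22 == 0.0 and s.E12 == 0.0

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_matches_finite_difference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        comps = rng.uniform(-0.2, 0.2, 6)
        e = StrainState(*comps)
        s = passive_stress(e, M).as_array()
        h = 1e-7
        fd = np.empty(6)
        for i in range(6):
            up = comps.copy()
            dn = comps.copy()
            up[i] += h
            dn[i] -= h
            fd[i] = (strain_energy(StrainState(*up), M)
                     - strain_energy(StrainState(*dn), M)) / (2 * h)
        np.testing.assert_allclose(s, fd, rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="module")
def soft_mech():
    """Mechanics with O(1) c1 at modest inflation (no extreme exponents)."""
    geom = build_semi_ellipsoid(10.0, 6.0, 1.5)
    fibers = assign_fibers(geom, 50.0, -50.0)
    return ReducedLVMechanics(geom, fibers, MaterialParams(c1=1.0))


class TestEquilibrium:
    def test_unloaded_state_is_reference(self, soft_mech):
        geom = soft_mech.geom
        state = equilibrium_state(geom, soft_mech.fibers, soft_mech.material,
                                  pressure=0.0)
        assert state.cavity_volume == pytest.approx(geom.cavity_volume)
        assert state.pressure == 0.0

    def test_pressure_monotone_in_activation(self, soft_mech):
        geom, fib, mat = soft_mech.geom, soft_mech.fibers, soft_mech.material
        V = 1.3 * geom.cavity_volume
        shape = (geom.n_layers, geom.n_segments)
        ps = []
        for ta in (0.0, 5.0, 10.0, 20.0, 40.0):
            st_ = equilibrium_state(geom, fib, mat,
                                    activation=np.full(shape, ta), volume=V)
            ps.append(st_.pressure)
        assert all(a < b for a, b in zip(ps[:-1], ps[1:]))

    def test_passive_pv_curve_monotone(self, soft_mech):
        v0 = soft_mech.V0
        vols = np.linspace(v0, 2.0 * v0, 12)
        shp = None
        ps = []
        for v in vols:
            shp = soft_mech.solve_shape(v, None, shp)
            ps.append(soft_mech.pressure_at(v, shp))
        assert np.all(np.diff(ps) > 0)

    def test_passive_pv_curve_convex_in_stiffening_regime(
            self, canonical_geom, canonical_fibers):
        # on the canonical geometry the exponential law dominates: the
        # end-diastolic branch is convex
        mech = ReducedLVMechanics(canonical_geom, canonical_fibers,
                                  MaterialParams(c1=2.4e-24))
        v_ed, _ = mech.solve_volume(1.0, None)
        vols = np.linspace(0.7 * v_ed, v_ed, 10)
        shp = None
        ps = []
        for v in vols:
            shp = mech.solve_shape(v, None, shp)
            ps.append(mech.pressure_at(v, shp))
        ps = np.array(ps)
        assert np.all(np.diff(ps) > 0)
        assert np.all(np.diff(ps, 2) > 0)

    def test_energy_consistency_pressure_vs_dU_dV(self, soft_mech):
        # p from the solve equals the numerical V-derivative of stored
        # energy along the equilibrium path (envelope property)
        v0 = soft_mech.V0
        for v in (1.2 * v0, 1.6 * v0):
            shp = soft_mech.solve_shape(v)
            p = soft_mech.pressure_at(v, shp)
            dv = 1e-5 * v
            u_p = soft_mech.passive_energy(
                v + dv, soft_mech.solve_shape(v + dv, None, shp))
            u_m = soft_mech.passive_energy(
                v - dv, soft_mech.solve_shape(v - dv, None, shp))
            assert p == pytest.approx((u_p - u_m) / (2 * dv), rel=1e-2)

    def test_wall_volume_conserved_at_equilibria(self, soft_mech):
        # shell-volume kinematics conserve the wall volume identically;
        # verify the bookkeeping of deformed nested shells
        geom = soft_mech.geom
        for v in (1.2, 1.7):
            V = v * geom.cavity_volume
            a, b = soft_mech.solve_shape(V)
            v_enc_outer = V + geom.wall_volume
            l_epi = a * geom.cavity_length + b * geom.LVWT
            r_epi = np.sqrt(3 * v_enc_outer / (2 * np.pi * l_epi))
            wall = (2 / 3 * np.pi * l_epi * r_epi**2) - V
            assert wall == pytest.approx(geom.wall_volume, rel=1e-12)

    def test_thin_wall_isotropic_matches_sphere_closed_form(self):
        # hemispherical thin shell (L = R), quasi-isotropic law, small
        # inflation.  Oracle: incompressible linear-elastic thick sphere,
        # u(r) = a/r², giving p = 4·μ·e_i·(1 − (R_i/R_o)³) with μ = c1·k/2
        # for Q = k·E:E; the thin-wall limit is the Laplace law 12·μ·t·e/R.
        R, t = 10.0, 0.5
        geom = build_semi_ellipsoid(R, 2 * R, t, n_layers=2, n_segments=48)
        fibers = FiberField(alpha_endo=0.0, alpha_epi=0.0)
        k = 3.0
        mat = MaterialParams(c1=1.0, c2=k + 1e-9, c3=k, c4=k)
        mech = ReducedLVMechanics(geom, fibers, mat)
        e = 0.002   # small strain: the oracle is the linearized solution
        V = geom.cavity_volume * (1 + e) ** 3
        shp = mech.solve_shape(V)
        p = mech.pressure_at(V, shp)
        mu = 0.5 * mat.c1 * k
        e_i = mech.endo_radius(V, shp) / R - 1.0
        p_sphere = 4.0 * mu * e_i * (1.0 - (R / (R + t)) ** 3)
        assert p == pytest.approx(p_sphere, rel=0.02)


class TestEndDiastolicInflation:
    def test_zero_pressure_returns_reference(self, soft_mech):
        state, lvedd = inflate_to_ed(soft_mech.geom, soft_mech.fibers,
                                     soft_mech.material, p_ed=0.0)
        assert state.cavity_volume == pytest.approx(
            soft_mech.geom.cavity_volume)

    def test_c1_ped_joint_doubling_invariance(self, soft_mech):
        geom, fib = soft_mech.geom, soft_mech.fibers
        s1, d1 = inflate_to_ed(geom, fib, MaterialParams(c1=1.0), p_ed=1.0)
        s2, d2 = inflate_to_ed(geom, fib, MaterialParams(c1=2.0), p_ed=2.0)
        assert s2.cavity_volume == pytest.approx(s1.cavity_volume, rel=1e-3)
        assert d2 == pytest.approx(d1, rel=1e-3)

    def test_softer_tissue_inflates_more(self, soft_mech):
        geom, fib = soft_mech.geom, soft_mech.fibers
        edvs = [inflate_to_ed(geom, fib, MaterialParams(c1=c1),
                              p_ed=1.0)[0].cavity_volume
                for c1 in (2.0, 1.0, 0.5)]
        assert edvs[0] < edvs[1] < edvs[2]


class TestCanonicalRegime:
    def test_extreme_inflation_is_finite_and_solvable(self, canonical_geom,
                                                      canonical_fibers):
        # the canonical reference cavity inflates several-fold; exponents are
        # clipped before overflow and the equilibrium remains solvable
        mech = ReducedLVMechanics(canonical_geom, canonical_fibers,
                                  MaterialParams(c1=2.4e-24))
        V, shp = mech.solve_volume(1.0, None)
        assert np.isfinite(V) and V > 10 * canonical_geom.cavity_volume
        assert 2.0 * mech.endo_radius(V, shp) == pytest.approx(8.5, abs=0.2)
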