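"""Windkessel circuit, unit consistency and the cardiac-cycle protocol."""

import numpy as np
import pytest

from lvcomp import units
from lvcomp.calcium import generate_calcium_transient
from lvcomp.circulation import (
    LVModel,
    WindkesselParams,
    ab_impedance,
    phenotypes_from_loop,
    round_to_sig_figs,
    simulate_cycle,
    windkessel_step,
)
from lvcomp.errors import InvalidParameterError
from lvcomp.tissue import MaterialParams

W = WindkesselParams()


class TestAbImpedance:
    def test_fifty_percent_scaling(self):
        z = ab_impedance(6.3, 0.5)
        assert z == pytest.approx(9.45)
        assert round_to_sig_figs(z) == 9.5

    def test_identity_and_doubling(self):
        assert ab_impedance(6.3, 0.0) == pytest.approx(6.3)
        assert ab_impedance(1.0, 1.0) == pytest.approx(2.0)

    def test_non_positive_raises(self):
        with pytest.raises(InvalidParameterError):
            ab_impedance(-1.0)


class TestWindkesselCircuit:
    def test_constant_flow_steady_state(self):
        # impose constant flow q0: p_art settles at q0·r and the proximal
        # gradient is q0·z (closed-form steady state of the linear circuit)
        q0 = 2.0  # µl/ms
        p_art = 0.0
        dt = 0.05
        for _ in range(2_000_000):
            p_lv = p_art + q0 * W.z_internal   # holds flow exactly at q0
            q, p_art_new = windkessel_step(p_art, p_lv, dt, W)
            if abs(p_art_new - p_art) < 1e-14:
                p_art = p_art_new
                break
            p_art = p_art_new
        assert q == pytest.approx(q0, rel=1e-8)
        assert p_art == pytest.approx(q0 * W.r_internal, rel=1e-8)
        assert p_lv - p_art == pytest.approx(q0 * W.z_internal, rel=1e-8)

    def test_diastolic_decay_time_constant(self):
        # valve closed (q = 0 achieved with p_lv = p_art): exponential decay
        # with τ = r·c = 1.47 s from the printed values
        tau = W.r_internal * W.c_internal
        assert tau == pytest.approx(1470.0, rel=1e-6)
        p_art = 12.0
        dt = 0.01
        n = int(round(500.0 / dt))
        for _ in range(n):
            _, p_art = windkessel_step(p_art, p_art, dt, W)
        assert p_art == pytest.approx(12.0 * np.exp(-500.0 / tau), rel=1e-4)

    def test_no_gradient_no_flow(self):
        q, _ = windkessel_step(10.0, 10.0, 0.5, W)
        assert q == 0.0

    def test_non_positive_dt_raises(self):
        with pytest.raises(InvalidParameterError):
            windkessel_step(1.0, 2.0, 0.0, W)

    def test_unit_system_consistency(self):
        # run the circuit in (mmHg, ml, s) directly and compare with the
        # internal (kPa, µl, ms) integration converted back
        r_c, c_c, z_c = 105.0, 0.014, 6.3      # conventional units
        p_lv_mmhg = 90.0
        p0_mmhg = 70.0
        dt_s = 1e-4
        n = 2000
        # conventional-unit integration
        p_conv = p0_mmhg
        for _ in range(n):
            q = (p_lv_mmhg - p_conv) / z_c          # ml/s
            p_conv = p_conv + dt_s * (q - p_conv / r_c) / c_c
        # internal-unit integration
        p_int = units.mmhg_to_kpa(p0_mmhg)
        p_lv = units.mmhg_to_kpa(p_lv_mmhg)
        for _ in range(n):
            _, p_int = windkessel_step(p_int, p_lv, dt_s * 1000.0, W)
        assert units.kpa_to_mmhg(p_int) == pytest.approx(p_conv, rel=1e-10)


@pytest.fixture(scope="module")
def sham_loop(sham_like_model):
    return simulate_cycle(sham_like_model)


class TestCycleProtocol:
    def test_loop_converges_with_phases_in_order(self, sham_loop):
        assert sham_loop.converged and not sham_loop.stalled
        phases = list(dict.fromkeys(sham_loop.phase.tolist()))
        assert phases == ["isovolumetric-contraction", "ejection",
                          "isovolumetric-relaxation", "filling"]

    def test_phenotype_contracts(self, sham_loop, sham_like_model):
        ph = phenotypes_from_loop(sham_loop, sham_like_model)
        assert 0.0 < ph.EF < 1.0
        assert ph.p_max >= sham_like_model.windkessel.p_a
        assert ph.EDV > ph.ESV > 0

    def test_volume_bookkeeping_closes(self, sham_loop):
        # stroke volume ejected into the Windkessel equals EDV − ESV: the
        # volume entering ejection (last isovolumetric sample) minus the
        # last ejection sample is the whole stroke, and filling restores
        # the end-diastolic volume within the limit-cycle tolerance
        mask = sham_loop.phase == "ejection"
        idx0 = np.nonzero(mask)[0][0]
        edv_start = sham_loop.volume[idx0 - 1]
        v_last = sham_loop.volume[np.nonzero(mask)[0][-1]]
        assert v_last == pytest.approx(sham_loop.esv, rel=1e-12)
        assert edv_start - v_last == pytest.approx(
            sham_loop.edv - sham_loop.esv, rel=2e-3)
        assert sham_loop.volume[0] == pytest.approx(sham_loop.edv, rel=2e-3)

    def test_isovolumetric_phases_hold_volume(self, sham_loop):
        for name in ("isovolumetric-contraction", "isovolumetric-relaxation"):
            v = sham_loop.volume[sham_loop.phase == name]
            assert np.ptp(v) < 1e-9 * v[0]

    def test_lvedd_matches_geometry_module(self, sham_loop, sham_like_model):
        from lvcomp.tissue import ReducedLVMechanics
        ph = phenotypes_from_loop(sham_loop, sham_like_model)
        mech = ReducedLVMechanics(sham_like_model.geometry,
                                  sham_like_model.fibers,
                                  sham_like_model.material)
        r = mech.endo_radius(ph.EDV, float(sham_loop.lambda_z[-1]))
        assert ph.LVEDD == pytest.approx(2.0 * r, rel=1e-12)

    def test_limit_cycle_independent_of_initial_volume(self, sham_like_model,
                                                       sham_loop):
        ph_ref = phenotypes_from_loop(sham_loop, sham_like_model)
        loop2 = simulate_cycle(sham_like_model,
                               initial_volume=0.7 * sham_loop.edv)
        ph2 = phenotypes_from_loop(loop2, sham_like_model)
        assert ph2.EF == pytest.approx(ph_ref.EF, abs=2e-3)
        assert ph2.EDV == pytest.approx(ph_ref.EDV, rel=1e-3)

    def test_no_activation_stalls_with_zero_ef(self):
        # flat transient at the diastolic level: no tension, no ejection
        flat = generate_calcium_transient(0.1, 0.1, 20, 50, 200, 0.5)
        m = LVModel.canonical(LVWT=2.0, material=MaterialParams(c1=2.4e-24),
                              transient=flat)
        loop = simulate_cycle(m)
        assert loop.stalled
        ph = phenotypes_from_loop(loop, m)
        assert ph.EF == 0.0

    def test_raising_impedance_lowers_ef(self, sham_like_model):
        efs = []
        for z in (6.3, 9.45, 14.0):
            m = sham_like_model.updated(
                windkessel=WindkesselParams(z=z, p_a=8.1))
            ph = phenotypes_from_loop(simulate_cycle(m), m)
            efs.append(ph.EF)
        assert efs[0] > efs[1] > efs[2]
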