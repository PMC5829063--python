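"""Compensatory-sensitivity functional S[EF, u]: closed forms and contracts."""

import numpy as np
import pytest

from lvcomp.circulation import simulate_cycle, phenotypes_from_loop
from lvcomp.errors import InvalidParameterError, SensitivityFailureError
from lvcomp.sensitivity import (
    DEFAULT_SPANS,
    central_sensitivity,
    ef_sensitivity,
    _current_value,
    _model_at,
)


class TestCentralDifferenceCore:
    def test_zero_span_is_exactly_zero(self):
        called = []

        def ef_at(x):
            called.append(x)
            return 0.7

        assert central_sensitivity(ef_at, 1.0, 0.0) == 0.0
        assert called == []   # no simulations spent on a zero span

    def test_linear_surrogate_closed_form(self):
        # EF(u) = a + b·u exactly: S = b·span/(a + b·u)
        a, b, u, span = 0.6, 0.05, 2.0, -0.6
        s = central_sensitivity(lambda x: a + b * x, u, span)
        assert s == pytest.approx(b * span / (a + b * u), rel=1e-6)

    def test_invariant_under_unit_rescaling(self):
        # rescaling the parameter's units rescales span and derivative
        # inversely, leaving S unchanged
        a, b, u, span = 0.6, 0.05, 2.0, 1.5
        k = 1000.0
        s1 = central_sensitivity(lambda x: a + b * x, u, span)
        s2 = central_sensitivity(lambda x: a + (b / k) * x, u * k, span * k)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_one_sided_fallback_on_failure(self):
        from lvcomp.errors import EquilibriumFailureError

        def ef_guarded(x):
            if x > 1.0:
                raise EquilibriumFailureError("perturbed point failed")
            return 0.5 + 0.1 * x

        s = central_sensitivity(ef_guarded, 1.0, 2.0, step_fraction=0.01)
        assert s == pytest.approx(0.1 * 2.0 / 0.6, rel=1e-3)

    def test_all_failures_raise(self):
        from lvcomp.errors import EquilibriumFailureError

        def ef_bad(x):
            if x != 1.0:
                raise EquilibriumFailureError("always fails")
            return 0.5

        with pytest.raises(SensitivityFailureError):
            central_sensitivity(ef_bad, 1.0, 2.0)


class TestModelParameterPlumbing:
    @pytest.mark.parametrize("name,value", [
        ("c1_tilde", 3.0e-24), ("Ca50", 0.9), ("p_a", 5.5), ("z", 9.45),
        ("PCa", 1.2), ("DCa", 0.12), ("LVWT", 2.5),
    ])
    def test_set_and_read_back(self, sham_like_model, name, value):
        m = _model_at(sham_like_model, name, value)
        assert _current_value(m, name) == pytest.approx(value, rel=1e-12)

    def test_unknown_parameter_raises(self, sham_like_model):
        with pytest.raises(InvalidParameterError):
            _model_at(sham_like_model, "bogus", 1.0)

    def test_u_coordinates_require_config_pair(self, sham_like_model):
        with pytest.raises(InvalidParameterError):
            _model_at(sham_like_model, "u_geom", 0.5)

    def test_pca_perturbation_preserves_shape(self, sham_like_model):
        m = _model_at(sham_like_model, "PCa", 1.2)
        np.testing.assert_allclose(m.transient.normalized(),
                                   sham_like_model.transient.normalized(),
                                   atol=1e-12)
        assert m.transient.PCa == pytest.approx(1.2)


class TestOrganLevelSigns:
    def test_ef_increases_with_peak_calcium(self, fig5_fit):
        # two full simulations at PCa and PCa+δ: EF must rise, so with the
        # negative AB−SHAM span S[EF, PCa] is negative
        model = fig5_fit.model
        s = ef_sensitivity(model, "PCa", span=DEFAULT_SPANS["PCa"],
                           step_fraction=0.05, ef0=fig5_fit.phenotypes.EF)
        assert s < 0.0

    def test_ef_decreases_with_ca50(self, fig5_fit):
        model = fig5_fit.model
        s = ef_sensitivity(model, "Ca50", span=DEFAULT_SPANS["Ca50"],
                           step_fraction=0.05, ef0=fig5_fit.phenotypes.EF)
        # dEF/dCa50 < 0 and the AB−SHAM span is negative: S > 0
        assert s > 0.0

    def test_thicker_wall_raises_ef_at_fixed_parameters(self, fig5_fit):
        model = fig5_fit.model
        s = ef_sensitivity(model, "LVWT", span=DEFAULT_SPANS["LVWT"],
                           step_fraction=0.05, ef0=fig5_fit.phenotypes.EF)
        assert s > 0.0


class TestTrajectoryScan:
    @pytest.fixture(scope="class")
    def endpoints(self, fig5_fit):
        # SHAM endpoint: the canonical LVWT=2 fit; AB endpoint: thicker wall,
        # banded impedance and the depressed banded calcium transient,
        # fitted to an AB-like measured triple
        from lvcomp.calcium import ab_transient
        from lvcomp.circulation import LVModel, WindkesselParams
        from lvcomp.fitting import PhenotypeTarget, fit_model
        from lvcomp.sensitivity import TrajectoryEndpoint

        sham = TrajectoryEndpoint(fit=fig5_fit,
                                  target=PhenotypeTarget(8.5, 16.0, 0.75))
        ab_target = PhenotypeTarget(8.6, 19.0, 0.70)
        ab_template = LVModel.canonical(
            LVWT=3.0, transient=ab_transient(),
            windkessel=WindkesselParams(z=9.45, p_a=8.1))
        ab = TrajectoryEndpoint(fit=fit_model(ab_target, ab_template),
                                target=ab_target)
        return sham, ab

    def test_geometry_sensitivity_drops_at_the_banded_endpoint(
            self, endpoints):
        # the published ordering: after hypertrophy the compensatory
        # leverage of further geometric remodeling is reduced
        from lvcomp.sensitivity import trajectory_scan
        sham, ab = endpoints
        reports = trajectory_scan(sham, ab, grid=(0.0, 1.0),
                                  params=("u_geom",), step_fraction=0.02)
        s_sham = reports[0].S["u_geom"]
        s_ab = reports[1].S["u_geom"]
        assert s_sham is not None and s_ab is not None
        assert s_sham > 0.0
        assert abs(s_ab) < abs(s_sham)

    def test_interior_point_refits_to_interpolated_targets(self, endpoints):
        from lvcomp.sensitivity import trajectory_scan
        sham, ab = endpoints
        reports = trajectory_scan(sham, ab, grid=(0.5,), params=())
        rep = reports[0]
        assert rep.diagnostics.get("refit") is None
        # the refit state simulates the linearly interpolated phenotypes;
        # its EF must sit midway between the endpoint targets within the
        # fit tolerance
        mid_ef = 0.5 * (sham.target.EF + ab.target.EF)
        assert rep.EF == pytest.approx(mid_ef, rel=0.01)
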