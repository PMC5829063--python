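import numpy as np
import pytest

from lvcomp.calcium import ab_transient, sham_transient
from lvcomp.circulation import LVModel
from lvcomp.geometry import assign_fibers, build_semi_ellipsoid
from lvcomp.tissue import MaterialParams


@pytest.fixture(scope="session")
def sham_ca():
    return sham_transient()


@pytest.fixture(scope="session")
def ab_ca():
    return ab_transient()


@pytest.fixture(scope="session")
def canonical_geom():
    """Canonical semi-ellipsoid: cavity length 10 mm, reference diameter 3 mm,
    wall thickness 2 mm."""
    return build_semi_ellipsoid(10.0, 3.0, 2.0)


@pytest.fixture(scope="session")
def canonical_fibers(canonical_geom):
    return assign_fibers(canonical_geom, 50.0, -50.0)


@pytest.fixture(scope="session")
def sham_like_model():
    """Canonical model pre-set near the SHAM operating point (stiffness gives
    LVEDD ~ 8.5 mm at the 1 kPa filling pressure)."""
    return LVModel.canonical(LVWT=2.0, material=MaterialParams(c1=2.4e-24))


@pytest.fixture(scope="session")
def fig5_fit():
    """Newton fit of the canonical LVWT=2 model to the first sweep target
    triple (8.5 mm, 16 kPa, 75%); shared because the fit is expensive."""
    from lvcomp.fitting import PhenotypeTarget, fit_model
    return fit_model(PhenotypeTarget(LVEDD=8.5, p_max=16.0, EF=0.75),
                     LVModel.canonical(LVWT=2.0))
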