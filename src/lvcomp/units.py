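"""Centralized unit conversions.

The simulator works internally in (kPa, µl, ms).  Circulation parameters are
conventionally reported in (mmHg, ml, s); because 1 s/ml = 1 ms/µl, resistances
and impedances convert by the pressure factor alone and compliances by its
inverse.
"""

KPA_PER_MMHG = 0.133322
MMHG_PER_KPA = 1.0 / KPA_PER_MMHG


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa: float) -> float:
    return p_kpa * MMHG_PER_KPA


def resistance_to_internal(r_mmhg_s_per_ml: float) -> float:
    """mmHg·s/ml -> kPa·ms/µl  (s/ml and ms/µl coincide numerically)."""
    return r_mmhg_s_per_ml * KPA_PER_MMHG


def resistance_to_conventional(r_kpa_ms_per_ul: float) -> float:
    """kPa·ms/µl -> mmHg·s/ml."""
    return r_kpa_ms_per_ul * MMHG_PER_KPA


def compliance_to_internal(c_ml_per_mmhg: float) -> float:
    """ml/mmHg -> µl/kPa  (1 ml/mmHg = 1000 µl / 0.133322 kPa)."""
    return c_ml_per_mmhg * 1000.0 / KPA_PER_MMHG


def compliance_to_conventional(c_ul_per_kpa: float) -> float:
    """µl/kPa -> ml/mmHg."""
    return c_ul_per_kpa * KPA_PER_MMHG / 1000.0
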