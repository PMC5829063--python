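"""Synthetic echo cohorts and the cylindrical-slice analysis.

Generates seeded SHAM and aortic-banded (AB) M-mode cohorts (10 rats each,
weeks 0/2/4), extracts wall dimensions, estimates ejection fractions and
normalized wall-growth rates, and compares the groups with Welch's t-test —
the full echocardiographic arm of the study on synthetic data.
"""

import numpy as np

from lvcomp import (
    LongitudinalSeries,
    ab_cohort_spec,
    cohort_compare,
    ejection_fraction,
    extract_dimensions,
    generate_echo_cohort,
    remodeling_rate,
    sham_cohort_spec,
)


def analyse(records, spec):
    efs, rates = [], []
    for rec in records:
        dims4 = extract_dimensions(rec.traces[4.0], spec.period_ms)
        efs.append(ejection_fraction(dims4))
        lvwt = [extract_dimensions(rec.traces[w], spec.period_ms).LVWT_dia
                for w in spec.weeks]
        rates.append(remodeling_rate(
            LongitudinalSeries(np.array(spec.weeks), np.array(lvwt))))
    return np.array(efs), np.array(rates)


sham_spec = sham_cohort_spec(seed=42)
ab_spec = ab_cohort_spec(seed=43)
sham_ef, sham_r = analyse(generate_echo_cohort(sham_spec), sham_spec)
ab_ef, ab_r = analyse(generate_echo_cohort(ab_spec), ab_spec)

print(f"week-4 EF      SHAM {sham_ef.mean():.3f} +/- {sham_ef.std(ddof=1):.3f}"
      f"   AB {ab_ef.mean():.3f} +/- {ab_ef.std(ddof=1):.3f}")
print(f"R[LVWT_dia]    SHAM {sham_r.mean():.3f} +/- {sham_r.std(ddof=1):.3f}"
      f" /wk  AB {ab_r.mean():.3f} +/- {ab_r.std(ddof=1):.3f} /wk")

rep = cohort_compare(ab_r, sham_r)
print(f"Welch test on wall-growth rates: t = {rep.t_statistic:.2f}, "
      f"p = {rep.p_value:.2e}")
print("\nAB hearts thicken their walls ~3x faster than SHAM while both"
      " groups keep a normal ejection fraction - the signature of"
      " compensated concentric hypertrophy.")
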