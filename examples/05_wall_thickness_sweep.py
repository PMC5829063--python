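"""Compensatory-sensitivity sweep over wall thickness.

For each wall thickness, refits (c1, p_a, Ca50) to the same phenotype
target, then evaluates the span-scaled EF sensitivities S[EF, u] for the
wall thickness itself, the peak calcium PCa and the calcium sensitivity
Ca50.  As the wall thickens, |S[EF, LVWT]| falls while |S[EF, PCa]| and
|S[EF, Ca50]| rise: hypertrophy loses compensatory leverage to the calcium
system.  Expect ~5 minutes of runtime (each grid point is a Newton fit plus
six limit-cycle simulations).
"""

from lvcomp import PhenotypeTarget, lvwt_sweep

df = lvwt_sweep(PhenotypeTarget(LVEDD=8.5, p_max=16.0, EF=0.75),
                lvwt_grid=(2.0, 2.5, 3.0))
cols = ["LVWT_mm", "c1_kPa", "pa_kPa", "Ca50_uM", "S_LVWT", "S_PCa", "S_Ca50"]
print(df[cols].to_string(index=False,
                         float_format=lambda v: f"{v:10.3g}"))
print("\n|S[EF, LVWT]| decreasing and |S[EF, PCa]|, |S[EF, Ca50]|"
      " increasing with LVWT reproduce the study's headline trend: a"
      " thick-walled ventricle gains less from further thickening and"
      " relies more on intracellular calcium remodeling to hold its"
      " ejection fraction.")
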