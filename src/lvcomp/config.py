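"""Configuration parsing, validation and run orchestration.

Run configurations are YAML mappings with one block per model component.
All physical quantities carry explicit unit suffixes in their key names
(``pa_kPa``, ``z_mmHg_s_per_ml``, ...) because the model mixes conventional
circulation units (mmHg, ml, s) with the internal mechanics units
(kPa, µl, ms); the conversion happens in exactly one place (`lvcomp.units`).

``run_experiment`` executes the requested stages in order and writes their
outputs plus a ``manifest.json`` (config echo, package/library versions,
seed, wall-clock and per-stage status) into the output directory.  Numeric
CSV output uses 12 significant digits so files round-trip through their
readers to within float formatting.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .calcium import generate_calcium_transient
from .cell import BindingParams, TensionParams, simulate_cell
from .circulation import (
    CycleProtocol,
    LVModel,
    WindkesselParams,
    phenotypes_from_loop,
    simulate_cycle,
)
from .cohort import CohortSpec, generate_echo_cohort
from .echo import ejection_fraction, extract_dimensions
from .errors import SchemaViolationError
from .fitting import PhenotypeTarget, fit_model
from .geometry import FiberField, LVGeometry
from .sensitivity import DEFAULT_SPANS, evaluate_report, lvwt_sweep
from .tissue import MaterialParams, ReducedLVMechanics

__all__ = ["load_config", "model_from_config", "cohort_spec_from_config",
           "run_experiment", "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.12g"

_STOCHASTIC_STAGES = {"cohort"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaViolationError("configuration root must be a mapping")
    return cfg


def _get(block: dict, key: str, default=None, required=False, where=""):
    if key in block:
        return block[key]
    if required:
        raise SchemaViolationError(f"missing required field {where}{key}")
    return default


def model_from_config(cfg: dict) -> LVModel:
    """Build an :class:`LVModel` from a ``model:`` configuration block."""
    if "model" not in cfg:
        raise SchemaViolationError("missing required field model")
    m = cfg["model"]
    g = m.get("geometry", {})
    geom = LVGeometry(
        cavity_length=_get(g, "cavity_length_mm", 10.0),
        cavity_radius=_get(g, "reference_diameter_mm", 3.0) / 2.0,
        LVWT=_get(g, "lvwt_mm", required=True, where="model.geometry."),
        n_layers=int(_get(g, "n_layers", 4)),
        n_segments=int(_get(g, "n_segments", 24)),
    )
    f = m.get("fibers", {})
    fibers = FiberField(alpha_endo=_get(f, "alpha_endo_deg", 50.0),
                        alpha_epi=_get(f, "alpha_epi_deg", -50.0))
    mat = m.get("material", {})
    material = MaterialParams(
        c1=_get(mat, "c1_kPa", required=True, where="model.material."),
        c2=_get(mat, "c2", 8.0), c3=_get(mat, "c3", 2.0),
        c4=_get(mat, "c4", 3.7), p_ed=_get(mat, "p_ed_kPa", 1.0),
    )
    b = m.get("binding", {})
    binding = BindingParams(
        Ca50=_get(b, "ca50_uM", 1.5), n_trpn=_get(b, "n_trpn", 2.0),
        k_trpn=_get(b, "k_trpn_per_ms", 0.1), n_xb=_get(b, "n_xb", 5.0),
        k_xb=_get(b, "k_xb_per_ms", 0.02), TRPN50=_get(b, "trpn50", 0.35),
    )
    tn = m.get("tension", {})
    tension = TensionParams(
        T_ref=_get(tn, "t_ref_kPa", 120.0),
        beta_len=_get(tn, "beta_len", 4.9),
        velocity_dependence=bool(_get(tn, "velocity_dependence", True)),
    )
    circ = m.get("circulation", {})
    wk = WindkesselParams(
        r=_get(circ, "r_mmHg_s_per_ml", 105.0),
        c=_get(circ, "c_ml_per_mmHg", 0.014),
        z=_get(circ, "z_mmHg_s_per_ml", 6.3),
        p_a=_get(circ, "pa_kPa", 8.1),
    )
    proto_blk = m.get("protocol", {})
    protocol = CycleProtocol(
        period_ms=_get(proto_blk, "period_ms", 200.0),
        p_ed=_get(proto_blk, "p_ed_kPa", 1.0),
        dt_ms=_get(proto_blk, "dt_ms", 0.5),
    )
    ca = m.get("calcium", {})
    transient = generate_calcium_transient(
        DCa=_get(ca, "dca_uM", 0.10), PCa=_get(ca, "pca_uM", 1.53),
        time_to_peak=_get(ca, "time_to_peak_ms", 20.0),
        decay_time_constant=_get(ca, "tau_ms", 50.0),
        period=protocol.period_ms, dt=_get(ca, "dt_ms", 0.5),
    )
    return LVModel(geometry=geom, fibers=fibers, material=material,
                   binding=binding, tension=tension, windkessel=wk,
                   transient=transient, protocol=protocol)


def cohort_spec_from_config(cfg: dict, seed=None) -> CohortSpec:
    if "cohort" not in cfg:
        raise SchemaViolationError("missing required field cohort")
    c = cfg["cohort"]
    use_seed = seed if seed is not None else c.get("seed", cfg.get("seed"))
    if use_seed is None:
        raise SchemaViolationError(
            "missing required field seed (cohort generation is stochastic)")
    return CohortSpec(
        n_rats=int(_get(c, "n_rats", 10)),
        lvd_dia_mean_mm=_get(c, "lvd_dia_mean_mm", 8.1),
        lvd_dia_sd_mm=_get(c, "lvd_dia_sd_mm", 0.35),
        lvwt_dia_mean_mm=_get(c, "lvwt_dia_mean_mm", 1.6),
        lvwt_dia_sd_mm=_get(c, "lvwt_dia_sd_mm", 0.15),
        growth_rate_mean_per_week=_get(c, "growth_rate_mean_per_week", 0.03),
        growth_rate_sd_per_week=_get(c, "growth_rate_sd_per_week", 0.02),
        ef_mean=_get(c, "ef_mean", 0.75),
        ef_sd=_get(c, "ef_sd", 0.05),
        shortening_fraction=_get(c, "shortening_fraction", 0.15),
        noise_sd_mm=_get(c, "noise_sd_mm", 0.05),
        weeks=tuple(_get(c, "weeks", (0.0, 2.0, 4.0))),
        n_beats=int(_get(c, "n_beats", 6)),
        period_ms=_get(c, "period_ms", 200.0),
        dt_ms=_get(c, "dt_ms", 1.0),
        seed=int(use_seed),
    )


def target_from_config(cfg: dict) -> PhenotypeTarget:
    if "target" not in cfg:
        raise SchemaViolationError("missing required field target")
    t = cfg["target"]
    return PhenotypeTarget(
        LVEDD=_get(t, "lvedd_mm", required=True, where="target."),
        p_max=_get(t, "p_max_kPa", required=True, where="target."),
        EF=_get(t, "ef", required=True, where="target."),
    )


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_cohort(cfg, out: Path, seed):
    spec = cohort_spec_from_config(cfg, seed)
    records = generate_echo_cohort(spec)
    rows = []
    for rec in records:
        for week, trace in rec.traces.items():
            trace.to_csv(out / f"rat{rec.rat_id:02d}_week{week:g}.csv")
        rows.append({
            "rat_id": rec.rat_id,
            "true_lvd_dia_mm": rec.true_lvd_dia_mm,
            "true_lvwt_dia_mm": rec.true_lvwt_dia_mm,
            "true_growth_rate_per_week": rec.true_growth_rate_per_week,
            "true_ef": rec.true_ef,
        })
    pd.DataFrame(rows).to_csv(out / "cohort_truth.csv", index=False,
                              float_format=FLOAT_FORMAT)
    return {"n_rats": spec.n_rats, "weeks": list(spec.weeks)}


def _stage_echo(cfg, out: Path, seed):
    from .cohort import MModeTrace
    blk = cfg.get("echo", {})
    trace_dir = Path(blk.get("trace_dir", out))
    formula = blk.get("formula", "corrected")
    period = blk.get("period_ms", 200.0)
    rows = []
    for path in sorted(trace_dir.glob("rat*_week*.csv")):
        trace = MModeTrace.from_csv(path)
        dims = extract_dimensions(trace, expected_period_ms=period)
        rows.append({
            "trace": path.name,
            "LVD_dia_mm": dims.LVD_dia, "LVD_sys_mm": dims.LVD_sys,
            "LVWT_dia_mm": dims.LVWT_dia, "LVWT_sys_mm": dims.LVWT_sys,
            "n_beats": dims.n_beats_averaged,
            "EF": ejection_fraction(dims, formula=formula),
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "echo_dimensions.csv", index=False, float_format=FLOAT_FORMAT)
    return {"n_traces": len(df), "formula": formula}


def _stage_cell(cfg, out: Path, seed):
    model = model_from_config(cfg)
    df = simulate_cell(model.transient, model.binding, model.tension)
    df.to_csv(out / "cell_trace.csv", index=False, float_format=FLOAT_FORMAT)
    return {"peak_f_xb": float(df["f_xb"].max()),
            "peak_T_a_kPa": float(df["T_a_kPa"].max())}


def _stage_pv(cfg, out: Path, seed):
    model = model_from_config(cfg)
    blk = cfg.get("pv", {})
    n = int(blk.get("n_points", 20))
    v_max_factor = float(blk.get("v_max_factor", 2.0))
    mech = ReducedLVMechanics(model.geometry, model.fibers, model.material)
    v0 = model.geometry.cavity_volume
    rows = []
    shp = None
    for v in np.linspace(v0, v_max_factor * v0, n):
        shp = mech.solve_shape(v, None, shp)
        rows.append({"volume_ul": v, "pressure_kPa": mech.pressure_at(v, shp)})
    pd.DataFrame(rows).to_csv(out / "pv_curve.csv", index=False,
                              float_format=FLOAT_FORMAT)
    return {"n_points": n}


def _stage_simulate(cfg, out: Path, seed):
    model = model_from_config(cfg)
    loop = simulate_cycle(model)
    loop.to_frame().to_csv(out / "pv_loop.csv", index=False,
                           float_format=FLOAT_FORMAT)
    ph = phenotypes_from_loop(loop, model)
    summary = {"LVEDD_mm": ph.LVEDD, "p_max_kPa": ph.p_max, "EF": ph.EF,
               "EDV_ul": ph.EDV, "ESV_ul": ph.ESV,
               "beats": loop.beats, "stalled": loop.stalled}
    (out / "phenotypes.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_fit(cfg, out: Path, seed):
    model = model_from_config(cfg)
    target = target_from_config(cfg)
    fit = fit_model(target, model)
    loop = simulate_cycle(fit.model)
    loop.to_frame().to_csv(out / "fitted_loop.csv", index=False,
                           float_format=FLOAT_FORMAT)
    result = {
        "c1_tilde_kPa": fit.c1_tilde, "pa_kPa": fit.p_a, "ca50_uM": fit.Ca50,
        "iterations": fit.iterations, "residuals": fit.residuals,
        "phenotypes": {"LVEDD_mm": fit.phenotypes.LVEDD,
                       "p_max_kPa": fit.phenotypes.p_max,
                       "EF": fit.phenotypes.EF},
    }
    (out / "fit.json").write_text(json.dumps(result, indent=2))
    return result


def _stage_sweep(cfg, out: Path, seed):
    target = target_from_config(cfg)
    blk = cfg.get("sweep", {})
    grid = tuple(blk.get("lvwt_grid_mm", (1.0, 2.0, 3.0)))
    df = lvwt_sweep(target, lvwt_grid=grid,
                    alpha_endo=blk.get("alpha_endo_deg", 50.0),
                    alpha_epi=blk.get("alpha_epi_deg", -50.0))
    df.to_csv(out / "lvwt_sweep.csv", index=False, float_format=FLOAT_FORMAT)
    return {"n_points": len(df)}


def _stage_sensitivity(cfg, out: Path, seed):
    model = model_from_config(cfg)
    blk = cfg.get("sensitivity", {})
    spans = {k.replace("span_", ""): v for k, v in blk.items()
             if k.startswith("span_")}
    if not spans:
        spans = dict(DEFAULT_SPANS)
    report = evaluate_report(model, spans)
    payload = {"EF": report.EF, "S": report.S, "spans": report.spans,
               "steps": report.steps, "diagnostics": report.diagnostics}
    (out / "sensitivity.json").write_text(json.dumps(payload, indent=2))
    return payload


_STAGES = {
    "cohort": _stage_cohort,
    "echo": _stage_echo,
    "cell": _stage_cell,
    "pv": _stage_pv,
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "sweep": _stage_sweep,
    "sensitivity": _stage_sensitivity,
}


def run_experiment(cfg: dict, out_dir, seed=None) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    stages = cfg.get("stages")
    if not stages:
        raise SchemaViolationError("missing required field stages")
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise SchemaViolationError(f"unknown stage(s): {unknown}")
    use_seed = seed if seed is not None else cfg.get("seed")
    if any(s in _STOCHASTIC_STAGES for s in stages) and use_seed is None \
            and "cohort" in cfg and "seed" not in cfg.get("cohort", {}):
        raise SchemaViolationError(
            "missing required field seed (stochastic stage requested)")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import scipy
    manifest = {
        "config": cfg,
        "seed": use_seed,
        "versions": {"lvcomp": _pkg_version, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    for stage in stages:
        t0 = time.time()
        try:
            info = _STAGES[stage](cfg, out, use_seed)
            manifest["stages"][stage] = {
                "status": "ok", "seconds": round(time.time() - t0, 3),
                "summary": info,
            }
        except Exception as exc:
            manifest["stages"][stage] = {
                "status": "error", "seconds": round(time.time() - t0, 3),
                "error": f"{type(exc).__name__}: {exc}",
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))
            raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
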