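"""End-to-end orchestration: simulate → quantify → calibrate → compare.

The pipeline drives a full synthetic method-comparison study from one truth:
a calibration series and a set of samples (several dilutions each) are
acquired in PRM and MRM modes, quantified through the shared extraction
contract, calibrated per target with 1/x weighting, and the back-calculated
concentrations of the two modes compared by Deming regression.  All outputs
are plain CSV plus a JSON manifest recording every parameter and seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import (
    CalibrationModel,
    CalibrationPoint,
    determine_linear_range,
    limits_of_detection,
    normalize_response,
)
from .compare import DemingRegressor, PairedMeasurements, agreement_report, deming_fit
from .extract import TargetArea, integrate_transition, quantify_prm
from .msdata import InclusionEntry
from .simulate import (
    AcquisitionConfig,
    SimTarget,
    default_panel,
    inclusion_list_from_targets,
    reference_spectra_from_targets,
    simulate_calibration_series,
    simulate_mrm_traces,
    simulate_prm_run,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "areas_to_frame", "quantify_mrm_traces"]

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "out_dir": "prmquant_out",
    "panel_size": 3,  # analytes drawn from the default panel (plus the IS)
    "internal_standard": "digoxin_d3",
    "levels_ng_ml": [0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0, 10000.0],
    "calibration_replicates": 3,
    "n_samples": 4,
    "dilutions": [1.0, 0.5, 0.05],
    "sample_concentration_ng_ml": 500.0,
    "noise_cv": 0.05,
    "gradient_length": 8.0,
    "desolvation_temperature": 400.0,
    "mz_tol_ppm": 25.0,
    "n_fragments": 3,
    "weighting": "1/x",
    "accuracy_tol": 0.20,
    "variance_ratio": 1.0,
}


def areas_to_frame(areas: list[TargetArea]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in areas],
            "target_id": [a.target_id for a in areas],
            "mode": [a.mode for a in areas],
            "area": [a.area for a in areas],
            "n_scans": [a.n_scans for a in areas],
            "fragments_used": [";".join(f"{f:.4f}" for f in a.fragments_used) for a in areas],
        }
    )


def quantify_mrm_traces(
    traces, entries: list[InclusionEntry], sample_id: str
) -> list[TargetArea]:
    """Integrate each target's MRM transition inside its scheduled window."""
    by_id = {t.target_id: t for t in traces}
    areas = []
    for entry in entries:
        trace = by_id.get(entry.target_id)
        if trace is None:
            raise KeyError(f"no MRM trace for target {entry.target_id!r}")
        area = integrate_transition(trace, entry.rt_center, entry.rt_window)
        area.sample_id = sample_id
        areas.append(area)
    return areas


def _panel(cfg: dict) -> list[SimTarget]:
    panel = default_panel()
    is_id = cfg["internal_standard"]
    analytes = [t for t in panel if t.target_id != is_id][: int(cfg["panel_size"])]
    internal = [t for t in panel if t.target_id == is_id]
    if not internal:
        raise ValueError(f"internal standard {is_id!r} not in panel")
    return analytes + internal


def _acq_config(cfg: dict, seed: int) -> AcquisitionConfig:
    return AcquisitionConfig(
        gradient_length=float(cfg["gradient_length"]),
        desolvation_temperature=float(cfg["desolvation_temperature"]),
        noise_cv=float(cfg["noise_cv"]),
        mz_tol_ppm=float(cfg["mz_tol_ppm"]),
        seed=seed,
    )


def _quantify_sample(mode, targets, entries, refspecs, acq, sample_id, cfg):
    if mode == "prm":
        run, _ = simulate_prm_run(targets, entries, acq, sample_id)
        return quantify_prm(
            run, entries, refspecs, cfg["mz_tol_ppm"], int(cfg["n_fragments"])
        )
    traces = simulate_mrm_traces(targets, acq)
    return quantify_mrm_traces(traces, entries, sample_id)


def _ratio_table(areas: list[TargetArea], is_id: str) -> dict[str, float]:
    by_id = {a.target_id: a for a in areas}
    is_area = by_id[is_id]
    return {
        tid: normalize_response(a, is_area) for tid, a in by_id.items() if tid != is_id
    }


def run_study(config: dict | None = None) -> dict:
    """Run the synthetic comparison study in memory.

    Returns a dict with ``areas`` (list of TargetArea), ``curves`` and
    ``merit`` (row dicts), ``concentrations`` (DataFrame of back-calculated
    sample concentrations by mode) and ``deming`` (agreement table).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    panel = _panel(cfg)
    is_id = cfg["internal_standard"]
    analyte_ids = [t.target_id for t in panel if t.target_id != is_id]
    entries = inclusion_list_from_targets(panel)
    refspecs = reference_spectra_from_targets(panel)
    levels = [float(x) for x in cfg["levels_ng_ml"]]
    modes = ("prm", "mrm")

    all_areas: list[TargetArea] = []
    curves: dict[tuple[str, str], CalibrationModel] = {}
    curve_rows, merit_rows = [], []

    # --- calibration per mode -------------------------------------------
    for mi, mode in enumerate(modes):
        acq = _acq_config(cfg, seed + 1000 * (mi + 1))
        acquisitions, design = simulate_calibration_series(
            panel, levels, int(cfg["calibration_replicates"]), acq,
            mode=mode, internal_standard_id=is_id,
        )
        ratios: dict[str, list[CalibrationPoint]] = {tid: [] for tid in analyte_ids}
        for sample_id, payload, _truth in acquisitions:
            if mode == "prm":
                areas = quantify_prm(
                    payload, entries, refspecs, cfg["mz_tol_ppm"], int(cfg["n_fragments"])
                )
            else:
                areas = quantify_mrm_traces(payload, entries, sample_id)
            all_areas.extend(areas)
            level = float(
                design.loc[
                    (design["sample_id"] == sample_id)
                    & (design["target_id"] == analyte_ids[0]),
                    "concentration_ng_ml",
                ].iloc[0]
            )
            rep = sample_id.rsplit("_r", 1)[1]
            for tid, ratio in _ratio_table(areas, is_id).items():
                ratios[tid].append(CalibrationPoint(level, ratio, rep))
        for tid in analyte_ids:
            # non-detects (zero response, e.g. below the PRM scheduling
            # threshold at the lowest standards) carry no calibration signal
            pts = [p for p in ratios[tid] if p.response > 0]
            model = CalibrationModel(weighting=cfg["weighting"]).fit(
                [p.concentration for p in pts], [p.response for p in pts]
            )
            curves[(mode, tid)] = model
            curve_rows.append(
                {
                    "mode": mode,
                    "target_id": tid,
                    "slope": model.slope_,
                    "intercept": model.intercept_,
                    "weighting": cfg["weighting"],
                    "r_squared": model.r_squared_,
                    "residual_sd": model.residual_sd_,
                    "n_points": model.n_points_,
                }
            )
            if cfg.get("compute_merit", True):
                merit_rows.append(_merit_row(mode, tid, pts, model, cfg))

    # --- samples at several dilutions, quantified by both modes ---------
    base = {
        (s, tid): float(cfg["sample_concentration_ng_ml"]) * rng.lognormal(0.0, 0.5)
        for s in range(int(cfg["n_samples"]))
        for tid in analyte_ids
    }
    conc_rows = []
    for mi, mode in enumerate(modes):
        for s in range(int(cfg["n_samples"])):
            for di, dil in enumerate(cfg["dilutions"]):
                sample_id = f"sample{s}_d{di}"
                adjusted = [
                    t
                    if t.target_id == is_id
                    else replace(t, concentration=base[(s, t.target_id)] * float(dil))
                    for t in panel
                ]
                acq = _acq_config(
                    cfg, seed + 10_000 * (mi + 1) + 100 * s + di
                )
                areas = _quantify_sample(
                    mode, adjusted, entries, refspecs, acq, sample_id, cfg
                )
                all_areas.extend(areas)
                for tid, ratio in _ratio_table(areas, is_id).items():
                    xhat = float(curves[(mode, tid)].inverse_predict(ratio))
                    conc_rows.append(
                        {
                            "sample_id": sample_id,
                            "target_id": tid,
                            "dilution": float(dil),
                            "mode": mode,
                            "response_ratio": ratio,
                            "concentration_ng_ml": xhat,
                            "true_concentration_ng_ml": base[(s, tid)] * float(dil),
                            "flag": "sub_blank" if xhat < 0 else "",
                        }
                    )
    conc = pd.DataFrame(conc_rows)

    # --- Deming comparison PRM vs MRM per target ------------------------
    fits = {}
    wide = conc.pivot_table(
        index=["sample_id", "target_id", "dilution"],
        columns="mode",
        values="concentration_ng_ml",
    ).reset_index()
    for tid, grp in wide.groupby("target_id"):
        data = PairedMeasurements(
            x=grp["mrm"].to_numpy(), y=grp["prm"].to_numpy(),
            ids=list(zip(grp["sample_id"], [tid] * len(grp), grp["dilution"])),
        )
        fits[(tid, "prm_vs_mrm")] = deming_fit(data, float(cfg["variance_ratio"]))
    deming_table = agreement_report(fits)
    return {
        "config": cfg,
        "areas": all_areas,
        "curves": curve_rows,
        "merit": merit_rows,
        "concentrations": conc,
        "deming": deming_table,
    }


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full synthetic study; returns paths of the written artifacts.

    Writes AREAS.csv, CURVES.csv, MERIT.csv, CONCENTRATIONS.csv, DEMING.csv
    and manifest.json into ``config['out_dir']``.
    """
    study = run_study(config)
    cfg = study["config"]
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "areas": out_dir / "AREAS.csv",
        "curves": out_dir / "CURVES.csv",
        "merit": out_dir / "MERIT.csv",
        "concentrations": out_dir / "CONCENTRATIONS.csv",
        "deming": out_dir / "DEMING.csv",
        "manifest": out_dir / "manifest.json",
    }
    areas_to_frame(study["areas"]).to_csv(paths["areas"], index=False)
    pd.DataFrame(study["curves"]).to_csv(paths["curves"], index=False)
    pd.DataFrame(study["merit"]).to_csv(paths["merit"], index=False)
    study["concentrations"].to_csv(paths["concentrations"], index=False)
    study["deming"].to_csv(paths["deming"], index=False)
    manifest = {"prmquant_version": __version__, "config": cfg}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}


def method_agreement_slope(seed: int, **overrides) -> float:
    """Pooled PRM-vs-MRM Deming slope for one simulated study replicate.

    Simulates calibration plus 10 samples at 3 dilutions in both modes from
    one truth (5% multiplicative noise by default), quantifies each mode
    through its own calibration, and fits one orthogonal regression over all
    (sample, target, dilution) concentration pairs.
    """
    cfg: dict = {
        "seed": int(seed),
        "n_samples": 10,
        "dilutions": [1.0, 0.5, 0.05],
        "calibration_replicates": 1,
        "noise_cv": 0.05,
        "compute_merit": False,  # single-replicate calibration carries no SD
    }
    cfg.update(overrides)
    conc = run_study(cfg)["concentrations"]
    wide = conc.pivot_table(
        index=["sample_id", "target_id", "dilution"], columns="mode",
        values="concentration_ng_ml",
    ).reset_index()
    fit = deming_fit(
        PairedMeasurements(x=wide["mrm"].to_numpy(), y=wide["prm"].to_numpy())
    )
    return fit.slope


def _merit_row(mode, tid, pts, model, cfg) -> dict:
    curve = model.to_curve()
    try:
        low, high = determine_linear_range(pts, curve, float(cfg["accuracy_tol"]))
    except ValueError:
        low = high = float("nan")
    # SD from replicate back-calculations at the lowest quantifiable level
    lowest = low if np.isfinite(low) else min(p.concentration for p in pts)
    reps = [p.response for p in pts if p.concentration == lowest]
    if len(reps) >= 2:
        back = model.inverse_predict(reps)
        sd = float(np.std(back, ddof=1))
        lod, loq = limits_of_detection(sd)
    else:
        warnings.warn(f"{mode}/{tid}: <2 replicates at lowest level; no LOD/LOQ", stacklevel=2)
        sd = lod = loq = float("nan")
    return {
        "mode": mode,
        "target_id": tid,
        "sd_ng_ml": sd,
        "lod_ng_ml": lod,
        "loq_ng_ml": loq,
        "linear_range_low_ng_ml": low,
        "linear_range_high_ng_ml": high,
    }
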