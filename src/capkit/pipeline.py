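"""Pipeline orchestration: stage execution, seeding and the run manifest.

A single configured seed feeds a counter-based derivation scheme (one
spawn key per stage), so adding a stage never perturbs the random streams
of earlier stages, and a rerun under the same configuration reproduces
byte-identical delimited outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np

from . import io as cio
from .cap import CapKinetics, InductionSchedule
from .pk import PKParams, build_scenario, simulate, translocation_fraction, \
    tumor_specificity
from .screen import blood_viability, fit_growth_rate, phage_sensitivity_auc, \
    screen_summary
from .synthetic import (DEFAULT_LOD, GrowthParams, TEMGeometry, ToxCohort,
                        generate_blood_killing, generate_growth_curve,
                        generate_tem_image, generate_tox_cohort)
from .tem import aggregate_histogram, fit_thickness, radial_thickness, \
    segment_layer
from .toxicity import fit_td50, mtd_fold_change, mtd_from_fit

__all__ = ["default_config", "run_pipeline", "stage_seed",
           "kinetics_from_config", "params_from_config",
           "scenario_from_config"]

_STAGE_IDS = {"generate": 0, "screen": 1, "simulate": 2, "fit_tox": 3,
              "measure_tem": 4}


def stage_seed(seed: int, stage: str, counter: int = 0) -> int:
    """Derive a per-stage substream seed (< 2**31) from the pipeline seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_IDS[stage], counter))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def default_config(seed: int = 0) -> dict:
    """Full pipeline configuration from the packaged default calibration."""
    d = cio.load_defaults()
    return {
        "seed": seed,
        "stages": ["generate", "screen", "simulate", "fit_tox", "measure_tem"],
        "generator": {
            "noise_cv": 0.05,
            "lod": DEFAULT_LOD,
            "tem_conditions": {"iptg_0": [[44.0, 5.0, 1.0]],
                               "iptg_0p1uM": [[44.0, 5.0, 0.5],
                                              [81.0, 5.0, 0.5]],
                               "iptg_1uM": [[81.0, 5.0, 1.0]]},
            "n_cells_per_condition": 5,
            "tox_td50": {"EcN_iCAP": 4.4e7, "EcN": 5.8e6, "EcN_dkfiC": 9.6e6},
            "tox_hill": 4.0,
            "tox_doses": [2e6, 5e6, 1.26e7, 3.16e7, 7.9e7, 2e8],
            "tox_n_per_dose": 10,
        },
        "kinetics": d["kinetics"],
        "pk": d["pk"],
        "scenario": d["scenario"],
        "tox_fit": {"n_boot": 200, "endpoint": "fraction"},
        "tem": {"blur_sigma": 2.0, "threshold_method": "otsu", "n_rays": 360,
                "bin_width_nm": 2.0, "max_components": 2, "nm_per_px": 4.0,
                "cell_radius_nm": 600.0, "noise_sd": 0.05},
    }


def kinetics_from_config(cfg: dict) -> CapKinetics:
    k = {**cio.load_defaults()["kinetics"], **cfg.get("kinetics", {})}
    return CapKinetics(**k)


def params_from_config(cfg: dict) -> PKParams:
    p = {**cio.load_defaults()["pk"], **cfg.get("pk", {})}
    return PKParams(**p)


def scenario_from_config(cfg: dict):
    s = {**cio.load_defaults()["scenario"], **cfg.get("scenario", {})}
    horizon = float(s["horizon"])
    schedule = None
    if s["cap_mode"] == "in_situ":
        schedule = InductionSchedule.step(float(s["induction_start_h"]),
                                          horizon,
                                          float(s["induction_iptg"]))
    return build_scenario(route=s["route"], dose=float(s["dose"]),
                          cap_mode=s["cap_mode"], schedule=schedule,
                          horizon=horizon,
                          treated_tumor=int(s.get("treated_tumor", 0)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# The knockdown panel used by the generate stage: growth rate in LB,
# blood-killing rate, and phage-lysis onset (None = immune).
_STRAIN_PANEL = {
    "EcN":        {"mu": 1.00, "k_kill": 0.4, "lysis_delay": 3.5},
    "kfiA_KD":    {"mu": 0.97, "k_kill": 2.0, "lysis_delay": 3.5},
    "kfiB_KD":    {"mu": 0.95, "k_kill": 1.8, "lysis_delay": 3.5},
    "kfiD_KD":    {"mu": 0.98, "k_kill": 2.2, "lysis_delay": 3.5},
    "kpsE_KD":    {"mu": 0.96, "k_kill": 1.0, "lysis_delay": 3.5},
    "kpsD_KD":    {"mu": 0.99, "k_kill": 1.1, "lysis_delay": 3.5},
    "EcN_dkfiC":  {"mu": 0.97, "k_kill": 5.0, "lysis_delay": None},
}


def _stage_generate(cfg: dict, out: Path) -> list[Path]:
    gen = cfg.get("generator", {})
    noise_cv = float(gen.get("noise_cv", 0.05))
    lod = float(gen.get("lod", DEFAULT_LOD))
    seed0 = cfg["seed"]
    files: list[Path] = []

    lb_times = np.arange(0.0, 12.01, 0.25)
    blood_times = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0])
    growth_curves, phage_curves, blood_series = [], [], []
    for i, (strain, spec) in enumerate(_STRAIN_PANEL.items()):
        gp = GrowthParams(od0=0.05, mu_max=spec["mu"], carrying_capacity=1.0,
                          noise_cv=noise_cv)
        growth_curves.append(generate_growth_curve(
            gp, lb_times, stage_seed(seed0, "generate", 10 + i),
            strain_label=strain, condition_label="LB"))
        pp = GrowthParams(od0=0.05, mu_max=spec["mu"], carrying_capacity=1.0,
                          lysis_delay=spec["lysis_delay"], lysis_rate=3.0,
                          noise_cv=noise_cv)
        phage_curves.append(generate_growth_curve(
            pp, lb_times, stage_seed(seed0, "generate", 40 + i),
            strain_label=strain, condition_label="phage"))
        blood_series.append(generate_blood_killing(
            n0=1e6, k_kill=spec["k_kill"], lod=lod, times=blood_times,
            seed=stage_seed(seed0, "generate", 70 + i),
            strain_label=strain, condition_label="blood"))

    for name, frame in [("growth_lb.csv", cio.growth_to_frame(growth_curves)),
                        ("growth_phage.csv", cio.growth_to_frame(phage_curves)),
                        ("blood_cfu.csv", cio.cfu_to_frame(blood_series))]:
        p = out / name
        cio.write_table(p, frame)
        files.append(p)

    hill = float(gen.get("tox_hill", 4.0))
    doses = [float(d) for d in gen.get("tox_doses", [])]
    n_per = int(gen.get("tox_n_per_dose", 10))
    for j, (strain, td50) in enumerate(sorted(
            gen.get("tox_td50", {}).items())):
        cohort = generate_tox_cohort(doses, float(td50), hill, n_per,
                                     stage_seed(seed0, "generate", 100 + j))
        p = out / f"tox_{strain}.csv"
        cio.write_table(p, cohort.to_frame())
        files.append(p)

    tem_cfg = cfg.get("tem", {})
    geo = TEMGeometry(cell_radius_nm=float(tem_cfg.get("cell_radius_nm", 600.0)),
                      nm_per_px=float(tem_cfg.get("nm_per_px", 4.0)),
                      wobble=0.03)
    n_cells = int(gen.get("n_cells_per_condition", 5))
    noise_sd = float(tem_cfg.get("noise_sd", 0.05))
    for cond, comps in gen.get("tem_conditions", {}).items():
        spec = [tuple(c) for c in comps]
        for cell in range(n_cells):
            cond_tag = zlib.crc32(cond.encode()) % 1000
            img = generate_tem_image(spec, geo, noise_sd,
                                     stage_seed(seed0, "generate",
                                                200 + 10 * cell) + cond_tag)
            p = out / "tem" / cond / f"cell_{cell}.tif"
            cio.write_tem_image(p, img)
            files.extend([p, p.with_suffix(".json"),
                          p.with_name(p.stem + "_truth.tif"),
                          p.with_name(p.stem + "_truth.json")])
    return files


def _stage_screen(cfg: dict, out: Path) -> list[Path]:
    growth = cio.growth_from_frame(
        cio.read_table(out / "growth_lb.csv", cio.GROWTH_SCHEMA))
    phage = cio.growth_from_frame(
        cio.read_table(out / "growth_phage.csv", cio.GROWTH_SCHEMA))
    blood = cio.cfu_from_frame(
        cio.read_table(out / "blood_cfu.csv", cio.CFU_SCHEMA))
    strains = [c.strain_label for c in growth]
    fits = [fit_growth_rate(c) for c in growth]
    aucs = [phage_sensitivity_auc(c) for c in phage]
    viab = [blood_viability(s) for s in blood]
    table = screen_summary(fits, viab, aucs, strains)
    p = out / "screen_table.csv"
    cio.write_table(p, table)
    pj = out / "screen_table.json"
    pj.write_text(table.to_json(orient="records", indent=2) + "\n")
    return [p, pj]


def _stage_simulate(cfg: dict, out: Path) -> list[Path]:
    kin = kinetics_from_config(cfg)
    params = params_from_config(cfg)
    base = scenario_from_config(cfg)
    grid = np.linspace(0.0, base.horizon, 289)
    files = []
    summary: dict = {"tumor_specificity_72h": {}}
    for mode in ("none", "static", "transient"):
        sc = build_scenario(base.route, base.dose, mode, None, base.horizon,
                            base.treated_tumor)
        traj = simulate(params, sc, kin, grid)
        p = out / f"traj_iv_{mode}.csv"
        cio.write_table(p, traj.to_frame())
        files.append(p)
        summary["tumor_specificity_72h"][mode] = tumor_specificity(
            traj, min(72.0, base.horizon))

    # intratumoral route: in-situ induction versus no induction; the
    # translocation route requires tumor -> blood escape
    from dataclasses import replace
    it_params = params if params.k_escape > 0 else replace(params,
                                                           k_escape=0.01)
    s = {**cio.load_defaults()["scenario"], **cfg.get("scenario", {})}
    schedule = InductionSchedule.step(float(s["induction_start_h"]),
                                      base.horizon,
                                      float(s["induction_iptg"]))
    frac = {}
    for label, mode, sched in [("no_induction", "none", None),
                               ("in_situ", "in_situ", schedule)]:
        sc = build_scenario("it", base.dose, mode, sched, base.horizon, 0)
        traj = simulate(it_params, sc, kin, grid)
        p = out / f"traj_it_{label}.csv"
        cio.write_table(p, traj.to_frame())
        files.append(p)
        frac[label] = translocation_fraction(traj, 0, min(72.0, base.horizon))
    summary["translocation_fraction_72h"] = {
        k: {str(j): v for j, v in d.items()} for k, d in frac.items()}
    ps = out / "pk_summary.json"
    ps.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    files.append(ps)
    return files


def _stage_fit_tox(cfg: dict, out: Path) -> list[Path]:
    n_boot = int(cfg.get("tox_fit", {}).get("n_boot", 200))
    fits = {}
    for j, path in enumerate(sorted(out.glob("tox_*.csv"))):
        strain = path.stem[4:]
        cohort = ToxCohort.from_frame(cio.read_table(path, cio.TOX_SCHEMA))
        fit = fit_td50(cohort, n_boot=n_boot,
                       seed=stage_seed(cfg["seed"], "fit_tox", j))
        mtd, ci = mtd_from_fit(fit)
        fits[strain] = {"td50_cfu": fit.td50, "hill": fit.hill,
                        "mtd_cfu": mtd, "mtd_ci": list(ci),
                        "n_boot": fit.n_boot}
        fits[strain]["_fit"] = fit
    strains = list(fits)
    if "EcN_iCAP" in fits and "EcN" in fits:
        ratio, ci = mtd_fold_change(fits["EcN_iCAP"]["_fit"],
                                    fits["EcN"]["_fit"])
        fits["mtd_fold_change_iCAP_over_EcN"] = {"ratio": ratio,
                                                 "ci": list(ci)}
    for s in strains:
        fits[s].pop("_fit")
    p = out / "tox_fits.json"
    p.write_text(json.dumps(fits, indent=2, sort_keys=True) + "\n")
    return [p]


def _stage_measure_tem(cfg: dict, out: Path) -> list[Path]:
    tem_cfg = cfg.get("tem", {})
    blur = float(tem_cfg.get("blur_sigma", 2.0))
    n_rays = int(tem_cfg.get("n_rays", 360))
    bin_w = float(tem_cfg.get("bin_width_nm", 2.0))
    maxc = int(tem_cfg.get("max_components", 2))
    results = {}
    files = []
    rows = []
    for cond_dir in sorted((out / "tem").iterdir()):
        if not cond_dir.is_dir():
            continue
        samples = []
        for tif in sorted(cond_dir.glob("cell_*.tif")):
            if tif.stem.endswith("_truth"):
                continue
            img = cio.read_tem_image(tif)
            mask = segment_layer(img, blur_sigma=blur)
            s = radial_thickness(mask, img.nm_per_px, n_rays=n_rays,
                                 cell_id=f"{cond_dir.name}/{tif.stem}")
            samples.append(s)
            for a, t in zip(s.angles, s.thickness_nm):
                rows.append((cond_dir.name, s.cell_id, a, t))
        hist = aggregate_histogram(samples, bin_width=bin_w)
        fit = fit_thickness(samples, max_components=maxc,
                            seed=stage_seed(cfg["seed"], "measure_tem", 0))
        results[cond_dir.name] = {
            "n_cells": hist.n_cells,
            "n_components": fit.n_components,
            "means_nm": list(fit.means),
            "sds_nm": list(fit.sds),
            "weights": list(fit.weights),
        }
    import pandas as pd
    p = out / "tem_thickness_samples.csv"
    cio.write_table(p, pd.DataFrame(
        rows, columns=["condition", "cell_id", "angle_rad", "thickness_nm"]))
    pj = out / "tem_fits.json"
    pj.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    return [p, pj]


_STAGE_FUNCS = {"generate": _stage_generate, "screen": _stage_screen,
                "simulate": _stage_simulate, "fit_tox": _stage_fit_tox,
                "measure_tem": _stage_measure_tem}

_STAGE_DEPS = {"screen": "generate", "fit_tox": "generate",
               "measure_tem": "generate"}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages and write a JSON manifest.

    Stages run in dependency order (generate -> screen / simulate /
    fit_tox / measure_tem); the manifest lists every produced file with
    its SHA-256 and records the seed, so byte-identical reruns are
    checkable.
    """
    cfg = cio._validate_config(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", list(_STAGE_FUNCS))
    unknown = set(stages) - set(_STAGE_FUNCS)
    if unknown:
        raise cio.SchemaError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in _STAGE_FUNCS if s in stages]  # dependency order
    for s in stages:
        dep = _STAGE_DEPS.get(s)
        if dep and dep not in stages and not (out / "growth_lb.csv").exists():
            raise cio.SchemaError(
                f"stage {s!r} needs artifacts from {dep!r}, which is neither "
                "scheduled nor already present in the output directory")
    manifest = {"seed": cfg["seed"], "stages": stages, "files": {}}
    for s in stages:
        for path in _STAGE_FUNCS[s](cfg, out):
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
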