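"""Table, image and configuration readers/writers.

Delimited outputs are comma-separated UTF-8 with LF newlines and a fixed
column order so that reruns under the same configuration are
byte-identical.  Numbers are parsed locale-independently (dot decimal,
scientific notation accepted).  TEM micrographs travel as 16-bit
grayscale TIFF with the physical scale in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import CfuSeries, GrowthCurve, TEMImage

__all__ = [
    "SchemaError",
    "GROWTH_SCHEMA",
    "CFU_SCHEMA",
    "TOX_SCHEMA",
    "read_table",
    "write_table",
    "growth_to_frame",
    "growth_from_frame",
    "cfu_to_frame",
    "cfu_from_frame",
    "write_tem_image",
    "read_tem_image",
    "load_config",
    "load_defaults",
]


class SchemaError(ValueError):
    """A table or configuration violates its declared schema."""


GROWTH_SCHEMA = {"strain": str, "condition": str, "time_h": float,
                 "od600": float}
CFU_SCHEMA = {"strain": str, "condition": str, "time_h": float,
              "cfu_per_ml": float, "lod": float, "censored": bool}
TOX_SCHEMA = {"mouse_id": str, "dose_cfu": float, "severe_tox": bool}


def _coerce(df: pd.DataFrame, schema: dict, path) -> pd.DataFrame:
    for col, typ in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
        if typ is bool:
            vals = df[col].astype(str).str.strip().str.lower()
            bad = ~vals.isin(["true", "false", "0", "1"])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(f"{path}: unparsable boolean in column "
                                  f"{col!r}, row {row}")
            df[col] = vals.isin(["true", "1"])
        elif typ is float:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(f"{path}: unparsable number in column "
                                  f"{col!r}, row {row}")
            df[col] = converted.astype(float)
        else:
            df[col] = df[col].astype(str)
    return df[list(schema)]


def read_table(path, schema: dict, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited table and validate it against a column schema."""
    df = pd.read_csv(path, delimiter=delimiter, dtype=str,
                     keep_default_na=False)
    return _coerce(df, schema, path)


def write_table(path, df: pd.DataFrame, delimiter: str = ",") -> None:
    """Write a table as delimited text (UTF-8, LF, fixed column order)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n",
              encoding="utf-8")


def growth_to_frame(curves: list[GrowthCurve]) -> pd.DataFrame:
    rows = [(c.strain_label, c.condition_label, t, od)
            for c in curves for t, od in zip(c.times, c.od600)]
    return pd.DataFrame(rows, columns=list(GROWTH_SCHEMA))


def growth_from_frame(df: pd.DataFrame) -> list[GrowthCurve]:
    curves = []
    for (strain, cond), grp in df.groupby(["strain", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        curves.append(GrowthCurve(times=grp["time_h"].to_numpy(),
                                  od600=grp["od600"].to_numpy(),
                                  strain_label=strain, condition_label=cond))
    return curves


def cfu_to_frame(series: list[CfuSeries]) -> pd.DataFrame:
    rows = [(s.strain_label, s.condition_label, t, v, s.lod, bool(c))
            for s in series
            for t, v, c in zip(s.times, s.cfu_per_ml, s.censored)]
    return pd.DataFrame(rows, columns=list(CFU_SCHEMA))


def cfu_from_frame(df: pd.DataFrame) -> list[CfuSeries]:
    out = []
    for (strain, cond), grp in df.groupby(["strain", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(CfuSeries(times=grp["time_h"].to_numpy(),
                             cfu_per_ml=grp["cfu_per_ml"].to_numpy(),
                             lod=float(grp["lod"].iloc[0]),
                             censored=grp["censored"].to_numpy(dtype=bool),
                             strain_label=strain, condition_label=cond))
    return out


def write_tem_image(path, image: TEMImage, with_truth: bool = True) -> None:
    """16-bit grayscale TIFF plus a JSON sidecar carrying nm_per_px.

    Ground truth (when present) is written next to the image as a mask
    TIFF and a JSON thickness table, both suffixed ``_truth``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(path, ((px - lo) * scale).astype(np.uint16))
    sidecar = {"nm_per_px": image.nm_per_px,
               "intensity_offset": lo, "intensity_scale": scale}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    if with_truth and image.truth is not None:
        t = image.truth
        tifffile.imwrite(path.with_name(path.stem + "_truth.tif"),
                         t["ring_mask"].astype(np.uint8) * 255)
        table = {"angles_rad": list(map(float, t["angles"])),
                 "thickness_nm": list(map(float, t["thickness_nm"]))}
        path.with_name(path.stem + "_truth.json").write_text(
            json.dumps(table) + "\n")


def read_tem_image(path) -> TEMImage:
    """Read a TIFF/PNG micrograph with its JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path} (nm_per_px)")
    sidecar = json.loads(sidecar_path.read_text())
    if "nm_per_px" not in sidecar:
        raise SchemaError(f"{sidecar_path}: missing key 'nm_per_px'")
    raw = tifffile.imread(path).astype(float)
    offset = sidecar.get("intensity_offset", 0.0)
    scale = sidecar.get("intensity_scale", 1.0)
    return TEMImage(pixels=raw / scale + offset,
                    nm_per_px=float(sidecar["nm_per_px"]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_SECTIONS = {
    "seed": None,
    "stages": None,
    "generator": {"n_strains", "noise_cv", "lod", "tem_conditions",
                  "n_cells_per_condition", "tox_td50", "tox_hill",
                  "tox_doses", "tox_n_per_dose"},
    "kinetics": {"ec50", "hill_n", "k_on", "k_off", "basal"},
    "pk": {"k_clear", "p_min", "k_mps", "delta_p", "k_entry", "k_escape",
           "r_t", "cap_k", "n_tumors"},
    "scenario": {"route", "dose", "cap_mode", "horizon", "treated_tumor",
                 "induction_start_h", "induction_iptg"},
    "tox_fit": {"n_boot", "endpoint"},
    "tem": {"blur_sigma", "threshold_method", "n_rays", "bin_width_nm",
            "max_components", "nm_per_px", "cell_radius_nm", "noise_sd"},
}


def _validate_config(cfg: dict, path="config") -> dict:
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    unknown = set(cfg) - set(_CONFIG_SECTIONS)
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    if "seed" not in cfg:
        raise SchemaError(f"{path}: missing required field 'seed'")
    if not isinstance(cfg["seed"], int):
        raise SchemaError(f"{path}: 'seed' must be an integer")
    for section, allowed in _CONFIG_SECTIONS.items():
        if allowed is None or section not in cfg:
            continue
        bad = set(cfg[section]) - allowed
        if bad:
            raise SchemaError(f"{path}: unknown keys in [{section}]: "
                              f"{sorted(bad)}")
    return cfg


def load_config(path) -> dict:
    """Load and strictly validate a JSON/YAML pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    cfg = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text))
    return _validate_config(cfg, path)


def load_defaults() -> dict:
    """Packaged default calibration (kinetics, PK rates, scenario)."""
    from importlib.resources import files
    text = (files("capkit") / "data" / "defaults.yaml").read_text()
    return yaml.safe_load(text)
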