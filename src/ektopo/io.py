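"""File formats: elevation-map CSV dialect, PRP maps, cohort directories.

An elevation map is stored as two header lines followed by a square matrix
of sag values in µm (``NaN`` marks invalid samples)::

    # grid_spacing_mm=0.05
    # half_width_mm=3.5
    0.0,0.1,...

PRP maps use the same dialect with values in diopters and an extra
``# zone_diameter_mm=`` header. A cohort directory holds one CSV per
surface per record plus ``manifest.csv`` and the JSON config used.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grading import PRPMap
from .synthetic import BscvaModel, CohortConfig, EyeRecord
from .wavefront import CorneaModel, ElevationMap

__all__ = [
    "read_elevation_csv",
    "write_elevation_csv",
    "read_prp_csv",
    "write_prp_csv",
    "write_cohort",
    "read_cohort",
]


def _read_headers(path: Path, expected: list[str]) -> dict[str, float]:
    headers: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            headers[key.strip()] = float(value)
    missing = [k for k in expected if k not in headers]
    if missing:
        raise ValueError(f"{path}: missing header(s) {missing}")
    return headers


def _read_matrix(path: Path) -> np.ndarray:
    values = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix must be square, got {values.shape}")
    return values


def write_elevation_csv(surface: ElevationMap, path: str | Path) -> None:
    """Write an elevation map; invalid samples become NaN."""
    path = Path(path)
    sag = np.where(surface.valid_mask, surface.sag, np.nan)
    with open(path, "w") as fh:
        fh.write(f"# grid_spacing_mm={surface.grid_spacing:g}\n")
        fh.write(f"# half_width_mm={surface.half_width:g}\n")
        np.savetxt(fh, sag, delimiter=",", fmt="%.6f")


def read_elevation_csv(path: str | Path) -> ElevationMap:
    """Read an elevation map, restoring grid metadata and the NaN mask."""
    path = Path(path)
    headers = _read_headers(path, ["grid_spacing_mm", "half_width_mm"])
    sag = _read_matrix(path)
    return ElevationMap(
        sag=sag,
        grid_spacing=headers["grid_spacing_mm"],
        half_width=headers["half_width_mm"],
        valid_mask=np.isfinite(sag),
    )


def write_prp_csv(m: PRPMap, path: str | Path) -> None:
    path = Path(path)
    prp = np.where(m.valid_mask, m.prp, np.nan)
    with open(path, "w") as fh:
        fh.write(f"# grid_spacing_mm={m.grid_spacing:g}\n")
        fh.write(f"# half_width_mm={m.half_width:g}\n")
        fh.write(f"# zone_diameter_mm={m.zone_diameter:g}\n")
        np.savetxt(fh, prp, delimiter=",", fmt="%.6f")


def read_prp_csv(path: str | Path) -> PRPMap:
    path = Path(path)
    headers = _read_headers(path, ["grid_spacing_mm", "half_width_mm"])
    prp = _read_matrix(path)
    return PRPMap(
        prp=prp,
        grid_spacing=headers["grid_spacing_mm"],
        half_width=headers["half_width_mm"],
        zone_diameter=headers.get("zone_diameter_mm", 6.0),
        valid_mask=np.isfinite(prp),
    )


def _config_to_dict(config: CohortConfig) -> dict:
    d = {
        "sizes": config.sizes,
        "seed": config.seed,
        "grid_spacing": config.grid_spacing,
        "half_width": config.half_width,
        "bscva_model": dataclasses.asdict(config.bscva_model),
        "timepoints": config.timepoints,
        "presets": {g: dataclasses.asdict(p) for g, p in config.presets.items()},
    }
    return d


def write_cohort(records: list[EyeRecord], out_dir: str | Path, config: CohortConfig | None = None) -> Path:
    """Persist a cohort: per-surface CSVs, manifest.csv, config.json."""
    out_dir = Path(out_dir)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = f"{rec.eye_id}_{rec.timepoint}"
        ant_path = maps_dir / f"{stem}_anterior.csv"
        post_path = maps_dir / f"{stem}_posterior.csv"
        write_elevation_csv(rec.cornea.anterior, ant_path)
        write_elevation_csv(rec.cornea.posterior, post_path)
        rows.append(
            {
                "eye_id": rec.eye_id,
                "group": rec.group,
                "timepoint": rec.timepoint,
                "sex": rec.sex,
                "eye_side": rec.eye_side,
                "cct_um": rec.cct,
                "bscva_logmar": rec.bscva if rec.bscva is not None else np.nan,
                "bscva_seed": rec.bscva_seed,
                "anterior_map": ant_path.relative_to(out_dir).as_posix(),
                "posterior_map": post_path.relative_to(out_dir).as_posix(),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    if config is not None:
        with open(out_dir / "config.json", "w") as fh:
            json.dump(_config_to_dict(config), fh, indent=2)
    return out_dir


def read_cohort(cohort_dir: str | Path) -> list[EyeRecord]:
    """Re-load a persisted cohort for analysis."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        ant = read_elevation_csv(cohort_dir / row["anterior_map"])
        post = read_elevation_csv(cohort_dir / row["posterior_map"])
        cornea = CorneaModel(anterior=ant, posterior=post, central_thickness=float(row["cct_um"]))
        bscva = None if pd.isna(row["bscva_logmar"]) else float(row["bscva_logmar"])
        records.append(
            EyeRecord(
                eye_id=str(row["eye_id"]),
                group=str(row["group"]),
                timepoint=str(row["timepoint"]),
                cornea=cornea,
                sex=str(row["sex"]),
                eye_side=str(row["eye_side"]),
                bscva=bscva,
                bscva_seed=int(row["bscva_seed"]),
            )
        )
    return records
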