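"""File I/O: NIfTI volumes, FSL-style .bval files, YAML configs, CSV/JSON reports.

NIfTI-1 affines are diagonal RAS with the translation placing voxel (0,0,0)'s
centre at ``origin + 0.5 * spacing``, so the scanner isocentre sits at world
coordinate (0,0,0) exactly as in :class:`~dwiqc.grid.GridSpec`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adc import ADCMap
from .exceptions import ValidationError
from .grid import GridSpec
from .qc import QCThresholds
from .roi import ROISpec
from .spheres import SphereLayout
from .synth import DWISeries

__all__ = [
    "write_dwi_series", "read_dwi_series", "write_adc_map", "read_adc_map",
    "read_bvals", "write_bvals", "read_roi_yaml", "read_layout_yaml",
    "read_thresholds_yaml", "write_json_report", "read_reader_table",
    "write_reader_table",
]


# ---------------------------------------------------------------------------
# NIfTI + bval
# ---------------------------------------------------------------------------

def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    for a in range(3):
        aff[a, a] = grid.spacing[a]
        aff[a, 3] = grid.origin[a] + 0.5 * grid.spacing[a]
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> GridSpec:
    spacing = tuple(float(aff[a, a]) for a in range(3))
    if any(s <= 0 for s in spacing):
        raise ValidationError("only diagonal RAS affines with positive "
                              "spacing are supported")
    origin = tuple(float(aff[a, 3]) - 0.5 * spacing[a] for a in range(3))
    return GridSpec(tuple(shape[:3]), spacing, origin)


def write_bvals(b_values: Sequence[float], path) -> None:
    Path(path).write_text(
        " ".join(f"{b:g}" for b in b_values) + "\n", encoding="ascii")


def read_bvals(path) -> tuple:
    text = Path(path).read_text(encoding="ascii").split()
    if not text:
        raise ValidationError(f"empty bval file {path}")
    return tuple(float(t) for t in text)


def write_dwi_series(series: DWISeries, nifti_path, bval_path=None) -> None:
    nifti_path = Path(nifti_path)
    img = nib.Nifti1Image(series.data.astype(np.float64), _affine(series.grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(nifti_path))
    if bval_path is None:
        bval_path = nifti_path.with_suffix("").with_suffix(".bval") \
            if nifti_path.name.endswith(".nii.gz") else nifti_path.with_suffix(".bval")
    write_bvals(series.b_values, bval_path)


def read_dwi_series(nifti_path, bval_path, repeat_index: int = 0,
                    label: str = "") -> DWISeries:
    """Load a 4-D DWI series; geometry from the affine, b-values from the sidecar."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValidationError(f"{nifti_path}: expected 4-D data, got {data.ndim}-D")
    b_values = read_bvals(bval_path)
    if len(b_values) != data.shape[3]:
        raise ValidationError(
            f"{bval_path}: {len(b_values)} b-values for {data.shape[3]} volumes")
    grid = _grid_from_affine(img.affine, data.shape)
    return DWISeries(data=data, b_values=b_values, grid=grid,
                     repeat_index=repeat_index, label=label or str(nifti_path))


def write_adc_map(adc_map: ADCMap, path, mask_path=None) -> None:
    path = Path(path)
    img = nib.Nifti1Image(adc_map.values.astype(np.float64),
                          _affine(adc_map.grid))
    nib.save(img, str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(adc_map.mask.astype(np.uint8),
                                 _affine(adc_map.grid)), str(mask_path))


def read_adc_map(path, b_values=(0.0, 800.0), mask_path=None) -> ADCMap:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    grid = _grid_from_affine(img.affine, values.shape)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.isfinite(values)
    return ADCMap(values=values, mask=mask, b_values=tuple(b_values), grid=grid)


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def read_roi_yaml(path) -> ROISpec:
    """ROI spec from YAML: ``shape, center_mm, diameter_mm[, plane]``."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return ROISpec(shape=raw["shape"], center=tuple(raw["center_mm"]),
                       diameter_mm=float(raw["diameter_mm"]),
                       plane=raw.get("plane"))
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"invalid ROI file {path}: {exc}") from exc


def read_layout_yaml(path) -> SphereLayout:
    """Sphere layout from YAML: ``spheres: [{id, center_mm, diameter_mm}]``."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return SphereLayout(tuple(
            (s["id"], tuple(s["center_mm"]), float(s["diameter_mm"]))
            for s in raw["spheres"]))
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"invalid layout file {path}: {exc}") from exc


def read_thresholds_yaml(path) -> QCThresholds:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(QCThresholds().__dict__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(
            f"unknown threshold field(s) in {path}: {sorted(unknown)}")
    try:
        return QCThresholds(**{k: float(v) for k, v in raw.items()})
    except TypeError as exc:
        raise ValidationError(f"invalid thresholds file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Reports and tables
# ---------------------------------------------------------------------------

def _config_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_json_report(payload: dict, path, seed: Optional[int] = None,
                      config: Optional[dict] = None) -> None:
    """JSON report stamped with tool version, seed and a config hash."""
    out = dict(payload)
    out["_meta"] = {"tool": "dwiqc", "version": __version__, "seed": seed,
                    "config_hash": _config_hash(config or {})}
    Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")


def write_reader_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_reader_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "node", "reader", "session", "mean_adc"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return df
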