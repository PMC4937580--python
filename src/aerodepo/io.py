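"""Reading and writing the pipeline's file formats.

* impactor runs: CSV with columns ``stage_index, d_lower_um, d_upper_um,
  activity`` (header required, dot decimal separator); optional
  ``loaded_activity`` / ``residual_activity`` columns (constant or on the
  first row); rows with an empty ``d_lower_um`` (or empty/inf
  ``d_upper_um``) are catch bins for activity below (above) the
  instrument range,
* stage tables: CSV with ``stage_index, cut_diameter_um``,
* count rasters and label volumes: single-channel TIFF (float32/uint16),
  PNG (uint16) or whitespace/comma-delimited text matrices,
* ROI masks: a labeled-integer raster plus a JSON label map,
* correction specs and scenarios: YAML,
* synthetic scenes: a directory with per-element rasters, masks,
  an acquisition manifest, ``correction.yaml`` and ``truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .impactor import ImpactorRun, StageTable
from .planar import CorrectionSpec, PlanarPair, RoiSet
from .synthetic import ACQUISITION_SCHEDULE, ELEMENT_REGION, PlanarScene

__all__ = [
    "read_impactor_csv",
    "read_raster",
    "write_raster",
    "read_roi_set",
    "write_roi_set",
    "read_correction_yaml",
    "write_correction_yaml",
    "write_scene_dir",
    "read_scene_dir",
]

_IMPACTOR_COLUMNS = ["stage_index", "d_lower_um", "d_upper_um", "activity"]


def read_impactor_csv(path) -> tuple[ImpactorRun, StageTable]:
    """Parse one impactor run and its stage table from a single CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _IMPACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    # catch-bin rows: missing d_lower_um = activity below the instrument
    # range, missing/inf d_upper_um = activity above it
    below = df[df.d_lower_um.isna()]
    above = df[df.d_upper_um.isna() | np.isinf(df.d_upper_um.fillna(0.0))]
    below_min = float(below.activity.sum())
    above_max = float(above.activity.sum())
    df = df.drop(index=below.index.union(above.index))
    df = df.sort_values("stage_index").reset_index(drop=True)
    if not len(df):
        raise ValidationError(f"{path}: no regular stage rows")
    for i in range(len(df) - 1):
        if not np.isclose(df.d_upper_um[i], df.d_lower_um[i + 1], rtol=1e-9):
            raise ValidationError(
                f"{path}: line {i + 3}: stages not contiguous "
                f"(d_upper {df.d_upper_um[i]} != next d_lower "
                f"{df.d_lower_um[i + 1]})")
    bad = df[~np.isfinite(df.activity) | (df.activity < 0)]
    if len(bad):
        raise ValidationError(
            f"{path}: line {bad.index[0] + 2}: invalid activity value")
    edges = np.concatenate((df.d_lower_um.to_numpy(float),
                            [float(df.d_upper_um.iloc[-1])]))
    loaded = residual = None
    if "loaded_activity" in df.columns:
        loaded = float(df.loaded_activity.dropna().iloc[0])
    if "residual_activity" in df.columns:
        residual = float(df.residual_activity.dropna().iloc[0])
    run = ImpactorRun(stage_activities=df.activity.to_numpy(float),
                      loaded_activity=loaded, residual_activity=residual,
                      below_min=below_min, above_max=above_max,
                      label=path.stem)
    return run, StageTable(edges)


# ---------------------------------------------------------------------------
# rasters


def write_raster(path, array: np.ndarray) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    elif suffix == ".png":
        import imageio.v3 as iio
        arr = np.asarray(array)
        if arr.max() > np.iinfo(np.uint16).max:
            raise ValidationError("PNG output limited to 16-bit counts")
        iio.imwrite(path, np.round(arr).astype(np.uint16))
    elif suffix in (".txt", ".csv"):
        np.savetxt(path, np.asarray(array), fmt="%.6g",
                   delimiter="," if suffix == ".csv" else " ")
    else:
        raise ValidationError(f"unsupported raster format '{suffix}'")


def read_raster(path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        return np.asarray(tifffile.imread(path), dtype=float)
    if suffix == ".png":
        import imageio.v3 as iio
        return np.asarray(iio.imread(path), dtype=float)
    if suffix in (".txt", ".csv"):
        return np.loadtxt(path, delimiter="," if suffix == ".csv" else None)
    raise ValidationError(f"unsupported raster format '{suffix}'")


def write_roi_set(raster_path, labelmap_path, rois: RoiSet) -> None:
    """Store masks as one labeled-integer raster plus a JSON label map."""
    some = next(iter(rois.masks.values()))
    labeled = np.zeros(some.shape, dtype=np.uint16)
    label_map = {}
    for i, (label, mask) in enumerate(sorted(rois.masks.items()), start=1):
        if np.any(labeled[mask]):
            raise ValidationError(
                "overlapping ROI masks cannot be stored as a labeled raster")
        labeled[mask] = i
        label_map[str(i)] = label
    write_raster(raster_path, labeled)
    Path(labelmap_path).write_text(json.dumps(label_map, indent=2))


def read_roi_set(raster_path, labelmap_path) -> RoiSet:
    labeled = read_raster(raster_path)
    label_map = json.loads(Path(labelmap_path).read_text())
    return RoiSet({label: labeled == int(value)
                   for value, label in label_map.items()})


# ---------------------------------------------------------------------------
# configuration


def write_correction_yaml(path, spec: CorrectionSpec) -> None:
    Path(path).write_text(yaml.safe_dump({
        "half_life_s": spec.half_life,
        "reference_time_s": spec.reference_time,
        "attenuation": spec.attenuation,
        "mirror_posterior": spec.posterior_mirroring,
        "background_correction": spec.background_correction,
    }))


def read_correction_yaml(path) -> CorrectionSpec:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: correction config must be a mapping")
    return CorrectionSpec(
        half_life=data.get("half_life_s", CorrectionSpec.half_life),
        reference_time=data.get("reference_time_s", 0.0),
        attenuation=data.get("attenuation"),
        posterior_mirroring=data.get("mirror_posterior", True),
        background_correction=data.get("background_correction", True),
    )


# ---------------------------------------------------------------------------
# scene directories


def write_scene_dir(directory, scene: PlanarScene, fmt: str = "tif") -> Path:
    """Persist a synthetic scene as rasters + manifest + truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for element, (pair, rois) in scene.elements.items():
        write_raster(directory / f"{element}_ant.{fmt}", pair.anterior)
        write_raster(directory / f"{element}_post.{fmt}", pair.posterior)
        write_roi_set(directory / f"{element}_masks.{fmt}",
                      directory / f"{element}_labels.json", rois)
        manifest[element] = {
            "duration_s": pair.duration,
            "start_time_s": pair.start_time,
            "pixel_size_mm": pair.pixel_size,
        }
    (directory / "acquisitions.json").write_text(json.dumps(manifest, indent=2))
    write_correction_yaml(directory / "correction.yaml", scene.correction)
    (directory / "truth.json").write_text(json.dumps(
        scene.truth.to_dict() | {"scenario_label": scene.scenario.label},
        indent=2))
    return directory


def read_scene_dir(directory, fmt: str = "tif") \
        -> tuple[dict[str, tuple[PlanarPair, RoiSet]], CorrectionSpec]:
    """Load an acquisition set written by :func:`write_scene_dir`."""
    directory = Path(directory)
    manifest_path = directory / "acquisitions.json"
    if not manifest_path.exists():
        raise ValidationError(f"{directory}: no acquisitions.json manifest")
    manifest = json.loads(manifest_path.read_text())
    elements = {}
    for element, meta in manifest.items():
        pair = PlanarPair(
            anterior=read_raster(directory / f"{element}_ant.{fmt}"),
            posterior=read_raster(directory / f"{element}_post.{fmt}"),
            duration=meta["duration_s"],
            start_time=meta["start_time_s"],
            pixel_size=meta.get("pixel_size_mm", 2.4),
        )
        rois = read_roi_set(directory / f"{element}_masks.{fmt}",
                            directory / f"{element}_labels.json")
        elements[element] = (pair, rois)
    correction = read_correction_yaml(directory / "correction.yaml")
    return elements, correction
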