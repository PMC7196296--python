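"""Readers and writers for every on-disk artifact.

Formats: NIfTI-1 for volumes (nibabel), TSV for region/reference/score
tables (pandas), YAML for configs, JSON for sidecars.  This module is the
single place where format dialects are decided; everything round-trips
exactly through its writer/reader pairs.

NIfTI convention: volumes are consumed as stored, no reorientation.  The
affine's translation encodes the world coordinate of the *center* of voxel
(0,0,0); :class:`~strokeflow.grid.VolumeGrid` stores the corner, so the two
differ by half a voxel and the conversion is applied symmetrically on read
and write.  The modality tag rides in the NIfTI ``descrip`` field.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grid import LabelVolume, VolumeGrid
from .tables import HealthyReference, RegionTable

__all__ = [
    "read_volume", "write_volume",
    "read_label_volume", "write_label_volume",
    "read_region_table", "write_region_table",
    "read_healthy_reference", "write_healthy_reference",
    "read_score_sheet", "write_score_sheet",
    "read_config", "write_config",
    "read_json", "write_json",
]


def _affine(vol) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.voxel_size_mm)
    # translation = world coordinate of the center of voxel (0,0,0)
    aff[:3, 3] = np.asarray(vol.origin_mm) + 0.5 * np.asarray(vol.voxel_size_mm)
    return aff


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol))
    img.header["descrip"] = f"strokeflow:{vol.modality}".encode()
    nib.save(img, str(path))
    return path


def read_volume(path: str | os.PathLike, allow_nan: bool = True) -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume.

    NaN voxels mark masked-out tissue and are accepted by default; pass
    ``allow_nan=False`` to reject them.  Infinite voxels are always rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    if np.isinf(data).any():
        raise ValueError(f"infinite voxel values in {path}")
    if not allow_nan and np.isnan(data).any():
        raise ValueError(f"non-finite (NaN) voxel values in {path}")
    aff = np.asarray(img.affine)
    spacing = tuple(float(v) for v in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(v) for v in (aff[:3, 3] - 0.5 * np.asarray(spacing)))
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
    modality = descrip.split(":", 1)[1] if descrip.startswith("strokeflow:") else "SPECT"
    return VolumeGrid(values=data, voxel_size_mm=spacing, origin_mm=origin,
                      modality=modality)


def _label_paths(path: Path) -> tuple[Path, Path, Path]:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            stem = name[: -len(ext)]
            return (path,
                    path.with_name(f"{stem}_hemispheres{ext}"),
                    path.with_name(f"{stem}_ventricles{ext}"))
    raise ValueError(f"label volume path must end in .nii or .nii.gz: {path}")


def write_label_volume(labels: LabelVolume, path: str | os.PathLike) -> Path:
    """Write a label volume as three NIfTI files (regions, hemispheres, ventricles)."""
    rpath, hpath, vpath = _label_paths(Path(path))
    rpath.parent.mkdir(parents=True, exist_ok=True)
    for lattice, p in ((labels.region_ids, rpath),
                       (labels.hemisphere_ids, hpath),
                       (labels.ventricle_mask.astype(np.int16), vpath)):
        carrier = VolumeGrid(np.zeros(labels.shape), labels.voxel_size_mm, labels.origin_mm)
        img = nib.Nifti1Image(np.asarray(lattice, dtype=np.int16), _affine(carrier))
        img.header["descrip"] = b"strokeflow:LABEL"
        nib.save(img, str(p))
    return rpath


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    rpath, hpath, vpath = _label_paths(Path(path))
    for p in (rpath, hpath, vpath):
        if not p.exists():
            raise FileNotFoundError(f"label component not found: {p}")
    imgs = [nib.load(str(p)) for p in (rpath, hpath, vpath)]
    arrays = [np.asanyarray(i.dataobj).astype(np.int64) for i in imgs]
    aff = np.asarray(imgs[0].affine)
    spacing = tuple(float(v) for v in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(v) for v in (aff[:3, 3] - 0.5 * np.asarray(spacing)))
    return LabelVolume(region_ids=arrays[0], hemisphere_ids=arrays[1],
                       ventricle_mask=arrays[2].astype(bool),
                       voxel_size_mm=spacing, origin_mm=origin)


def write_region_table(table: RegionTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, sep="\t", index=False)
    return path


def read_region_table(path: str | os.PathLike) -> RegionTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"region table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"no regions in {path}") from None
    return RegionTable(df)


def write_healthy_reference(ref: HealthyReference, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ref.frame.to_csv(path, sep="\t", index=False)
    return path


def read_healthy_reference(path: str | os.PathLike) -> HealthyReference:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"healthy reference not found: {path}")
    return HealthyReference(pd.read_csv(path, sep="\t"))


def write_score_sheet(frame: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_score_sheet(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"score sheet not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_config(config: dict, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def read_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_JSONEncoder)
        fh.write("\n")
    return path


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)
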