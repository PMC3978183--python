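"""Standard-format I/O: NIfTI volumes/sinograms with JSON sidecars, CSV tables.

Volumes and sinograms are written as NIfTI-1 images whose header pixdim
carries the voxel/bin size; everything the arrays cannot hold (orbit
geometry, energy windows, noise seed, reconstruction provenance) goes to a
JSON sidecar next to the image. Result tables are CSV with typed flag
columns. Round-trips are exact for integer counts and to float precision for
volumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .acquisition import EnergyWindowPair, SinogramSet
from .grid import GridSpec
from .projector import OrbitGeometry
from .recon import ReconVolume


def _sidecar(path: Path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_volume(path, vol: ReconVolume) -> None:
    affine = np.diag([vol.grid.voxel_mm, vol.grid.voxel_mm, vol.grid.voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.values, np.float64)[..., None], affine)
    nib.save(img, str(path))
    meta = {"voxel_mm": vol.grid.voxel_mm, "n_xy": vol.grid.n_xy,
            "provenance": _jsonable(vol.provenance)}
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str))


def read_volume(path) -> ReconVolume:
    img = nib.load(str(path))
    voxel = float(img.header["pixdim"][1])
    if voxel <= 0:
        raise ValueError(f"{path}: missing voxel size in NIfTI header")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[..., 0]
    prov = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        prov = meta.get("provenance", {})
        voxel = float(meta.get("voxel_mm", voxel))
    return ReconVolume(np.asarray(data, float), GridSpec(data.shape[0], voxel), prov)


def write_sinogram(path, s: SinogramSet) -> None:
    layers = [s.photopeak]
    names = ["photopeak"]
    for name in ("lower", "truth_primary", "truth_scatter"):
        a = getattr(s, name)
        if a is not None:
            layers.append(a)
            names.append(name)
    stack = np.stack(layers, axis=-1)
    affine = np.diag([1.0, s.geometry.bin_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(stack, affine), str(path))
    meta = {
        "layers": names,
        "geometry": _jsonable(s.geometry),
        "windows": None if s.windows is None else _jsonable(s.windows),
        "seed": s.seed,
        "noise_applied": s.noise_applied,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_sinogram(path) -> SinogramSet:
    sc = _sidecar(path)
    if not sc.exists():
        raise ValueError(f"{path}: missing JSON sidecar with geometry metadata")
    meta = json.loads(sc.read_text())
    stack = np.asanyarray(nib.load(str(path)).dataobj)
    geom = OrbitGeometry(**meta["geometry"])
    win = None if meta["windows"] is None else EnergyWindowPair(**meta["windows"])
    parts = {name: np.asarray(stack[..., k], float)
             for k, name in enumerate(meta["layers"])}
    return SinogramSet(
        photopeak=parts["photopeak"],
        lower=parts.get("lower"),
        geometry=geom,
        windows=win,
        truth_primary=parts.get("truth_primary"),
        truth_scatter=parts.get("truth_scatter"),
        seed=meta.get("seed"),
        noise_applied=bool(meta.get("noise_applied", False)),
    )


_FLAG_COLUMNS = ("valid",)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(_jsonable(obj), sort_keys=False))
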