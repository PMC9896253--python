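"""File I/O: NIfTI volumes via nibabel, cohort CSVs, JSON configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import CTVolume, PhantomSpec, ProbAtlas, TissueMap


def save_ct(ct: CTVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(ct.values, dtype=np.float32), ct.affine)
    img.header.set_zooms(ct.voxel_size)
    nib.save(img, str(path))
    return path


def load_ct(path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(values=data, voxel_size=zooms, affine=np.asarray(img.affine))


def _save_4d(data4d: np.ndarray, voxel_size, path) -> Path:
    path = Path(path)
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    img = nib.Nifti1Image(np.asarray(data4d, dtype=np.float32), affine)
    img.header.set_zooms(tuple(voxel_size) + (1.0,))
    nib.save(img, str(path))
    return path


def save_atlas(atlas: ProbAtlas, path) -> Path:
    return _save_4d(atlas.probs, atlas.voxel_size, path)


def load_atlas(path, intracranial_mask_threshold: float = 0.5) -> ProbAtlas:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ProbAtlas(
        probs=data,
        voxel_size=zooms,
        intracranial_mask_threshold=intracranial_mask_threshold,
    )


def save_tissue_map(tmap: TissueMap, path) -> Path:
    return _save_4d(tmap.fractions, tmap.voxel_size, path)


def load_tissue_map(path) -> TissueMap:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TissueMap(fractions=data, voxel_size=zooms)


def save_cohort(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"etici": "string"})


def spec_to_json(spec, path) -> Path:
    """Serialize a (nested) dataclass spec to JSON."""
    path = Path(path)

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    path.write_text(json.dumps(spec, indent=2, default=default, sort_keys=True))
    return path


def phantom_spec_from_json(path) -> PhantomSpec:
    raw = json.loads(Path(path).read_text())
    for key in ("grid_shape", "voxel_size", "head_semiaxes", "ventricle_semiaxes_max"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomSpec(**raw)
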