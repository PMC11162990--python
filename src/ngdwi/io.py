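"""NIfTI / bval / CSV input-output with grid validation.

Maps and masks are exchanged as NIfTI (.nii or .nii.gz) files; metric maps
are written one file per map, named ``<MODEL>-<metric>.nii.gz`` (e.g.
``CTRW-D.nii.gz``), with a JSON QC sidecar.  Grids must match exactly —
resampling is out of scope, mirroring acquisition protocols in which all
metric maps share dimensions so a VOI can be copied between them directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import MAP_NAMES
from .scheme import BValueScheme, read_bval

__all__ = ["load_volume", "save_volume", "load_dwi", "save_map_set",
           "load_map_set", "save_qc", "write_features_csv",
           "read_features_csv"]


def load_volume(path):
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(path, data, affine=None, voxel_size=(1.0, 1.0, 1.0)):
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), affine), str(path))


def load_dwi(dwi_path, mask_path, bval_path, delta=20.0, Delta=40.0):
    """Load and cross-validate a DWI volume, VOI mask and bval file.

    Returns ``(dwi, mask, scheme, affine)``; raises descriptive errors on
    grid or count mismatches.
    """
    dwi, affine = load_volume(dwi_path)
    if dwi.ndim != 4:
        raise ValueError(f"DWI must be 4D, got shape {dwi.shape}")
    mask, _ = load_volume(mask_path)
    if mask.shape != dwi.shape[:3]:
        raise ValueError(f"mask grid {mask.shape} does not match DWI grid "
                         f"{dwi.shape[:3]}")
    bvals = read_bval(bval_path)
    if len(bvals) != dwi.shape[3]:
        raise ValueError(f"bval file has {len(bvals)} entries but DWI has "
                         f"{dwi.shape[3]} volumes")
    scheme = BValueScheme(tuple(bvals), delta=delta, Delta=Delta)
    return dwi, mask.astype(bool), scheme, affine


def save_map_set(out_dir, maps: dict, affine=None, voxel_size=(1, 1, 1)):
    """Write each metric map as ``<name>.nii.gz``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, data in maps.items():
        save_volume(out / f"{name}.nii.gz", data, affine, voxel_size)


def load_map_set(map_dir, map_names=MAP_NAMES):
    """Read metric maps from a directory; returns (maps, affine)."""
    map_dir = Path(map_dir)
    maps, affine = {}, None
    for name in map_names:
        path = map_dir / f"{name}.nii.gz"
        if not path.exists():
            path = map_dir / f"{name}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing metric map: {name} in {map_dir}")
        data, aff = load_volume(path)
        if affine is None:
            affine = aff
        maps[name] = data
    shapes = {m.shape for m in maps.values()}
    if len(shapes) > 1:
        raise ValueError(f"metric maps disagree on grid shape: {shapes}")
    return maps, affine


def save_qc(path, qc: dict):
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_bval_manifest(out_dir, scheme, rows):
    """Write the cohort manifest CSV and the shared .bval file."""
    out = Path(out_dir)
    from .scheme import write_bval
    write_bval(out / "scheme.bval", scheme.b)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def write_features_csv(path, table: pd.DataFrame):
    table.to_csv(path, index_label="id")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
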