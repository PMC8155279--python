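"""Reading and writing the on-disk fixture tree.

Tabular inputs (scores, norms, covariates, tract profiles, texture
features) are CSV with a header row and subject_id as the join key;
volumes and masks are NIfTI (via nibabel); corresponded meshes are PLY
(via trimesh) with one file per subject sharing a triangulation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine); the affine is used for voxel-size metadata."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_nifti(data: np.ndarray, path, affine: np.ndarray | None = None
                ) -> None:
    import nibabel as nib

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def read_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    mesh = trimesh.load_mesh(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float), \
        np.asarray(mesh.faces, dtype=np.int64)


def write_mesh(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    import trimesh

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(str(path))


def mesh_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume (mm^3) of a closed triangulated surface."""
    import trimesh

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return float(abs(mesh.volume))


def profiles_to_tidy(profiles: np.ndarray, subject_ids, tract_id: str,
                     metric: str) -> pd.DataFrame:
    n, S = profiles.shape
    return pd.DataFrame({
        "subject_id": np.repeat(list(subject_ids), S),
        "tract_id": tract_id,
        "metric": metric,
        "segment": np.tile(np.arange(S), n),
        "value": np.asarray(profiles).ravel(),
    })


def tidy_to_profiles(df: pd.DataFrame, tract_id: str, metric: str
                     ) -> tuple[np.ndarray, list]:
    sub = df[(df["tract_id"] == tract_id) & (df["metric"] == metric)]
    if sub.empty:
        raise ValidationError(f"no profiles for {tract_id}/{metric}")
    wide = sub.pivot(index="subject_id", columns="segment", values="value")
    wide = wide.sort_index(axis=1)
    if wide.isna().any().any():
        raise ValidationError("subjects with missing segments")
    return wide.to_numpy(dtype=float), list(wide.index)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON-serializable: {type(o)}")
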