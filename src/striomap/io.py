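"""Readers and writers for the standard neuroimaging formats the pipeline touches.

Conventions, asserted here and relied on everywhere else:

* voxel indices are 0-based; affines map voxel (i, j, k) to world mm (RAS);
* masks are half-open in index space;
* integer maps round-trip exactly, float series within 1e-6;
* a series file and its mask must share an affine, or reading fails hard.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

__all__ = [
    "FormatError",
    "save_nifti",
    "load_nifti",
    "save_gifti_mesh",
    "load_gifti_mesh",
    "save_gifti_data",
    "load_gifti_data",
    "save_tsv",
    "load_tsv",
    "save_sparse",
    "load_sparse",
    "save_json",
    "load_json",
    "require_same_affine",
]


class FormatError(ValueError):
    """A file failed to parse or violated a format contract."""


def _as_path(path, mkdir: bool = False) -> Path:
    p = Path(path)
    if mkdir:
        p.parent.mkdir(parents=True, exist_ok=True)
    return p


def require_same_affine(a: np.ndarray, b: np.ndarray, what: str = "volumes") -> None:
    if not np.allclose(a, b, atol=1e-4):
        raise FormatError(f"affine mismatch between {what}:\n{a}\nvs\n{b}")


def save_nifti(path, data: np.ndarray, affine: np.ndarray, dtype=None) -> Path:
    path = _as_path(path, mkdir=True)
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=np.float64))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    path = _as_path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # noqa: BLE001 - translate to a format error
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    if affine is None:
        raise FormatError(f"NIfTI {path} has no affine")
    return data, np.asarray(affine, dtype=np.float64)


def save_gifti_mesh(path, vertices: np.ndarray, faces: np.ndarray) -> Path:
    path = _as_path(path, mkdir=True)
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                np.asarray(vertices, dtype=np.float32),
                intent="NIFTI_INTENT_POINTSET",
                datatype="NIFTI_TYPE_FLOAT32",
            ),
            nib.gifti.GiftiDataArray(
                np.asarray(faces, dtype=np.int32),
                intent="NIFTI_INTENT_TRIANGLE",
                datatype="NIFTI_TYPE_INT32",
            ),
        ]
    )
    nib.save(img, str(path))
    return path


def load_gifti_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    path = _as_path(path)
    try:
        img = nib.load(str(path))
        arrays = {d.intent: d.data for d in img.darrays}
        verts = arrays[nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]]
        faces = arrays[nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]]
    except FormatError:
        raise
    except KeyError as exc:
        raise FormatError(f"GIFTI {path} lacks a pointset/triangle array") from exc
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read GIFTI mesh {path}: {exc}") from exc
    return np.asarray(verts, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def save_gifti_data(path, data: np.ndarray, labels: bool = False) -> Path:
    """Per-vertex data: integer label map or a vertices x T float series."""
    path = _as_path(path, mkdir=True)
    data = np.asarray(data)
    if labels:
        darr = nib.gifti.GiftiDataArray(
            data.astype(np.int32), intent="NIFTI_INTENT_LABEL", datatype="NIFTI_TYPE_INT32"
        )
    else:
        # GIFTI's conforming float type is float32: round trips are exact to
        # relative 1e-6, not bit-for-bit
        darr = nib.gifti.GiftiDataArray(
            data.astype(np.float32),
            intent="NIFTI_INTENT_NONE",
            datatype="NIFTI_TYPE_FLOAT32",
            encoding="GIFTI_ENCODING_B64GZ",
        )
    nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))
    return path


def load_gifti_data(path) -> np.ndarray:
    path = _as_path(path)
    try:
        img = nib.load(str(path))
        if not img.darrays:
            raise FormatError(f"GIFTI {path} contains no data arrays")
        return np.asarray(img.darrays[0].data)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read GIFTI data {path}: {exc}") from exc


def save_tsv(path, frame: pd.DataFrame) -> Path:
    path = _as_path(path, mkdir=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def load_tsv(path) -> pd.DataFrame:
    path = _as_path(path)
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read TSV {path}: {exc}") from exc


def save_sparse(path, matrix) -> Path:
    """Sparse matrix as MatrixMarket coordinate (triplet) text."""
    path = _as_path(path, mkdir=True)
    scipy_io.mmwrite(str(path), sparse.coo_matrix(matrix))
    return path


def load_sparse(path) -> sparse.csr_matrix:
    path = _as_path(path)
    try:
        return sparse.csr_matrix(scipy_io.mmread(str(path)))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read sparse matrix {path}: {exc}") from exc


def save_json(path, obj) -> Path:
    path = _as_path(path, mkdir=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_json(path):
    path = _as_path(path)
    try:
        return json.loads(path.read_text())
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read JSON {path}: {exc}") from exc
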