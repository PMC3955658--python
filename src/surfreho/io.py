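"""File formats: meshes, per-vertex data, motion traces, volumes, sidecars.

Supported formats
-----------------
* Surface meshes: GIfTI surface files (``.gii``, via nibabel) and a plain
  text dialect -- a header line ``V F`` followed by ``V`` lines ``x y z``
  and ``F`` lines ``i j k`` (0-based vertex indices).
* Per-vertex data (maps or time series): GIfTI functional files or
  whitespace-delimited text (rows = vertices, columns = frames).
* Motion traces: 6-column whitespace text, one row per frame (3 translations
  in mm, 3 rotations in radians).
* Nuisance series: 2-column text (white-matter mean, CSF mean).
* Volumes: NIfTI-1 with the affine honored.
* Provenance/report sidecars: JSON.

All writers round-trip: reading a written text file recovers the values
exactly (text output uses full double precision).  GIfTI stores floating
data as float32, the format's conforming type, so GIfTI round-trips are
exact for values representable in single precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .mesh import SurfaceMesh

_FMT = "%.17g"


def _is_gifti(path) -> bool:
    return str(path).endswith(".gii")


# ---------------------------------------------------------------------------
# meshes

def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if _is_gifti(path):
        coords = nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET",
            datatype="NIFTI_TYPE_FLOAT32")
        faces = nib.gifti.GiftiDataArray(
            mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE",
            datatype="NIFTI_TYPE_INT32")
        nib.save(nib.gifti.GiftiImage(darrays=[coords, faces]), path)
    else:
        with open(path, "w") as fh:
            fh.write(f"{mesh.n_vertices} {mesh.n_triangles}\n")
            np.savetxt(fh, mesh.vertices, fmt=_FMT)
            np.savetxt(fh, mesh.triangles, fmt="%d")


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if _is_gifti(path):
        img = nib.load(path)
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, np.int64))
    with open(path) as fh:
        header = fh.readline().split()
        n_v, n_f = int(header[0]), int(header[1])
        body = np.loadtxt(fh, ndmin=2)
    if body.shape[0] != n_v + n_f:
        raise ValueError(f"mesh file {path}: expected {n_v + n_f} body rows")
    return SurfaceMesh(body[:n_v], body[n_v:].astype(np.int64))


# ---------------------------------------------------------------------------
# per-vertex data

def write_vertex_data(values: np.ndarray, path, meta: dict | None = None) -> None:
    """Write a per-vertex map (V,) or time-series matrix (V, T)."""
    values = np.asarray(values, dtype=np.float64)
    path = Path(path)
    if _is_gifti(path):
        mat = values if values.ndim == 2 else values[:, None]
        darrays = [
            nib.gifti.GiftiDataArray(
                np.ascontiguousarray(mat[:, t], dtype=np.float32),
                intent="NIFTI_INTENT_NONE", datatype="NIFTI_TYPE_FLOAT32")
            for t in range(mat.shape[1])
        ]
        img = nib.gifti.GiftiImage(darrays=darrays)
        if meta:
            for k, v in meta.items():
                img.meta[str(k)] = str(v)
        nib.save(img, path)
    else:
        np.savetxt(path, values, fmt=_FMT)
        if meta:
            write_json(meta, path.with_suffix(path.suffix + ".json"))


def read_vertex_data(path) -> np.ndarray:
    """Read per-vertex data; returns (V,) for a map, (V, T) for a series."""
    path = Path(path)
    if _is_gifti(path):
        img = nib.load(path)
        cols = [np.asarray(d.data, dtype=np.float64) for d in img.darrays]
        out = np.column_stack(cols)
        return out[:, 0] if out.shape[1] == 1 else out
    return np.loadtxt(path)


# ---------------------------------------------------------------------------
# motion / nuisance traces

def write_motion(trace: np.ndarray, path) -> None:
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be (frames, 6)")
    np.savetxt(path, trace, fmt=_FMT)


def read_motion(path) -> np.ndarray:
    trace = np.loadtxt(path, ndmin=2)
    if trace.shape[1] != 6:
        raise ValueError(f"motion file {path}: expected 6 columns")
    return trace


def write_nuisance(wm: np.ndarray, csf: np.ndarray, path) -> None:
    np.savetxt(path, np.column_stack([wm, csf]), fmt=_FMT)


def read_nuisance(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"nuisance file {path}: expected 2 columns (WM, CSF)")
    return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# volumes

def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(path)
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


# ---------------------------------------------------------------------------
# json sidecars

def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
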