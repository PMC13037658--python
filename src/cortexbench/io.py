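"""Readers and writers: OFF/GIFTI surfaces, delimited tables, JSON sidecars.

Numeric tables are plain tab-delimited text written at full double precision
(%.17g), so write -> read round-trips are exact; each table may carry a JSON
sidecar (same stem, .json extension) holding its metadata. Surface writers
preserve vertex order bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import LeadField, SensorArray
from .inversion import EvokedData
from .mesh import Mesh
from .shape import ShapeBasis, SignVector, Trajectory

_FMT = "%.17g"


class MeshParseError(ValueError):
    """Raised when a surface file cannot be parsed."""


# ---------------------------------------------------------------- surfaces


def write_mesh(mesh: Mesh, path: str | Path) -> None:
    """Write a mesh as ASCII OFF (.off) or GIFTI surface (.gii)."""
    path = Path(path)
    if path.suffix == ".off":
        lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} 0"]
        lines += [
            " ".join(_FMT % x for x in v) for v in mesh.vertices
        ]
        lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix == ".gii":
        import nibabel as nib

        pts = nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float64),
            intent="NIFTI_INTENT_POINTSET",
            datatype="NIFTI_TYPE_FLOAT64",
        )
        tris = nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32),
            intent="NIFTI_INTENT_TRIANGLE",
            datatype="NIFTI_TYPE_INT32",
        )
        img = nib.gifti.GiftiImage(darrays=[pts, tris])
        # float64 pointsets keep the round trip exact; "force" lets nibabel
        # write them even though the GIFTI standard nominally wants float32
        img.to_file_map({"image": nib.FileHolder(filename=str(path))}, mode="force")
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r} (use .off or .gii)")


def _parse_off(text: str, name: str) -> Mesh:
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise MeshParseError(f"{name}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
    except (IndexError, ValueError) as err:
        raise MeshParseError(f"{name}: malformed element counts") from err
    pos = 4  # header keyword + 3 counts
    need = nv * 3
    try:
        verts = np.array([float(t) for t in tokens[pos : pos + need]]).reshape(nv, 3)
    except ValueError as err:
        raise MeshParseError(f"{name}: malformed vertex coordinates") from err
    if len(tokens) < pos + need:
        raise MeshParseError(f"{name}: truncated vertex list")
    pos += need
    faces = []
    for i in range(nf):
        try:
            k = int(tokens[pos])
        except (IndexError, ValueError) as err:
            raise MeshParseError(f"{name}: malformed face {i}") from err
        if k != 3:
            raise MeshParseError(f"{name}: face {i} is not a triangle")
        try:
            idx = [int(t) for t in tokens[pos + 1 : pos + 4]]
        except ValueError as err:
            raise MeshParseError(f"{name}: malformed face index in face {i}") from err
        if len(idx) < 3 or any(not 0 <= j < nv for j in idx):
            raise MeshParseError(f"{name}: face index out of range in face {i}")
        faces.append(idx)
        pos += 4
    return Mesh(vertices=verts, faces=np.asarray(faces, dtype=np.int64).reshape(nf, 3))


def read_mesh(path: str | Path) -> Mesh:
    """Read a surface from ASCII OFF (.off) or GIFTI (.gii)."""
    path = Path(path)
    if path.suffix == ".off":
        return _parse_off(path.read_text(), path.name)
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        pts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
        tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
        if not pts or not tris:
            raise MeshParseError(f"{path.name}: missing pointset or triangle array")
        return Mesh(
            vertices=np.asarray(pts[0].data, dtype=np.float64),
            faces=np.asarray(tris[0].data, dtype=np.int64),
        )
    raise ValueError(f"unsupported mesh format {path.suffix!r} (use .off or .gii)")


# ----------------------------------------------------------------- tables


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_table(array: np.ndarray, path: str | Path, sidecar: dict | None = None) -> None:
    """Tab-delimited full-precision numeric table, optional JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.atleast_2d(array), fmt=_FMT, delimiter="\t")
    if sidecar is not None:
        save_json(_sidecar(path), sidecar)


def load_table(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta = load_json(_sidecar(path)) if _sidecar(path).exists() else {}
    return arr, meta


# ----------------------------------------------------- domain serialization


def save_basis(basis: ShapeBasis, path: str | Path) -> None:
    flat = basis.fields.reshape(basis.K, -1)
    save_table(
        flat,
        path,
        sidecar=dict(
            kind="shape_basis",
            K=basis.K,
            n_vertices=basis.n_vertices,
            size_components=list(basis.size_components),
            global_scale=basis.global_scale,
            seed=basis.seed,
            calibration_target_mm=basis.calibration_target_mm,
        ),
    )


def load_basis(path: str | Path) -> ShapeBasis:
    arr, meta = load_table(path)
    if meta.get("kind") != "shape_basis":
        raise ValueError(f"{path}: not a shape-basis table")
    K, nv = int(meta["K"]), int(meta["n_vertices"])
    return ShapeBasis(
        fields=arr.reshape(K, nv, 3),
        size_components=tuple(meta["size_components"]),
        global_scale=float(meta["global_scale"]),
        seed=int(meta["seed"]),
        calibration_target_mm=float(meta["calibration_target_mm"]),
    )


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    save_table(
        traj.steps,
        path,
        sidecar=dict(
            kind="trajectory",
            seed=traj.sign_vector.seed,
            size_components=list(traj.sign_vector.size_components),
            Z=traj.Z,
            N=traj.N,
        ),
    )


def load_trajectory(path: str | Path) -> Trajectory:
    arr, meta = load_table(path)
    if meta.get("kind") != "trajectory":
        raise ValueError(f"{path}: not a trajectory table")
    N = int(meta["N"])
    mid = (N + 1) // 2
    sign = np.sign(arr[-1]).astype(np.int8)
    sv = SignVector(
        s=sign,
        seed=int(meta["seed"]),
        size_components=tuple(meta["size_components"]),
    )
    return Trajectory(sign_vector=sv, Z=float(meta["Z"]), N=N, steps=arr)


def save_leadfield(L: LeadField, path: str | Path, extra: dict | None = None) -> None:
    meta = dict(
        kind="leadfield",
        units=L.units,
        channel_labels=list(L.channel_labels),
        n_sources=L.n_sources,
        permuted=L.permuted,
        permutation_seed=L.permutation_seed,
    )
    if extra:
        meta.update(extra)
    save_table(L.matrix, path, sidecar=meta)


def load_leadfield(path: str | Path) -> LeadField:
    arr, meta = load_table(path)
    if meta.get("kind") != "leadfield":
        raise ValueError(f"{path}: not a lead-field table")
    return LeadField(
        matrix=arr,
        channel_labels=list(meta["channel_labels"]),
        units=meta.get("units", "fT/nAm"),
        permuted=bool(meta.get("permuted", False)),
        permutation_seed=meta.get("permutation_seed"),
    )


def save_sensors(sensors: SensorArray, path: str | Path) -> None:
    df = pd.DataFrame(
        dict(
            x=sensors.positions[:, 0],
            y=sensors.positions[:, 1],
            z=sensors.positions[:, 2],
            ox=sensors.orientations[:, 0],
            oy=sensors.orientations[:, 1],
            oz=sensors.orientations[:, 2],
            label=sensors.labels,
        )
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def load_sensors(path: str | Path) -> SensorArray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return SensorArray(
        positions=df[["x", "y", "z"]].to_numpy(dtype=np.float64),
        orientations=df[["ox", "oy", "oz"]].to_numpy(dtype=np.float64),
        labels=[str(x) for x in df["label"]],
    )


def save_evoked(data: EvokedData, path: str | Path) -> None:
    save_table(
        data.Y,
        path,
        sidecar=dict(
            kind="evoked",
            sfreq=data.sfreq,
            n_trials_averaged=data.n_trials_averaged,
            channel_labels=list(data.channel_labels),
            metadata=data.metadata,
        ),
    )


def load_evoked(path: str | Path) -> EvokedData:
    arr, meta = load_table(path)
    if meta.get("kind") != "evoked":
        raise ValueError(f"{path}: not an evoked-data table")
    return EvokedData(
        Y=arr,
        sfreq=float(meta["sfreq"]),
        n_trials_averaged=int(meta["n_trials_averaged"]),
        channel_labels=list(meta["channel_labels"]),
        metadata=meta.get("metadata", {}),
    )
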