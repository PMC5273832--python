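"""File I/O: NIfTI volumes, STL / PLY meshes, cohort CSV tables.

Volumes are stored as NIfTI-1 (via nibabel) with spacing and origin carried
in the affine.  Meshes use STL (binary or ASCII) for geometry and an ASCII
PLY with one float scalar per vertex for the signed-distance color maps.
Cohort tables round-trip through a flat one-row-per-joint CSV with the
owning patient's clinical columns replicated; missing cells are ``NA``.
"""

from __future__ import annotations

import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import MaskVolume, VoxelVolume
from .mesh import SurfaceMesh
from .records import (
    JOINT_COLUMNS,
    PATIENT_COLUMNS,
    CohortTable,
    JointRecord,
    PatientRecord,
)

# ---------------------------------------------------------------------------
# volumes (NIfTI-1)
# ---------------------------------------------------------------------------


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path, as_mask: bool = False) -> VoxelVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError(f"{path}: missing or invalid voxel spacing in affine")
    data = np.asanyarray(img.dataobj)
    cls = MaskVolume if as_mask else VoxelVolume
    return cls(data=data, spacing=spacing, origin=affine[:3, 3].copy())


# ---------------------------------------------------------------------------
# STL meshes
# ---------------------------------------------------------------------------


def _weld(triangles: np.ndarray) -> SurfaceMesh:
    """Build an indexed mesh from (M, 3, 3) triangle soup by welding vertices."""
    flat = triangles.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return SurfaceMesh(vertices, faces).drop_degenerate_faces()


def write_mesh(mesh: SurfaceMesh, path: str | Path, ascii_format: bool = False) -> None:
    """Write an STL file (binary by default; ``ascii_format`` for text STL)."""
    path = Path(path)
    tri = mesh.triangles().astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if ascii_format:
        lines = ["solid tmjmorph"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid tmjmorph")
        path.write_text("\n".join(lines) + "\n")
        return
    with open(path, "wb") as fh:
        fh.write(b"tmjmorph binary STL".ljust(80, b" "))
        fh.write(struct.pack("<I", len(tri)))
        record = np.zeros(len(tri), dtype=_BINARY_STL_DTYPE)
        record["normal"] = normals
        record["v"] = tri
        fh.write(record.tobytes())


_BINARY_STL_DTYPE = np.dtype(
    [("normal", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
)


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read an STL file, auto-detecting ASCII vs binary encoding."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise ValueError(f"{path}: too short to be an STL file")
    if raw.lstrip().startswith(b"solid"):
        try:
            text = raw.decode("ascii")
        except UnicodeDecodeError:
            text = None
        if text is not None and "facet" in text:
            return _read_ascii_stl(text, path)
        if text is not None and "endsolid" in text:  # empty ASCII solid
            return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    return _read_binary_stl(raw, path)


def _read_ascii_stl(text: str, path: Path) -> SurfaceMesh:
    vertices: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if tokens[:1] == ["vertex"]:
            if len(tokens) != 4:
                raise ValueError(f"{path}:{lineno}: malformed vertex record {line.strip()!r}")
            try:
                vertices.append([float(t) for t in tokens[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric vertex {line.strip()!r}") from exc
    if len(vertices) % 3 != 0:
        raise ValueError(f"{path}: vertex count {len(vertices)} is not a multiple of 3")
    tri = np.array(vertices, dtype=np.float32).reshape(-1, 3, 3)
    return _weld(tri)


def _read_binary_stl(raw: bytes, path: Path) -> SurfaceMesh:
    if len(raw) < 84:
        raise ValueError(f"{path}: truncated binary STL header")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + count * _BINARY_STL_DTYPE.itemsize
    if len(raw) < expected:
        raise ValueError(
            f"{path}: binary STL declares {count} facets but holds "
            f"{(len(raw) - 84) // _BINARY_STL_DTYPE.itemsize}"
        )
    record = np.frombuffer(raw, dtype=_BINARY_STL_DTYPE, count=count, offset=84)
    return _weld(record["v"].astype(np.float32))


# ---------------------------------------------------------------------------
# PLY with one float scalar per vertex (color-map export)
# ---------------------------------------------------------------------------


def write_scalar_mesh(mesh: SurfaceMesh, path: str | Path, scalar_name: str = "signed_distance") -> None:
    """Write an ASCII PLY carrying the mesh plus a per-vertex scalar channel."""
    scalars = mesh.vertex_scalars
    if scalars is None:
        scalars = np.zeros(len(mesh))
    header = [
        "ply",
        "format ascii 1.0",
        "comment tmjmorph per-vertex scalar mesh",
        f"element vertex {len(mesh)}",
        "property float x",
        "property float y",
        "property float z",
        f"property float {scalar_name}",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines = header[:]
    for v, s in zip(mesh.vertices, scalars):
        lines.append(f"{v[0]:.7g} {v[1]:.7g} {v[2]:.7g} {s:.7g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scalar_mesh(path: str | Path) -> SurfaceMesh:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vert = n_face = None
    body_at = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if tokens[:2] == ["element", "vertex"]:
            n_vert = int(tokens[2])
        elif tokens[:2] == ["element", "face"]:
            n_face = int(tokens[2])
        elif tokens[:1] == ["end_header"]:
            body_at = i + 1
            break
    if body_at is None or n_vert is None or n_face is None:
        raise ValueError(f"{path}: incomplete PLY header")
    vert_rows = lines[body_at : body_at + n_vert]
    face_rows = lines[body_at + n_vert : body_at + n_vert + n_face]
    if len(vert_rows) != n_vert or len(face_rows) != n_face:
        raise ValueError(f"{path}: body shorter than declared element counts")
    data = np.array([[float(t) for t in r.split()] for r in vert_rows])
    faces = np.array([[int(t) for t in r.split()[1:4]] for r in face_rows], dtype=int) if n_face else np.zeros((0, 3), int)
    scalars = data[:, 3] if data.shape[1] > 3 else None
    return SurfaceMesh(data[:, :3], faces, scalars)


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = JOINT_COLUMNS + [c for c in PATIENT_COLUMNS if c not in ("patient_id", "group")]


def export_cohort_csv(table: CohortTable, path: str | Path) -> None:
    jf = table.joints_frame()
    pf = table.patients_frame().drop(columns=["group", "joint_ids"])
    merged = jf.merge(pf, on="patient_id", how="left", validate="many_to_one")
    merged[_CSV_COLUMNS].to_csv(path, index=False, na_rep="NA")


def import_cohort_csv(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")

    def val(row, col):
        return CohortTable.nan_to_none(row[col])

    joints, patients, seen = [], {}, {}
    for _, row in df.iterrows():
        joints.append(
            JointRecord(
                joint_id=int(row["joint_id"]),
                group=str(row["group"]),
                condyle_dsi=val(row, "condyle_dsi"),
                condyle_rmsd=val(row, "condyle_rmsd"),
                disc_dsi=val(row, "disc_dsi"),
                disc_rmsd=val(row, "disc_rmsd"),
                mxd_t1=val(row, "mxd_t1"),
                mxd_t2=val(row, "mxd_t2"),
            )
        )
        pid = int(row["patient_id"])
        seen.setdefault(pid, []).append(int(row["joint_id"]))
        if pid not in patients:
            patients[pid] = dict(
                patient_id=pid,
                group=str(row["group"]),
                mouth_opening_t1=val(row, "mouth_opening_t1"),
                mouth_opening_t2=val(row, "mouth_opening_t2"),
                jfls_t1=val(row, "jfls_t1"),
                jfls_t2=val(row, "jfls_t2"),
                age=val(row, "age"),
                sex=val(row, "sex"),
                tumor=val(row, "tumor"),
            )
    records = [
        PatientRecord(joint_ids=tuple(seen[pid]), **kw) for pid, kw in patients.items()
    ]
    return CohortTable(patients=records, joints=joints)
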