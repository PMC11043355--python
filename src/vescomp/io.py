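"""Mesh and report I/O: OFF/PLY with a JSON sidecar, legacy-VTK export,
run manifests.

Region labels, solid rest geometry and build metadata do not fit the bare
geometry formats, so every mesh file is accompanied by ``<file>.json``
carrying them; floats are written with 17 significant digits so that a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .mesh import FLUID, SOLID, MeshError, TriangleMesh, \
    vertex_gaussian_curvature, vertex_mean_curvature

_FMT = "%.17g"


def _fmt_row(row) -> str:
    return " ".join(_FMT % v for v in row)


def write_mesh(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write OFF or PLY (by extension) plus the ``.json`` label sidecar."""
    path = Path(path)
    if path.suffix == ".off":
        _write_off(mesh, path)
    elif path.suffix == ".ply":
        _write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    sidecar = {
        "face_region": ["s" if r == SOLID else "f" for r in mesh.face_region],
        "rigid_core": bool(mesh.rigid_core),
    }
    if mesh.rest_lengths is not None:
        sidecar["rest_lengths"] = [[_FMT % v for v in row]
                                   for row in mesh.rest_lengths]
        sidecar["solid_face_index"] = mesh.solid_face_index.tolist()
    meta = {k: v for k, v in mesh.meta.items()
            if isinstance(v, (int, float, str, bool))}
    if meta:
        sidecar["meta"] = meta
    Path(str(path) + ".json").write_text(json.dumps(sidecar))
    return path


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read a mesh written by :func:`write_mesh`; validates closedness."""
    path = Path(path)
    if path.suffix == ".off":
        verts, faces = _read_off(path)
    elif path.suffix == ".ply":
        verts, faces = _read_ply(path)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise MeshError(f"missing region sidecar {sidecar_path.name} "
                        "(face_region labels are required)")
    sc = json.loads(sidecar_path.read_text())
    if "face_region" not in sc:
        raise MeshError("sidecar lacks the required 'face_region' property")
    region = np.array([SOLID if r == "s" else FLUID for r in sc["face_region"]],
                      dtype=object)
    if len(region) != len(faces):
        raise MeshError("face_region length does not match face count")
    rest = None
    sfi = None
    if "rest_lengths" in sc:
        rest = np.array([[float(v) for v in row] for row in sc["rest_lengths"]])
        sfi = np.asarray(sc["solid_face_index"], dtype=np.int64)
    mesh = TriangleMesh(verts, faces, region, rest_lengths=rest,
                        solid_face_index=sfi,
                        rigid_core=bool(sc.get("rigid_core", False)),
                        meta=dict(sc.get("meta", {})))
    mesh.validate()
    return mesh


def _write_off(mesh: TriangleMesh, path: Path) -> None:
    lines = ["OFF", f"{mesh.n_vertices} {len(mesh.faces)} 0"]
    lines += [_fmt_row(v) for v in mesh.vertices]
    lines += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


def _read_off(path: Path) -> tuple[np.ndarray, np.ndarray]:
    tokens = path.read_text().split()
    if tokens[0] != "OFF":
        raise MeshError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    p = 4
    verts = np.array(tokens[p:p + 3 * nv], float).reshape(nv, 3)
    p += 3 * nv
    faces = np.empty((nf, 3), np.int64)
    for i in range(nf):
        if tokens[p] != "3":
            raise MeshError("non-triangular face in OFF file")
        faces[i] = [int(t) for t in tokens[p + 1:p + 4]]
        p += 4
    return verts, faces


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    head = ["ply", "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            "property double x", "property double y", "property double z",
            f"element face {len(mesh.faces)}",
            "property list uchar int vertex_indices", "end_header"]
    body = [_fmt_row(v) for v in mesh.vertices]
    body += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    path.write_text("\n".join(head + body) + "\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    lines = path.read_text().splitlines()
    if lines[0].strip() != "ply":
        raise MeshError("not a PLY file")
    nv = nf = None
    i = 0
    for i, line in enumerate(lines):
        t = line.split()
        if t[:2] == ["element", "vertex"]:
            nv = int(t[2])
        elif t[:2] == ["element", "face"]:
            nf = int(t[2])
        elif t[0] == "format" and t[1] != "ascii":
            raise MeshError("only ascii PLY is supported")
        elif t[0] == "end_header":
            break
    if nv is None or nf is None:
        raise MeshError("malformed PLY header")
    verts = np.array([lines[i + 1 + k].split() for k in range(nv)], float)
    faces = np.array([lines[i + 1 + nv + k].split()[1:4] for k in range(nf)],
                     np.int64)
    return verts, faces


def write_vtk(mesh: TriangleMesh, path: str | Path,
              with_curvatures: bool = True) -> Path:
    """Legacy-ASCII VTK polydata with per-vertex H and K_G fields."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "vescomp surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {mesh.n_vertices} double"]
    lines += [_fmt_row(v) for v in mesh.vertices]
    nf = len(mesh.faces)
    lines.append(f"POLYGONS {nf} {4 * nf}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in mesh.faces]
    lines.append(f"CELL_DATA {nf}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += ["1" if r == SOLID else "0" for r in mesh.face_region]
    if with_curvatures:
        h = vertex_mean_curvature(mesh)
        k = vertex_gaussian_curvature(mesh)
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in (("mean_curvature", h), ("gaussian_curvature", k)):
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [_FMT % v for v in arr]
    path.write_text("\n".join(lines) + "\n")
    return path


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Manifest of every artifact in ``out_dir`` with checksums."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    from . import __version__
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "files": {str(p.relative_to(out_dir)): sha256_of(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
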