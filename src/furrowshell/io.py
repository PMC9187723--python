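"""File formats: meshes with per-facet fields, tables, trajectories, configs.

Meshes travel as ASCII PLY (with the mechanical per-facet fields A_i, A_0,
region and row_distance as face properties), geometry-only OFF, or legacy
ASCII VTK PolyData (fields as CELL_DATA arrays, convenient for ParaView).
Tables are UTF-8 comma-separated CSV with a header row and '.' decimal;
parameter sets are JSON/YAML.  Coordinates are stored in code (nondimensional)
units; the physical scale lives in the config metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    EmbryoMesh,
    GeometryParams,
    MesodermExtent,
)

__all__ = [
    "write_mesh_ply",
    "read_mesh_ply",
    "write_mesh_off",
    "write_mesh_vtk",
    "read_mesh_vtk",
    "write_table",
    "read_table",
    "RunConfig",
    "sha256_of",
]

_FACE_FIELDS = ("reference_area", "target_area", "region", "row_distance")

TRACKING_COLUMNS = (
    "cell_id",
    "time",
    "row_index",
    "dv_distance",
    "apical_area",
    "len_AP",
    "len_DV",
    "intensity",
)


# --------------------------------------------------------------------------- #
# PLY with per-face fields
# --------------------------------------------------------------------------- #
def write_mesh_ply(path, mesh: EmbryoMesh, vertices: np.ndarray | None = None) -> None:
    """ASCII PLY with the per-facet mechanical fields as face properties."""
    v = mesh.vertices if vertices is None else np.asarray(vertices)
    lines = [
        "ply",
        "format ascii 1.0",
        "comment furrowshell embryo mesh",
        f"element vertex {len(v)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "property double reference_area",
        "property double target_area",
        "property int region",
        "property double row_distance",
        "end_header",
    ]
    out = ["\n".join(lines)]
    out.append("\n".join(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in v))
    rows = []
    for i, f in enumerate(mesh.faces):
        rows.append(
            f"3 {f[0]} {f[1]} {f[2]} {mesh.reference_area[i]:.17g} "
            f"{mesh.target_area[i]:.17g} {int(mesh.region[i])} {mesh.row_distance[i]:.17g}"
        )
    out.append("\n".join(rows))
    Path(path).write_text("\n".join(out) + "\n")


def read_mesh_ply(path, params: GeometryParams | None = None) -> EmbryoMesh:
    """Read an ASCII PLY written by :func:`write_mesh_ply`."""
    text = Path(path).read_text().splitlines()
    it = iter(enumerate(text))
    n_v = n_f = None
    header_end = None
    for i, line in it:
        tok = line.split()
        if tok[:2] == ["element", "vertex"]:
            n_v = int(tok[2])
        elif tok[:2] == ["element", "face"]:
            n_f = int(tok[2])
        elif tok == ["end_header"]:
            header_end = i
            break
    if n_v is None or n_f is None or header_end is None:
        raise ValueError(f"{path}: malformed PLY header")
    body = text[header_end + 1 :]
    if len(body) < n_v + n_f:
        raise ValueError(
            f"{path}: truncated PLY body at line {header_end + 1 + len(body)}"
        )
    verts = np.array([[float(x) for x in body[i].split()] for i in range(n_v)])
    faces = np.empty((n_f, 3), dtype=int)
    fields = {k: np.empty(n_f) for k in _FACE_FIELDS}
    for j in range(n_f):
        tok = body[n_v + j].split()
        if tok[0] != "3" or len(tok) != 8:
            raise ValueError(f"{path}: malformed face record at body line {n_v + j}")
        faces[j] = [int(t) for t in tok[1:4]]
        fields["reference_area"][j] = float(tok[4])
        fields["target_area"][j] = float(tok[5])
        fields["region"][j] = int(tok[6])
        fields["row_distance"][j] = float(tok[7])
    return EmbryoMesh(
        vertices=verts,
        faces=faces,
        reference_area=fields["reference_area"],
        target_area=fields["target_area"],
        region=fields["region"].astype(np.int8),
        row_distance=fields["row_distance"],
        params=params or GeometryParams(),
    )


def write_mesh_off(path, mesh: EmbryoMesh, vertices: np.ndarray | None = None) -> None:
    """Geometry-only OFF export."""
    v = mesh.vertices if vertices is None else np.asarray(vertices)
    lines = ["OFF", f"{len(v)} {mesh.n_faces} 0"]
    lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in v]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------- #
# legacy VTK PolyData
# --------------------------------------------------------------------------- #
def write_mesh_vtk(
    path,
    mesh: EmbryoMesh,
    vertices: np.ndarray | None = None,
    extra_cell_data: dict | None = None,
) -> None:
    """Legacy ASCII VTK PolyData with per-facet fields as CELL_DATA arrays."""
    v = mesh.vertices if vertices is None else np.asarray(vertices)
    parts = [
        "# vtk DataFile Version 3.0",
        "furrowshell embryo surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} double",
    ]
    parts += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in v]
    parts.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    parts += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    cell_data = {
        "reference_area": mesh.reference_area,
        "target_area": mesh.target_area,
        "region": mesh.region,
        "row_distance": mesh.row_distance,
    }
    if extra_cell_data:
        cell_data.update(extra_cell_data)
    parts.append(f"CELL_DATA {mesh.n_faces}")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        parts.append(f"SCALARS {name} {kind} 1")
        parts.append("LOOKUP_TABLE default")
        fmt = (lambda x: str(int(x))) if kind == "int" else (lambda x: f"{x:.17g}")
        parts += [fmt(x) for x in arr]
    Path(path).write_text("\n".join(parts) + "\n")


def read_mesh_vtk(path):
    """Read vertices, faces and CELL_DATA arrays from a legacy VTK file."""
    lines = Path(path).read_text().split("\n")
    i = 0

    def expect(prefix):
        nonlocal i
        while i < len(lines) and not lines[i].startswith(prefix):
            i += 1
        if i >= len(lines):
            raise ValueError(f"{path}: missing '{prefix}' section")
        return lines[i]

    head = expect("POINTS").split()
    n_v = int(head[1])
    verts = np.array(
        [[float(x) for x in lines[i + 1 + j].split()] for j in range(n_v)]
    )
    i += n_v
    head = expect("POLYGONS").split()
    n_f = int(head[1])
    faces = np.array(
        [[int(x) for x in lines[i + 1 + j].split()[1:]] for j in range(n_f)]
    )
    i += n_f
    cell_data = {}
    try:
        expect("CELL_DATA")
    except ValueError:
        return verts, faces, cell_data
    while True:
        try:
            head = expect("SCALARS").split()
        except ValueError:
            break
        name, kind = head[1], head[2]
        i += 2  # skip LOOKUP_TABLE
        vals = [lines[i + j].strip() for j in range(n_f)]
        cell_data[name] = np.array(
            [int(x) for x in vals] if kind == "int" else [float(x) for x in vals]
        )
        i += n_f
    return verts, faces, cell_data


# --------------------------------------------------------------------------- #
# tables
# --------------------------------------------------------------------------- #
def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_table(path, required_columns=None) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if required_columns is not None:
        missing = set(required_columns) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --------------------------------------------------------------------------- #
# run configuration
# --------------------------------------------------------------------------- #
@dataclasses.dataclass
class RunConfig:
    """Validated, serialisable configuration of a full pipeline run."""

    schema_version: int = 1
    # geometry
    ap_dv_ratio: float = 3.0
    dissymmetry: float = 0.15
    subdivisions: int = 4
    n_dv_cells: int = 80
    dv_arc_fraction: float = 1.0 / 6.0
    ap_arc_fraction: float = 1.0 / 3.0
    gap: float = 0.004
    # elasticity
    chi_tilde: float = 50.0
    nu: float = 0.0
    bending_modulus: float = 1.0
    # pre-strain profile and ramp
    profile_r0: float = 4.0
    profile_p: float = 2.0
    ramp: tuple = (0.0, 0.43)
    tolerance: float = 1e-3
    # analysis
    ap_stations: tuple = (0.0, 0.75, 1.5)
    # bookkeeping
    out_dir: str = "run_output"
    seed: int = 0
    log_level: str = "INFO"
    length_scale_um: float = 90.0  # physical DV semi-axis

    def geometry_params(self) -> GeometryParams:
        return GeometryParams(
            ap_dv_ratio=self.ap_dv_ratio,
            dissymmetry=self.dissymmetry,
            subdivisions=self.subdivisions,
            n_dv_cells=self.n_dv_cells,
            mesoderm_extent=MesodermExtent(
                dv_arc_fraction=self.dv_arc_fraction,
                ap_arc_fraction=self.ap_arc_fraction,
            ),
        )

    def elastic_params(self):
        from .shell_solver import ElasticParams

        return ElasticParams(
            chi_tilde=self.chi_tilde, nu=self.nu, bending_modulus=self.bending_modulus
        )

    def validate(self) -> "RunConfig":
        if self.schema_version != 1:
            raise ValueError(f"unsupported config schema version {self.schema_version}")
        self.geometry_params()
        self.elastic_params()
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        if len(self.ramp) < 1 or any(
            b < a for a, b in zip(self.ramp, self.ramp[1:])
        ):
            raise ValueError("ramp must be a non-decreasing sequence")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ramp"] = list(self.ramp)
        d["ap_stations"] = list(self.ap_stations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("ramp", "ap_stations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
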