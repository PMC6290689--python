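"""Readers, writers and domain containers for every artifact the pipeline touches.

Canonical formats (fixed by convention, files never carry mixed units):

* surface meshes and cross-section patches — VTK legacy polydata v3.0, ASCII,
  triangles only, per-vertex ``SCALARS``/``VECTORS`` point data;
* metric tables — RFC-4180 CSV with a header row;
* region definitions and cohort manifests — YAML with explicit keys.

Units: coordinates mm, WSS Pa, velocity cm/s, flow mL/s, viscosity cP,
density g/cm^3.  Conversions happen inside operations via exact factors
(1 cP = 1e-3 Pa*s, 1 mL/s = 1e-6 m^3/s).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateKeyError,
    FieldMissingError,
    PlanarityError,
    UnsupportedCellError,
    VelocityAmbiguityError,
)

__all__ = [
    "SurfaceMesh",
    "CrossSectionPatch",
    "ClipPlaneDef",
    "SlicePlaneDef",
    "OutletSliceDef",
    "RegionSet",
    "TeamMeta",
    "MetricsTable",
    "read_surface",
    "write_surface",
    "read_section",
    "write_section",
    "read_metrics_table",
    "write_metrics_table",
    "read_regions",
    "write_regions",
]

EXPERIENCE_LEVELS = ("high", "medium", "low")


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated lumen surface with named per-vertex fields.

    ``points`` are mm coordinates, shape (n, 3); ``triangles`` are vertex
    index triples, shape (m, 3); ``vertex_fields`` maps a name to a scalar
    array (n,) or vector array (n, 3).  The WSS-magnitude field required by
    the sac/parent analysis is named ``"wss"`` and holds Pa.
    """

    points: np.ndarray
    triangles: np.ndarray
    vertex_fields: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.vertex_fields = {k: np.asarray(v, dtype=float)
                              for k, v in self.vertex_fields.items()}
        self.validate()

    def validate(self) -> None:
        n = len(self.points)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                raise ValueError("triangle index out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2])
                      | (t[:, 0] == t[:, 2])):
                raise ValueError("triangle repeats a vertex")
        for name, arr in self.vertex_fields.items():
            if arr.shape[0] != n:
                raise ValueError(
                    f"field {name!r} has {arr.shape[0]} entries for {n} vertices")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def require_field(self, name: str) -> np.ndarray:
        try:
            return self.vertex_fields[name]
        except KeyError:
            raise FieldMissingError(
                f"mesh is missing required vertex field {name!r}") from None

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.points.copy(), self.triangles.copy(),
                           {k: v.copy() for k, v in self.vertex_fields.items()})


@dataclass
class CrossSectionPatch:
    """Planar triangulated lumen cut carrying per-vertex velocity data.

    ``velocity`` holds per-vertex 3-vectors (cm/s) when ``is_magnitude_only``
    is False, otherwise per-vertex magnitudes (cm/s).  ``normal`` is the unit
    plane normal oriented downstream.
    """

    points: np.ndarray
    triangles: np.ndarray
    normal: np.ndarray
    velocity: np.ndarray
    is_magnitude_only: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.velocity = np.asarray(self.velocity, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if abs(nrm - 1.0) > 1e-9:
            self.normal = self.normal / nrm
        want = (self.points.shape[0],) if self.is_magnitude_only \
            else (self.points.shape[0], 3)
        if self.velocity.shape != want:
            raise ValueError(
                f"velocity shape {self.velocity.shape} != expected {want}")


@dataclass
class ClipPlaneDef:
    """Clip plane: keep vertices with ``side * (x - origin) . normal >= 0``."""

    origin: np.ndarray
    normal: np.ndarray
    side: int = 1

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        nrm = np.linalg.norm(self.normal)
        if nrm == 0:
            raise ValueError("zero plane normal")
        if abs(nrm - 1.0) > 1e-9:
            self.normal = self.normal / nrm
        if self.side not in (-1, 1):
            raise ValueError("side must be +1 or -1")


@dataclass
class SlicePlaneDef:
    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = self.normal / np.linalg.norm(self.normal)


@dataclass
class OutletSliceDef:
    label: str
    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = self.normal / np.linalg.norm(self.normal)


@dataclass
class RegionSet:
    """Per-submission region definitions: the same clipping planes are applied
    to every team's co-registered surface.

    ``sac_seed`` / ``parent_seed`` are points (mm) on the kept side of the
    respective plane sets, used to pick the connected component after clipping.
    """

    sac_planes: list[ClipPlaneDef]
    parent_band_planes: list[ClipPlaneDef]
    slice_planes: list[SlicePlaneDef]
    outlet_slices: list[OutletSliceDef]
    dominant_outlet: str
    sac_seed: np.ndarray = None
    parent_seed: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.sac_planes or not self.parent_band_planes:
            raise ValueError("need at least one sac plane and one parent-band plane")
        if not 1 <= len(self.slice_planes) <= 5:
            raise ValueError("slice count must be in 1..5")
        labels = [o.label for o in self.outlet_slices]
        if self.dominant_outlet not in labels:
            raise ValueError(
                f"dominant outlet {self.dominant_outlet!r} not among {labels}")
        if self.sac_seed is not None:
            self.sac_seed = np.asarray(self.sac_seed, dtype=float).reshape(3)
        if self.parent_seed is not None:
            self.parent_seed = np.asarray(self.parent_seed, dtype=float).reshape(3)


_EXPERIENCE_BINS = {"high": "> 100 cases", "medium": "11-100 cases",
                    "low": "<= 10 cases"}


@dataclass
class TeamMeta:
    """Questionnaire-style team/simulation characteristics."""

    team_id: str
    experience: str = "medium"
    temporal_scheme: str = "steady"
    inlet_location: str = "MCA"
    inflow_scaling_exponent: int | str = 2
    viscosity: float = 3.5
    density: float = 1.06

    def __post_init__(self) -> None:
        if self.experience not in EXPERIENCE_LEVELS:
            raise ValueError(
                f"experience must be one of {EXPERIENCE_LEVELS} "
                f"(bins: {_EXPERIENCE_BINS})")
        if self.temporal_scheme not in ("steady", "pulsatile"):
            raise ValueError("temporal_scheme must be steady or pulsatile")
        if self.inlet_location not in ("MCA", "ICA"):
            raise ValueError("inlet_location must be MCA or ICA")


# --------------------------------------------------------------------------
# VTK legacy polydata ASCII
# --------------------------------------------------------------------------

def _fmt_floats(arr: np.ndarray, per_line: int) -> str:
    flat = np.asarray(arr, dtype=float).ravel()
    out = []
    for i in range(0, len(flat), per_line):
        out.append(" ".join(repr(float(v)) for v in flat[i:i + per_line]))
    return "\n".join(out)


def _write_polydata(fh: io.TextIOBase, points: np.ndarray, triangles: np.ndarray,
                    scalars: Mapping[str, np.ndarray],
                    vectors: Mapping[str, np.ndarray], title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write("DATASET POLYDATA\n")
    fh.write(f"POINTS {len(points)} double\n")
    fh.write(_fmt_floats(points, 3) + "\n")
    fh.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
    for t in triangles:
        fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    if scalars or vectors:
        fh.write(f"POINT_DATA {len(points)}\n")
        for name, arr in scalars.items():
            fh.write(f"SCALARS {name} double 1\n")
            fh.write("LOOKUP_TABLE default\n")
            fh.write(_fmt_floats(arr, 9) + "\n")
        for name, arr in vectors.items():
            fh.write(f"VECTORS {name} double\n")
            fh.write(_fmt_floats(arr, 3) + "\n")


class _Tokens:
    """Whitespace token stream over a VTK legacy ASCII body."""

    def __init__(self, text: str):
        # header: line 1 version comment, line 2 free-form title
        lines = text.split("\n", 2)
        if len(lines) < 3 or not lines[0].startswith("# vtk DataFile"):
            raise ValueError("not a VTK legacy DataFile")
        self._toks = lines[2].split()
        self._i = 0

    def next(self) -> str:
        if self._i >= len(self._toks):
            raise ValueError("unexpected end of VTK file")
        tok = self._toks[self._i]
        self._i += 1
        return tok

    def peek(self) -> str | None:
        return self._toks[self._i] if self._i < len(self._toks) else None

    def floats(self, n: int) -> np.ndarray:
        j = self._i + n
        if j > len(self._toks):
            raise ValueError("unexpected end of VTK file")
        out = np.array(self._toks[self._i:j], dtype=float)
        self._i = j
        return out

    def ints(self, n: int) -> np.ndarray:
        j = self._i + n
        if j > len(self._toks):
            raise ValueError("unexpected end of VTK file")
        out = np.array(self._toks[self._i:j], dtype=np.int64)
        self._i = j
        return out


def _read_polydata(path: str | Path):
    text = Path(path).read_text()
    tk = _Tokens(text)
    if tk.next().upper() != "ASCII":
        raise ValueError("only ASCII VTK legacy files are supported")
    if tk.next().upper() != "DATASET" or tk.next().upper() != "POLYDATA":
        raise ValueError("only DATASET POLYDATA is supported")
    points = None
    triangles = None
    scalars: dict[str, np.ndarray] = {}
    vectors: dict[str, np.ndarray] = {}
    n_points = 0
    while (kw := tk.peek()) is not None:
        kw = tk.next().upper()
        if kw == "POINTS":
            n_points = int(tk.next())
            tk.next()  # dtype
            points = tk.floats(3 * n_points).reshape(-1, 3)
        elif kw == "POLYGONS":
            n_poly = int(tk.next())
            size = int(tk.next())
            data = tk.ints(size)
            tris = []
            i = 0
            while i < len(data):
                cnt = int(data[i])
                if cnt != 3:
                    raise UnsupportedCellError(
                        f"polygon with {cnt} vertices; only triangles supported")
                tris.append(data[i + 1:i + 4])
                i += cnt + 1
            if len(tris) != n_poly:
                raise ValueError("POLYGONS count mismatch")
            triangles = np.array(tris, dtype=np.int64).reshape(-1, 3)
        elif kw in ("LINES", "VERTICES", "TRIANGLE_STRIPS"):
            raise UnsupportedCellError(f"unsupported cell block {kw}")
        elif kw == "POINT_DATA":
            n = int(tk.next())
            if n != n_points:
                raise ValueError("POINT_DATA size mismatch")
        elif kw == "SCALARS":
            name = tk.next()
            tk.next()  # dtype
            ncomp = 1
            if tk.peek() not in (None, "LOOKUP_TABLE"):
                ncomp = int(tk.next())
            if tk.peek() == "LOOKUP_TABLE":
                tk.next()
                tk.next()  # table name
            vals = tk.floats(ncomp * n_points)
            scalars[name] = vals if ncomp == 1 else vals.reshape(-1, ncomp)
        elif kw == "VECTORS":
            name = tk.next()
            tk.next()  # dtype
            vectors[name] = tk.floats(3 * n_points).reshape(-1, 3)
        elif kw == "FIELD":
            tk.next()  # field name
            n_arrays = int(tk.next())
            for _ in range(n_arrays):
                name = tk.next()
                ncomp = int(tk.next())
                ntup = int(tk.next())
                tk.next()  # dtype
                vals = tk.floats(ncomp * ntup)
                scalars[name] = vals if ncomp == 1 else vals.reshape(-1, ncomp)
        else:
            raise ValueError(f"unsupported VTK keyword {kw!r}")
    if points is None or triangles is None:
        raise ValueError("VTK file lacks POINTS or POLYGONS")
    return points, triangles, scalars, vectors


def mirror_mesh(mesh: SurfaceMesh, axis: int = 0) -> SurfaceMesh:
    """Flip one coordinate axis and reverse triangle winding.

    A mirrored submission has negated signed volume; reversing the winding
    restores outward orientation, so mirroring twice is the identity and all
    triangle areas are preserved exactly.
    """
    pts = mesh.points.copy()
    pts[:, axis] = -pts[:, axis]
    tris = mesh.triangles[:, [0, 2, 1]].copy()
    return SurfaceMesh(pts, tris, {k: v.copy()
                                   for k, v in mesh.vertex_fields.items()})


def read_surface(path: str | Path, scale_factor: float = 1.0,
                 mirror_axis: int | None = None,
                 require_wss: bool = False) -> SurfaceMesh:
    """Read a VTK legacy polydata surface, rescaling to mm.

    ``scale_factor`` multiplies all coordinates (e.g. 1000 for a mesh stored
    in metres).  ``mirror_axis`` (0/1/2), if given, mirrors the surface about
    that coordinate plane with a winding fix.  With ``require_wss`` a missing
    ``"wss"`` scalar field raises :class:`FieldMissingError`.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    points, triangles, scalars, vectors = _read_polydata(path)
    fields: dict[str, np.ndarray] = {}
    fields.update(scalars)
    fields.update(vectors)
    mesh = SurfaceMesh(points * scale_factor, triangles, fields)
    if mirror_axis is not None:
        mesh = mirror_mesh(mesh, mirror_axis)
    if require_wss:
        mesh.require_field("wss")
    return mesh


def write_surface(mesh: SurfaceMesh, path: str | Path,
                  title: str = "aneuvar surface") -> None:
    scalars = {k: v for k, v in mesh.vertex_fields.items() if v.ndim == 1}
    vectors = {k: v for k, v in mesh.vertex_fields.items() if v.ndim == 2}
    with open(path, "w") as fh:
        _write_polydata(fh, mesh.points, mesh.triangles, scalars, vectors, title)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through points: (centroid, unit normal, max |dist|)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    dist = centered @ normal
    return centroid, normal, float(np.abs(dist).max())


def read_section(path: str | Path, planarity_tol: float = 1e-6,
                 downstream_sign: float | None = None) -> CrossSectionPatch:
    """Read a planar cross-section patch with velocity data.

    The patch must carry exactly one of a ``velocity`` vector field (cm/s) or
    a ``velocity_magnitude`` scalar field.  The plane normal is fitted by
    least squares; with vector data its sign is chosen so the mean
    through-plane velocity is non-negative ("oriented downstream"); with
    magnitude-only data the sign comes from ``downstream_sign`` applied to
    the fitted normal (default +1).

    ``planarity_tol`` is relative to the patch diameter (bounding-box
    diagonal); exceeding it raises :class:`PlanarityError`.
    """
    points, triangles, scalars, vectors = _read_polydata(path)
    has_vec = "velocity" in vectors
    has_mag = "velocity_magnitude" in scalars
    if has_vec == has_mag:
        raise VelocityAmbiguityError(
            "section must carry exactly one of 'velocity' (vectors) or "
            "'velocity_magnitude' (scalars)")
    centroid, normal, max_dist = fit_plane(points)
    diam = float(np.linalg.norm(points.max(axis=0) - points.min(axis=0)))
    if diam > 0 and max_dist > planarity_tol * diam:
        raise PlanarityError(
            f"points deviate {max_dist:.3g} mm from plane "
            f"(tolerance {planarity_tol:.1g} x diameter {diam:.3g} mm)")
    if has_vec:
        vel = vectors["velocity"]
        if float(np.mean(vel @ normal)) < 0:
            normal = -normal
        return CrossSectionPatch(points, triangles, normal, vel,
                                 is_magnitude_only=False)
    sign = 1.0 if downstream_sign is None else float(np.sign(downstream_sign))
    return CrossSectionPatch(points, triangles, sign * normal,
                             scalars["velocity_magnitude"],
                             is_magnitude_only=True)


def write_section(patch: CrossSectionPatch, path: str | Path,
                  title: str = "aneuvar section") -> None:
    scalars = {}
    vectors = {}
    if patch.is_magnitude_only:
        scalars["velocity_magnitude"] = patch.velocity
    else:
        vectors["velocity"] = patch.velocity
    with open(path, "w") as fh:
        _write_polydata(fh, patch.points, patch.triangles, scalars, vectors, title)


# --------------------------------------------------------------------------
# metrics tables (CSV)
# --------------------------------------------------------------------------

_META_COLUMNS = ["experience", "temporal_scheme", "inlet_location",
                 "inflow_scaling_exponent", "viscosity", "density"]
_KEY_COLUMNS = ["team", "case", "parameter"]


@dataclass
class MetricsTable:
    """Long-format (team x case x parameter) value table with team metadata.

    Missing entries are simply absent rows (or NaN values) — representable
    and distinct from zero.  ``meta`` maps team_id -> :class:`TeamMeta`.
    """

    df: pd.DataFrame
    meta: dict[str, TeamMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _KEY_COLUMNS + ["value"] if c not in self.df.columns]
        if missing:
            raise ValueError(f"metrics table missing columns {missing}")
        dup = self.df.duplicated(subset=_KEY_COLUMNS)
        if dup.any():
            rows = self.df.loc[dup, _KEY_COLUMNS].values.tolist()
            raise DuplicateKeyError(f"duplicate (team, case, parameter) rows: {rows[:5]}")

    @property
    def cases(self) -> list[str]:
        return sorted(self.df["case"].unique().tolist())

    @property
    def teams(self) -> list[str]:
        return sorted(self.df["team"].unique().tolist())

    @property
    def parameters(self) -> list[str]:
        return sorted(self.df["parameter"].unique().tolist())

    def value(self, team: str, case: str, parameter: str) -> float:
        sel = self.df[(self.df["team"] == team) & (self.df["case"] == case)
                      & (self.df["parameter"] == parameter)]
        if sel.empty:
            return float("nan")
        return float(sel["value"].iloc[0])

    def pivot(self, parameter: str) -> pd.DataFrame:
        """team x case wide table for one parameter (NaN where missing)."""
        sub = self.df[self.df["parameter"] == parameter]
        return sub.pivot(index="team", columns="case", values="value")

    def experience_of(self, team: str) -> str | None:
        m = self.meta.get(team)
        return m.experience if m is not None else None


def write_metrics_table(table: MetricsTable, path: str | Path) -> None:
    df = table.df.copy()
    for col in _META_COLUMNS:
        if col not in df.columns:
            df[col] = df["team"].map(
                lambda t: getattr(table.meta[t], col) if t in table.meta else None)
    df.to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> MetricsTable:
    df = pd.read_csv(path, dtype={"team": str, "case": str, "parameter": str})
    meta: dict[str, TeamMeta] = {}
    have_meta = all(c in df.columns for c in _META_COLUMNS)
    if have_meta:
        for team, grp in df.groupby("team"):
            row = grp.iloc[0]
            if pd.isna(row["experience"]):
                continue
            exp = row["inflow_scaling_exponent"]
            if not isinstance(exp, str):
                exp = "other" if pd.isna(exp) else int(exp)
            meta[str(team)] = TeamMeta(
                team_id=str(team), experience=str(row["experience"]),
                temporal_scheme=str(row["temporal_scheme"]),
                inlet_location=str(row["inlet_location"]),
                inflow_scaling_exponent=exp,
                viscosity=float(row["viscosity"]),
                density=float(row["density"]))
    keep = [c for c in df.columns if c not in _META_COLUMNS]
    return MetricsTable(df[keep], meta)


# --------------------------------------------------------------------------
# region sets (YAML)
# --------------------------------------------------------------------------

def _plane_to_dict(p: ClipPlaneDef) -> dict:
    return {"origin": [float(v) for v in p.origin],
            "normal": [float(v) for v in p.normal],
            "side": int(p.side)}


def write_regions(regions: RegionSet, path: str | Path) -> None:
    doc = {
        "sac_planes": [_plane_to_dict(p) for p in regions.sac_planes],
        "parent_band_planes": [_plane_to_dict(p) for p in regions.parent_band_planes],
        "slice_planes": [{"origin": [float(v) for v in s.origin],
                          "normal": [float(v) for v in s.normal]}
                         for s in regions.slice_planes],
        "outlet_slices": [{"label": o.label,
                           "origin": [float(v) for v in o.origin],
                           "normal": [float(v) for v in o.normal]}
                          for o in regions.outlet_slices],
        "dominant_outlet": regions.dominant_outlet,
    }
    if regions.sac_seed is not None:
        doc["sac_seed"] = [float(v) for v in regions.sac_seed]
    if regions.parent_seed is not None:
        doc["parent_seed"] = [float(v) for v in regions.parent_seed]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_regions(path: str | Path) -> RegionSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RegionSet(
        sac_planes=[ClipPlaneDef(**p) for p in doc["sac_planes"]],
        parent_band_planes=[ClipPlaneDef(**p) for p in doc["parent_band_planes"]],
        slice_planes=[SlicePlaneDef(**s) for s in doc["slice_planes"]],
        outlet_slices=[OutletSliceDef(**o) for o in doc["outlet_slices"]],
        dominant_outlet=doc["dominant_outlet"],
        sac_seed=doc.get("sac_seed"),
        parent_seed=doc.get("parent_seed"),
    )
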