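"""Particle, membrane and annotation I/O.

Everything is converted to the package's internal conventions at the read
boundary: lengths in nanometres, particle orientation as an outward unit
axis in the tomogram frame. Angstroms and voxel coordinates exist only in
files.

Euler convention
----------------
Subtomogram-averaging particle tables carry ZYZ Euler triplets
(rot, tilt, psi). We use the intrinsic ZYZ convention with rotation matrix
``A = Rz(psi) @ Ry(tilt) @ Rz(rot)`` mapping the tomogram frame into the
particle reference frame; the particle's outward axis in the tomogram frame
is then ``A.T @ (0, 0, 1)``. Tables written with the opposite sense are
handled by ``euler_sense="particle_to_reference"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._star import read_star, write_star
from .errors import ConfigurationError, FormatError

__all__ = [
    "Particle",
    "MembraneSurface",
    "AnnotationTable",
    "axis_from_eulers",
    "read_particle_table",
    "write_particle_table",
    "read_membrane",
    "read_annotations",
    "write_annotations",
    "write_vesicle_table",
    "read_vesicle_table",
    "CSV_COLUMNS",
]

#: Documented CSV dialect column names (header row mandatory).
CSV_COLUMNS = (
    "particle_id", "tomogram_id", "x_nm", "y_nm", "z_nm",
    "ax", "ay", "az", "rot", "tilt", "psi", "class_label",
)


@dataclass
class Particle:
    """One picked complex: position (nm, tomogram frame) and outward axis."""

    particle_id: str
    tomogram_id: str
    position: np.ndarray
    axis: np.ndarray
    eulers: tuple[float, float, float] | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"particle {self.particle_id}: invalid position")
        norm = np.linalg.norm(self.axis)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError(f"particle {self.particle_id}: zero or non-finite axis")
        if abs(norm - 1.0) > 1e-12:  # idempotent: already-unit axes untouched
            self.axis = self.axis / norm


@dataclass
class MembraneSurface:
    """Membrane as a point cloud (optionally a triangle mesh)."""

    tomogram_id: str
    points: np.ndarray
    faces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise FormatError("membrane surface must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise FormatError("membrane surface contains non-finite coordinates")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)


@dataclass
class AnnotationTable:
    """Annotator x vesicle x class count tensor."""

    counts: np.ndarray
    class_names: list[str]
    annotator_ids: list[str] = field(default_factory=list)
    vesicle_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise FormatError("annotation counts must be a 3-d tensor")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise FormatError("annotation counts must be integers")
            self.counts = self.counts.astype(int)
        if np.any(self.counts < 0):
            raise FormatError("annotation counts must be non-negative")
        if self.counts.shape[2] != len(self.class_names):
            raise FormatError(
                f"class axis {self.counts.shape[2]} != {len(self.class_names)} class names"
            )
        if not self.annotator_ids:
            self.annotator_ids = [f"annotator_{i}" for i in range(self.counts.shape[0])]
        if not self.vesicle_ids:
            self.vesicle_ids = [f"vesicle_{i}" for i in range(self.counts.shape[1])]


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def axis_from_eulers(
    rot: float, tilt: float, psi: float,
    sense: str = "reference_to_particle",
) -> np.ndarray:
    """Particle outward axis in the tomogram frame from ZYZ Eulers (degrees).

    With the default sense, ``A = Rz(psi) @ Ry(tilt) @ Rz(rot)`` rotates the
    tomogram frame into the particle reference frame and the axis is
    ``A.T @ e_z``; ``sense="particle_to_reference"`` uses ``A @ e_z`` for
    dialects defining the transpose convention.
    """
    angles = np.array([rot, tilt, psi], dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("Euler angles must be finite")
    a = _rot_z(psi) @ _rot_y(tilt) @ _rot_z(rot)
    if sense == "reference_to_particle":
        axis = a.T @ np.array([0.0, 0.0, 1.0])
    elif sense == "particle_to_reference":
        axis = a @ np.array([0.0, 0.0, 1.0])
    else:
        raise ConfigurationError(f"unknown euler sense: {sense!r}")
    return axis / np.linalg.norm(axis)


def _require_columns(df: pd.DataFrame, names: Sequence[str], path) -> None:
    for name in names:
        if name not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {name!r}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            )
        df[col] = vals


def read_particle_table(
    path: str | Path,
    dialect: str | None = None,
    pixel_size: float | None = None,
    euler_sense: str = "reference_to_particle",
    voxel_center_offset: bool = False,
) -> list[Particle]:
    """Read particles from a STAR or CSV table, normalized to nm + unit axes.

    Parameters
    ----------
    dialect : {"star", "csv"} or None
        Inferred from the file suffix when None.
    pixel_size : float, optional
        Voxel size in Angstrom/voxel. Required for STAR tables, whose
        rlnCoordinate columns are in voxels; must be None/ignored for the
        CSV dialect, which is in nm by definition.
    euler_sense : str
        ZYZ convention sense, see :func:`axis_from_eulers`.
    voxel_center_offset : bool
        Add +0.5 voxel before conversion, for dialects that center voxels.
    """
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix.lower() == ".star" else "csv"
    if dialect == "star":
        return _read_star_particles(path, pixel_size, euler_sense, voxel_center_offset)
    if dialect == "csv":
        return _read_csv_particles(path, euler_sense)
    raise ConfigurationError(f"unknown dialect: {dialect!r}")


def _read_star_particles(path, pixel_size, euler_sense, voxel_center_offset):
    blocks = read_star(path)
    df = next(iter(blocks.values()))
    coord_cols = ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]
    _require_columns(df, coord_cols, path)
    euler_cols = ["rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"]
    has_eulers = all(c in df.columns for c in euler_cols)
    if not has_eulers:
        # no native axis columns exist in the STAR dialect: orientations are
        # mandatory, and a missing tilt column is the canonical failure
        missing = next(c for c in euler_cols if c not in df.columns)
        raise FormatError(f"{path}: missing mandatory column {missing!r}")
    if pixel_size is None:
        raise ConfigurationError(
            f"{path}: pixel_size (Angstrom/voxel) is required for voxel "
            "coordinates in STAR tables"
        )
    _numeric(df, coord_cols + euler_cols, path)
    offset = 0.5 if voxel_center_offset else 0.0
    nm_per_voxel = pixel_size / 10.0
    particles = []
    for i, row in df.reset_index(drop=True).iterrows():
        pos = (np.array([row[c] for c in coord_cols]) + offset) * nm_per_voxel
        eulers = tuple(float(row[c]) for c in euler_cols)
        axis = axis_from_eulers(*eulers, sense=euler_sense)
        tomo = str(row["rlnTomoName"]) if "rlnTomoName" in df.columns else "tomo_0"
        particles.append(Particle(
            particle_id=str(row["rlnParticleName"]) if "rlnParticleName" in df.columns else f"p{i:06d}",
            tomogram_id=tomo, position=pos, axis=axis, eulers=eulers,
        ))
    return particles


def _read_csv_particles(path, euler_sense):
    df = pd.read_csv(path, dtype={"particle_id": str, "tomogram_id": str},
                     float_precision="round_trip")
    _require_columns(df, ["particle_id", "tomogram_id", "x_nm", "y_nm", "z_nm"], path)
    has_axis = all(c in df.columns for c in ("ax", "ay", "az"))
    has_eulers = all(c in df.columns for c in ("rot", "tilt", "psi"))
    if not has_axis and not has_eulers:
        raise FormatError(
            f"{path}: missing orientation columns (ax,ay,az or rot,tilt,psi)"
        )
    num_cols = ["x_nm", "y_nm", "z_nm"]
    num_cols += ["ax", "ay", "az"] if has_axis else ["rot", "tilt", "psi"]
    _numeric(df, num_cols, path)
    particles = []
    for _, row in df.reset_index(drop=True).iterrows():
        pos = np.array([row["x_nm"], row["y_nm"], row["z_nm"]])
        if has_axis:
            axis = np.array([row["ax"], row["ay"], row["az"]])
            eulers = None
        else:
            eulers = (float(row["rot"]), float(row["tilt"]), float(row["psi"]))
            axis = axis_from_eulers(*eulers, sense=euler_sense)
        label = row.get("class_label")
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        particles.append(Particle(
            particle_id=str(row["particle_id"]), tomogram_id=str(row["tomogram_id"]),
            position=pos, axis=axis, eulers=eulers,
            class_label=None if label is None else str(label),
        ))
    return particles


def write_particle_table(
    particles: Iterable[Particle], path: str | Path, dialect: str | None = None,
    pixel_size: float | None = None,
) -> None:
    """Write particles as CSV (nm) or STAR (voxels; requires pixel_size)."""
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix.lower() == ".star" else "csv"
    particles = list(particles)
    if dialect == "csv":
        rows = []
        for p in particles:
            row = {
                "particle_id": p.particle_id, "tomogram_id": p.tomogram_id,
                "x_nm": p.position[0], "y_nm": p.position[1], "z_nm": p.position[2],
                "ax": p.axis[0], "ay": p.axis[1], "az": p.axis[2],
                "class_label": "" if p.class_label is None else p.class_label,
            }
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    elif dialect == "star":
        if pixel_size is None:
            raise ConfigurationError("pixel_size required to write voxel STAR coordinates")
        nm_per_voxel = pixel_size / 10.0
        rows = []
        for p in particles:
            eulers = p.eulers if p.eulers is not None else _eulers_from_axis(p.axis)
            rows.append({
                "rlnParticleName": p.particle_id,
                "rlnTomoName": p.tomogram_id,
                "rlnCoordinateX": p.position[0] / nm_per_voxel,
                "rlnCoordinateY": p.position[1] / nm_per_voxel,
                "rlnCoordinateZ": p.position[2] / nm_per_voxel,
                "rlnAngleRot": eulers[0], "rlnAngleTilt": eulers[1],
                "rlnAnglePsi": eulers[2],
            })
        write_star(pd.DataFrame(rows), path)
    else:
        raise ConfigurationError(f"unknown dialect: {dialect!r}")


def _eulers_from_axis(axis: np.ndarray) -> tuple[float, float, float]:
    """A ZYZ triplet whose reference z-axis maps onto the given axis.

    The in-plane angle is unconstrained by an axis alone; psi is set to 0.
    Inverse of axis_from_eulers for the default sense: axis = A.T e_z with
    A = Rz(psi) Ry(tilt) Rz(rot) gives axis = Rz(-rot) Ry(-tilt) e_z at psi=0.
    """
    x, y, z = axis
    tilt = np.rad2deg(np.arccos(np.clip(z, -1.0, 1.0)))
    rot = np.rad2deg(np.arctan2(y, -x)) if (abs(x) > 1e-15 or abs(y) > 1e-15) else 0.0
    return (float(rot), float(tilt), 0.0)


def read_membrane(path: str | Path, tomogram_id: str | None = None) -> MembraneSurface:
    """Read a membrane surface from CSV/XYZ point cloud or PLY mesh."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        import trimesh

        mesh = trimesh.load(path, file_type="ply", process=False)
        if len(mesh.vertices) == 0:
            raise FormatError(f"{path}: empty mesh")
        return MembraneSurface(
            tomogram_id=tomogram_id or path.stem,
            points=np.asarray(mesh.vertices, dtype=float),
            faces=np.asarray(mesh.faces, dtype=int) if len(mesh.faces) else None,
        )
    if suffix == ".xyz":
        try:
            pts = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse XYZ point cloud: {exc}") from exc
        if pts.size == 0:
            raise FormatError(f"{path}: empty membrane file")
        return MembraneSurface(tomogram_id=tomogram_id or path.stem, points=pts[:, :3])
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty membrane file")
    cols = ["x", "y", "z"] if "x" in df.columns else ["x_nm", "y_nm", "z_nm"]
    _require_columns(df, cols, path)
    _numeric(df, cols, path)
    tomo = tomogram_id
    if tomo is None:
        tomo = str(df["tomogram_id"].iloc[0]) if "tomogram_id" in df.columns else path.stem
    return MembraneSurface(tomogram_id=tomo, points=df[cols].to_numpy())


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a long-format annotation CSV (annotator, vesicle, class, count)."""
    df = pd.read_csv(path)
    _require_columns(df, ["annotator", "vesicle", "class", "count"], path)
    _numeric(df, ["count"], path)
    # first-appearance order so write -> read preserves the tensor layout
    annotators = list(pd.unique(df["annotator"].astype(str)))
    vesicles = list(pd.unique(df["vesicle"].astype(str)))
    classes = list(pd.unique(df["class"].astype(str)))
    a_idx = {a: i for i, a in enumerate(annotators)}
    v_idx = {v: i for i, v in enumerate(vesicles)}
    c_idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(annotators), len(vesicles), len(classes)), dtype=int)
    for _, row in df.iterrows():
        val = float(row["count"])
        if val != int(val) or val < 0:
            raise FormatError(f"{path}: counts must be non-negative integers, got {val}")
        counts[a_idx[str(row["annotator"])], v_idx[str(row["vesicle"])],
               c_idx[str(row["class"])]] = int(val)
    return AnnotationTable(counts=counts, class_names=classes,
                           annotator_ids=annotators, vesicle_ids=vesicles)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    rows = []
    for a, aid in enumerate(table.annotator_ids):
        for v, vid in enumerate(table.vesicle_ids):
            for c, cname in enumerate(table.class_names):
                rows.append({"annotator": aid, "vesicle": vid, "class": cname,
                             "count": int(table.counts[a, v, c])})
    pd.DataFrame(rows).to_csv(path, index=False)


_VESICLE_COLUMNS = ("vesicle_id", "tomogram_id", "cx_nm", "cy_nm", "cz_nm",
                    "radius_nm", "radius_source", "fit_rms_nm", "member_particle_ids")


def write_vesicle_table(vesicles, path: str | Path) -> None:
    """Write fitted vesicles as a stable-schema CSV (lossless round trip)."""
    rows = []
    for v in vesicles:
        rows.append({
            "vesicle_id": v.vesicle_id, "tomogram_id": v.tomogram_id,
            "cx_nm": v.center[0], "cy_nm": v.center[1], "cz_nm": v.center[2],
            "radius_nm": v.radius, "radius_source": v.radius_source,
            "fit_rms_nm": v.fit_rms,
            "member_particle_ids": ";".join(v.member_particle_ids),
        })
    pd.DataFrame(rows, columns=_VESICLE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_vesicle_table(path: str | Path):
    from .geometry import Vesicle

    df = pd.read_csv(path, dtype={"vesicle_id": str, "tomogram_id": str},
                     float_precision="round_trip")
    _require_columns(df, _VESICLE_COLUMNS, path)
    vesicles = []
    for _, row in df.iterrows():
        members = str(row["member_particle_ids"])
        vesicles.append(Vesicle(
            vesicle_id=str(row["vesicle_id"]), tomogram_id=str(row["tomogram_id"]),
            center=np.array([row["cx_nm"], row["cy_nm"], row["cz_nm"]], dtype=float),
            radius=float(row["radius_nm"]),
            member_particle_ids=members.split(";") if members else [],
            radius_source=str(row["radius_source"]), fit_rms=float(row["fit_rms_nm"]),
        ))
    return vesicles
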