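"""On-disk formats: MRC2014 volumes, point models, particle tables.

Internal contrast convention is protein-positive (protein = high values).
MRC export *defaults to inverting* the contrast so files look like standard
cryo-EM density; pass ``invert_contrast=False`` to keep the internal sign.

Particle tables are the motive-list equivalent: one row per subtomogram with
position (nm), intrinsic Z-X-Z Euler angles (degrees), cross-correlation
score, class label and keep flag.  On disk they are TSV with a '#'-prefixed
header line.  Point models follow IMOD's model2point text layout
(``object contour x y z``, 1-based object/contour ids, coordinates in voxels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "FilamentModel",
    "PARTICLE_COLUMNS",
    "new_particle_table",
    "validate_particle_table",
    "read_mrc",
    "write_mrc",
    "read_point_model",
    "write_point_model",
    "read_table",
    "write_table",
    "write_star",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact is malformed."""


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel size.

    ``data`` is indexed (z, y, x); the centre of voxel (0,0,0) sits at
    ``origin`` (nm).  Physical position of voxel (iz, iy, ix) is
    ``origin + voxel_size * (ix, iy, iz)`` in (x, y, z) order.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume.data must be 3D")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self):
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin.copy())


@dataclass
class FilamentModel:
    """One filament's picking path: an ordered 3D polyline in nm."""

    filament_id: int
    points: np.ndarray
    kind: str = "MT"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("FilamentModel needs at least 2 points")


PARTICLE_COLUMNS = [
    "particle_id",
    "filament_id",
    "tomogram_id",
    "x",
    "y",
    "z",
    "phi",
    "theta",
    "psi",
    "cc_score",
    "class_label",
    "keep_flag",
    "arclength",
]

_PARTICLE_DTYPES = {
    "particle_id": np.int64,
    "filament_id": np.int64,
    "tomogram_id": np.int64,
    "x": float,
    "y": float,
    "z": float,
    "phi": float,
    "theta": float,
    "psi": float,
    "cc_score": float,
    "class_label": np.int64,
    "keep_flag": bool,
    "arclength": float,
}


def new_particle_table(n: int = 0) -> pd.DataFrame:
    """An empty motive-list table with the canonical columns."""
    df = pd.DataFrame({c: np.zeros(n, dtype=_PARTICLE_DTYPES[c]) for c in PARTICLE_COLUMNS})
    df["keep_flag"] = True
    df["class_label"] = -1
    df["particle_id"] = np.arange(n, dtype=np.int64)
    return df


def validate_particle_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in PARTICLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"particle table missing mandatory column '{col}'")
    if df["particle_id"].duplicated().any():
        raise FormatError("particle_id values must be unique")
    return df


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_HEADER = np.dtype(
    [
        ("nx", "<i4"), ("ny", "<i4"), ("nz", "<i4"), ("mode", "<i4"),
        ("nxstart", "<i4"), ("nystart", "<i4"), ("nzstart", "<i4"),
        ("mx", "<i4"), ("my", "<i4"), ("mz", "<i4"),
        ("cella", "<f4", 3), ("cellb", "<f4", 3),
        ("mapc", "<i4"), ("mapr", "<i4"), ("maps", "<i4"),
        ("dmin", "<f4"), ("dmax", "<f4"), ("dmean", "<f4"),
        ("ispg", "<i4"), ("nsymbt", "<i4"), ("extra1", "S8"),
        ("exttyp", "S4"), ("nversion", "<i4"), ("extra2", "S84"),
        ("origin", "<f4", 3), ("map", "S4"), ("machst", "u1", 4),
        ("rms", "<f4"), ("nlabl", "<i4"), ("label", "S800"),
    ]
)

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def write_mrc(volume: Volume, path, invert_contrast: bool = True) -> None:
    """Write a Volume as MRC2014 mode-2 (float32), voxel size in the header.

    ``invert_contrast`` multiplies the data by -1 on output so that protein
    appears dark-on-light as in conventional cryo-EM maps.
    """
    data = volume.data.astype("<f4")
    if invert_contrast:
        data = -data
    nz, ny, nx = data.shape
    h = np.zeros((), dtype=_MRC_HEADER)
    h["nx"], h["ny"], h["nz"] = nx, ny, nz
    h["mode"] = 2
    h["mx"], h["my"], h["mz"] = nx, ny, nz
    # MRC cell lengths are in angstrom; internal unit is nm
    h["cella"] = np.array([nx, ny, nz]) * volume.voxel_size * 10.0
    h["cellb"] = (90.0, 90.0, 90.0)
    h["mapc"], h["mapr"], h["maps"] = 1, 2, 3
    h["dmin"], h["dmax"], h["dmean"] = float(data.min()), float(data.max()), float(data.mean())
    h["ispg"] = 1
    h["nversion"] = 20140
    h["origin"] = np.asarray(volume.origin, dtype="<f4") * 10.0
    h["map"] = b"MAP "
    h["machst"] = (0x44, 0x44, 0, 0)
    h["rms"] = float(data.std())
    with open(path, "wb") as f:
        f.write(h.tobytes())
        f.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path, invert_contrast: bool = True) -> Volume:
    """Read an MRC2014 volume; by default re-inverts contrast to protein-positive."""
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER.itemsize:
        raise FormatError(f"{path}: file shorter than an MRC header")
    h = np.frombuffer(raw[: _MRC_HEADER.itemsize], dtype=_MRC_HEADER)[0]
    if bytes(h["map"]) != b"MAP ":
        raise FormatError(f"{path}: not an MRC2014 file (missing 'MAP ' magic)")
    mode = int(h["mode"])
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    nx, ny, nz = int(h["nx"]), int(h["ny"]), int(h["nz"])
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    nbytes = nx * ny * nz * dtype.itemsize
    start = _MRC_HEADER.itemsize + int(h["nsymbt"])
    if len(raw) < start + nbytes:
        raise FormatError(f"{path}: truncated MRC data block")
    data = np.frombuffer(raw[start : start + nbytes], dtype=dtype).reshape(nz, ny, nx)
    data = data.astype(np.float32)
    if invert_contrast:
        data = -data
    mx = int(h["mx"]) or nx
    voxel = float(h["cella"][0]) / mx / 10.0 if h["cella"][0] > 0 else 1.0
    origin = np.asarray(h["origin"], dtype=float) / 10.0
    return Volume(data, voxel, origin)


# ---------------------------------------------------------------------------
# Point models (model2point text)
# ---------------------------------------------------------------------------

def read_point_model(path, voxel_size: float) -> list[FilamentModel]:
    """Parse ``object contour x y z`` text into FilamentModels (nm).

    One model per (object, contour) pair; contours with fewer than two points
    are skipped with a warning.  Voxel coordinates are scaled by
    ``voxel_size`` into nm.
    """
    import warnings

    groups: dict[tuple[int, int], list] = {}
    order: list[tuple[int, int]] = []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: expected 'object contour x y z'")
            try:
                obj, cont = int(parts[0]), int(parts[1])
                xyz = [float(v) for v in parts[2:5]]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
            key = (obj, cont)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(xyz)
    models = []
    for i, key in enumerate(order):
        pts = np.asarray(groups[key], dtype=float) * voxel_size
        if len(pts) < 2:
            warnings.warn(f"contour {key} has <2 points; skipped")
            continue
        models.append(FilamentModel(filament_id=i, points=pts))
    return models


def write_point_model(models: list[FilamentModel], path, voxel_size: float) -> None:
    """Write models as model2point text (1-based ids, voxel coordinates)."""
    with open(path, "w") as f:
        for i, m in enumerate(models, start=1):
            for p in m.points / voxel_size:
                f.write(f"{i:6d} {1:6d} {p[0]:12.3f} {p[1]:12.3f} {p[2]:12.3f}\n")


# ---------------------------------------------------------------------------
# Particle tables (TSV motive lists)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6f"


def write_table(df: pd.DataFrame, path) -> None:
    """TSV with '#'-prefixed header; fixed column order; idempotent bytes."""
    validate_particle_table(df)
    df = df[PARTICLE_COLUMNS]
    with open(path, "w") as f:
        f.write("#" + "\t".join(PARTICLE_COLUMNS) + "\n")
        for _, row in df.iterrows():
            cells = []
            for c in PARTICLE_COLUMNS:
                v = row[c]
                if _PARTICLE_DTYPES[c] is float:
                    cells.append(_FLOAT_FMT % v)
                elif _PARTICLE_DTYPES[c] is bool:
                    cells.append("1" if v else "0")
                else:
                    cells.append(str(int(v)))
            f.write("\t".join(cells) + "\n")


def read_table(path) -> pd.DataFrame:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '#' header line")
        cols = header[1:].strip().split("\t")
        df = pd.read_csv(f, sep="\t", names=cols)
    for col in PARTICLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{col}'")
    df["keep_flag"] = df["keep_flag"].astype(bool)
    for c, t in _PARTICLE_DTYPES.items():
        df[c] = df[c].astype(t)
    return validate_particle_table(df)


def write_star(df: pd.DataFrame, path) -> None:
    """Minimal STAR export: one data_ block with a loop_ over the TSV columns."""
    validate_particle_table(df)
    with open(path, "w") as f:
        f.write("data_particles\n\nloop_\n")
        for i, c in enumerate(PARTICLE_COLUMNS, 1):
            f.write(f"_axontomo{c.title().replace('_', '')} #{i}\n")
        for _, row in df[PARTICLE_COLUMNS].iterrows():
            f.write(" ".join(str(row[c]) for c in PARTICLE_COLUMNS) + "\n")


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path):
    return json.loads(Path(path).read_text())
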