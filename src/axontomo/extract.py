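"""Particle picking along filaments and subtomogram cropping.

Picking places frames every ``spacing`` nm (8 nm = tubulin dimer, 4 nm =
monomer) with the box z-axis along the local tangent and in-plane angle 0;
both filament ends are sampled.  Cropping resamples the tomogram by trilinear
interpolation on the rotated grid, so boxes come out already rotated into the
filament frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .geometry import (
    euler_to_matrix,
    matrix_to_euler,
    parallel_transport_frames,
    path_tangents,
    resample_path,
    wrap_angle,
)
from .io import FilamentModel, Volume, new_particle_table

__all__ = ["SubtomogramStack", "frames_along_filament", "crop", "randomize_inplane"]


@dataclass
class SubtomogramStack:
    """N cubic boxes plus the particle table they were cropped with."""

    boxes: np.ndarray  # (N, b, b, b) float32, (z, y, x) per box
    voxel_size: float
    table: pd.DataFrame

    def __post_init__(self):
        if self.boxes.ndim != 4:
            raise ValueError("boxes must be (N, b, b, b)")
        b = self.boxes.shape[1]
        if self.boxes.shape[2] != b or self.boxes.shape[3] != b:
            raise ValueError("boxes must be cubic")
        if b % 2 == 0:
            raise ValueError("box_size must be odd (unambiguous centre)")
        if len(self.boxes) != len(self.table):
            raise ValueError("stack/table length mismatch")

    @property
    def box_size(self) -> int:
        return self.boxes.shape[1]


def frames_along_filament(model: FilamentModel, spacing: float,
                          tomogram_id: int = 0) -> pd.DataFrame:
    """Evenly spaced oriented picking positions along one filament.

    Positions at arclengths 0, spacing, 2*spacing, ... up to and including
    the total length; Euler angles orient the box z-axis along the local
    tangent (central differences, one-sided at the ends) with in-plane
    angle 0 via parallel transport.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    from .geometry import path_arclength

    L = float(path_arclength(model.points)[-1])
    if spacing > L:
        warnings.warn(f"spacing {spacing} exceeds filament length {L:.1f}; single frame")
        s_vals = np.array([0.0])
    else:
        s_vals = np.arange(0.0, L + 1e-9, spacing)
    pos = resample_path(model.points, s_vals)
    if len(pos) > 2:
        tangents = path_tangents(pos)
    else:
        tangents = path_tangents(resample_path(model.points, np.array([0.0, L])))
        tangents = np.tile(tangents[:1], (len(pos), 1))
    frames = parallel_transport_frames(tangents)
    # standardize the in-plane frame: beam (tomogram +z) projects onto box +y,
    # so the missing wedge sits identically in every particle frame
    for k, F in enumerate(frames):
        v = F.T @ np.array([0.0, 0.0, 1.0])
        if np.hypot(v[0], v[1]) > 1e-6:
            a = np.arctan2(v[0], v[1])
            ca, sa = np.cos(a), np.sin(a)
            Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
            frames[k] = F @ Rz

    table = new_particle_table(len(pos))
    table["filament_id"] = model.filament_id
    table["tomogram_id"] = tomogram_id
    table[["x", "y", "z"]] = pos
    eulers = np.array([matrix_to_euler(F) for F in frames])
    table[["phi", "theta", "psi"]] = eulers
    table["arclength"] = s_vals
    return table


def crop(volume: Volume, table: pd.DataFrame, box_size: int) -> SubtomogramStack:
    """Extract rotated subtomograms centred on each table position.

    Sample points are ``position + R @ grid`` (grid in nm, centred), so the
    output box is expressed in the particle frame with z along the filament.
    Particles whose sampling grid leaves the volume are dropped with
    keep_flag False, never zero-padded silently.
    """
    if box_size % 2 == 0:
        raise ValueError("box_size must be odd")
    vx = volume.voxel_size
    half = (box_size - 1) / 2.0
    ax = (np.arange(box_size) - half) * vx
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.stack([xx.ravel(), yy.ravel(), zz.ravel()])  # (3, b^3) nm, (x,y,z) rows

    nz, ny, nx = volume.shape
    boxes, kept_idx = [], []
    table = table.reset_index(drop=True)
    dropped = []
    for i, row in table.iterrows():
        R = euler_to_matrix(row.phi, row.theta, row.psi)
        pts = R @ grid + np.array([[row.x], [row.y], [row.z]]) - volume.origin[:, None]
        vox = pts / vx  # (x, y, z) voxel coords
        if (vox.min(axis=1) < -0.5).any() or (
            vox[0].max() > nx - 0.5 or vox[1].max() > ny - 0.5 or vox[2].max() > nz - 0.5
        ):
            dropped.append(i)
            continue
        coords = np.array([vox[2], vox[1], vox[0]])  # map_coordinates wants (z, y, x)
        box = map_coordinates(volume.data, coords, order=1, mode="nearest")
        boxes.append(box.reshape(box_size, box_size, box_size).astype(np.float32))
        kept_idx.append(i)
    if dropped:
        warnings.warn(f"{len(dropped)} particles outside the volume were dropped")
    out = table.loc[kept_idx].copy()
    flagged = table.copy()
    flagged.loc[dropped, "keep_flag"] = False
    out = out.reset_index(drop=True)
    stack = SubtomogramStack(
        boxes=np.asarray(boxes).reshape(-1, box_size, box_size, box_size),
        voxel_size=vx,
        table=out,
    )
    stack.dropped_table = flagged  # full table incl. dropped rows, keep_flag False
    return stack


def save_stack(stack: SubtomogramStack, mrc_path, table_path) -> None:
    """Persist a stack as one MRC volume (boxes stacked along z) plus TSV."""
    from .io import Volume, write_mrc, write_table

    n, b = len(stack.boxes), stack.box_size
    write_mrc(Volume(stack.boxes.reshape(n * b, b, b), stack.voxel_size), mrc_path)
    write_table(stack.table, table_path)


def load_stack(mrc_path, table_path) -> SubtomogramStack:
    from .io import read_mrc, read_table

    vol = read_mrc(mrc_path)
    table = read_table(table_path)
    b = vol.data.shape[1]
    boxes = vol.data.reshape(-1, b, b, b)
    return SubtomogramStack(boxes, vol.voxel_size, table)


def randomize_inplane(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Uniform random spin about the filament axis; other angles untouched."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["psi"] = wrap_angle(rng.uniform(-180.0, 180.0, size=len(table)))
    return out
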