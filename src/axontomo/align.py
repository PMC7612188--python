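"""Constrained subtomogram alignment, cleaning, symmetry expansion, averaging,
projections and Fourier shell correlation.

Alignment maximizes a masked, optionally wedge-aware, normalized
cross-correlation over a discretized transform grid inside user limits
(2-degree in-plane steps, half-voxel shifts by default -- finer than the
28-degree / 2.2-nm limits used for the MT work).  Particle tables carry the
crop-time orientation in (phi, theta, psi, x, y, z) and the alignment result
as a *residual* transform in (rphi, rtheta, rpsi, sx, sy, sz): box content ==
reference rotated by the residual rotation then shifted by (sx, sy, sz) nm in
the box frame.  Averaging undoes the residual per particle before summing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform

from .extract import SubtomogramStack
from .geometry import euler_to_matrix, fibonacci_sphere, wrap_angle
from .io import Volume

__all__ = [
    "AlignmentLimits",
    "gaussian_tube",
    "gaussian_sphere",
    "align",
    "cc_clean",
    "distance_clean",
    "symmetry_expand",
    "average",
    "project",
    "fsc",
    "resolution_at",
    "ensure_residual_columns",
]

RESIDUAL_COLUMNS = ["rphi", "rtheta", "rpsi", "sx", "sy", "sz"]


def ensure_residual_columns(table: pd.DataFrame) -> pd.DataFrame:
    for c in RESIDUAL_COLUMNS:
        if c not in table.columns:
            table = table.copy()
            for cc in RESIDUAL_COLUMNS:
                if cc not in table.columns:
                    table[cc] = 0.0
            break
    return table


@dataclass
class AlignmentLimits:
    """Search limits: degrees for angles, nm for shifts; cone 0 locks the axis.

    mask is None, ("tube", radius_nm, sigma_nm) or ("sphere", radius_nm,
    sigma_nm); a Gaussian tube keeps the alignment off luminal densities, a
    Gaussian sphere focuses on them.
    """

    max_inplane: float = 28.0
    max_axial_shift: float = 2.2
    max_lateral_shift: float = 0.0
    cone: float = 0.0
    mask: Optional[tuple] = ("tube", 10.6, 4.0)
    angle_step: float = 2.0
    shift_step: Optional[float] = None  # nm; default half a voxel

    def __post_init__(self):
        if min(self.max_inplane, self.max_axial_shift, self.max_lateral_shift, self.cone) < 0:
            raise ValueError("alignment limits must be non-negative")

    def mask_array(self, box_size: int, voxel: float) -> np.ndarray:
        if self.mask is None:
            return np.ones((box_size,) * 3, dtype=np.float32)
        kind, radius, sigma = self.mask
        if kind == "tube":
            return gaussian_tube(box_size, voxel, radius, sigma)
        if kind == "sphere":
            return gaussian_sphere(box_size, voxel, radius, sigma)
        raise ValueError(f"unknown mask kind {kind!r}")


def _radial_grids(box_size: int, voxel: float):
    ax = (np.arange(box_size) - (box_size - 1) / 2.0) * voxel
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    return z, y, x


def gaussian_tube(box_size: int, voxel: float, radius: float, sigma: float) -> np.ndarray:
    """Soft cylinder along the box z-axis: 1 inside radius, Gaussian falloff."""
    z, y, x = _radial_grids(box_size, voxel)
    r = np.hypot(x, y)
    m = np.where(r <= radius, 1.0, np.exp(-0.5 * ((r - radius) / sigma) ** 2))
    return m.astype(np.float32)


def gaussian_sphere(box_size: int, voxel: float, radius: float, sigma: float) -> np.ndarray:
    z, y, x = _radial_grids(box_size, voxel)
    r = np.sqrt(x * x + y * y + z * z)
    m = np.where(r <= radius, 1.0, np.exp(-0.5 * ((r - radius) / sigma) ** 2))
    return m.astype(np.float32)


def _normalize_under_mask(v: np.ndarray, mask: np.ndarray) -> np.ndarray:
    w = mask.ravel()
    x = v.ravel().astype(np.float64) * w
    wsum = w.sum()
    x = x - w * (x.sum() / wsum)
    n = np.linalg.norm(x)
    if n < 1e-12:
        return None
    return (x / n).astype(np.float32)


def _transform_volume(vol: np.ndarray, R: np.ndarray, shift_nm, voxel: float) -> np.ndarray:
    """Rotate ``vol`` by R (box->box) then translate by shift_nm (x, y, z)."""
    b = vol.shape[0]
    c = (b - 1) / 2.0
    # array index order is (z, y, x): permute R accordingly
    P = R[::-1, ::-1]
    shift_vox = np.asarray(shift_nm, dtype=float)[::-1] / voxel  # (z, y, x)
    # output voxel o maps to input voxel P^T (o - c - shift) + c
    M = P.T
    offset = c - M @ (c + shift_vox)
    return affine_transform(vol, M, offset=offset, order=1, mode="constant", cval=0.0)


def _wedge_mask_for(shape, tilt_range: float, M: np.ndarray) -> np.ndarray:
    """Box/reference-frame wedge mask when tomogram freq = M @ local freq."""
    b = shape[0]
    f = np.fft.fftfreq(b)
    kz, ky, kx = np.meshgrid(f, f, f, indexing="ij")
    k = np.stack([kx.ravel(), ky.ravel(), kz.ravel()])
    kt = M @ k
    ang = np.degrees(np.arctan2(np.abs(kt[2]), np.abs(kt[0])))
    return (ang <= tilt_range + 1e-12).reshape(shape)


def _candidate_grid(limits: AlignmentLimits, voxel: float):
    """List of (R, shift_nm, dpsi_deg_or_None) candidates inside the limits."""
    astep = max(limits.angle_step, 1e-3)
    sstep = limits.shift_step if limits.shift_step is not None else 0.5 * voxel

    if limits.max_inplane >= 180.0:
        spins = np.arange(-180.0, 180.0, max(astep, 30.0) if limits.cone >= 180 else astep)
    else:
        nspin = int(np.floor(limits.max_inplane / astep))
        spins = np.arange(-nspin, nspin + 1) * astep
    if limits.cone <= 1e-9:
        dirs = np.array([[0.0, 0.0, 1.0]])
    else:
        if limits.cone >= 180:
            dirs = fibonacci_sphere(48)
        else:
            cand = fibonacci_sphere(512)
            keep = np.degrees(np.arccos(np.clip(cand[:, 2], -1, 1))) <= limits.cone
            dirs = cand[keep]
        # the identity orientation must always be searchable
        dirs = np.vstack([[0.0, 0.0, 1.0], dirs])

    nax = int(np.floor(limits.max_axial_shift / sstep))
    dz_vals = np.arange(-nax, nax + 1) * sstep
    nlat = int(np.floor(limits.max_lateral_shift / sstep))
    dl_vals = np.arange(-nlat, nlat + 1) * sstep

    cands = []
    for d in dirs:
        v = np.cross([0.0, 0.0, 1.0], d)
        s = np.linalg.norm(v)
        c = float(d[2])
        if s < 1e-12:
            Rt = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            Rt = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        for spin in spins:
            R = Rt @ euler_to_matrix(0.0, 0.0, spin)
            for dz in dz_vals:
                for dx in dl_vals:
                    for dy in dl_vals:
                        cands.append((R, (dx, dy, dz), spin if limits.cone <= 1e-9 else None))
    return cands


def align(stack: SubtomogramStack, reference: Volume, limits: AlignmentLimits,
          iterations: int = 1, wedge_aware: bool = False,
          tilt_range: float = 60.0) -> pd.DataFrame:
    """Grid-search alignment of every particle against one reference.

    Returns the table with updated residual transform columns and cc_score.
    With ``wedge_aware`` the reference bank is filtered by each filament's
    missing-wedge mask before scoring (particles of one filament share a
    wedge orientation to good approximation).  All-zero boxes are flagged
    with cc_score -1 and keep_flag False.
    """
    from scipy.ndimage import shift as _ndshift

    if reference.data.shape != stack.boxes.shape[1:]:
        raise ValueError("reference and boxes must have the same size")
    b = stack.box_size
    voxel = stack.voxel_size
    mask = limits.mask_array(b, voxel)
    cands = _candidate_grid(limits, voxel)
    # group candidates by rotation: rotate once, then translate cheaply
    # (the wedge filter is a Fourier multiplier, so it commutes with shifts)
    rot_groups: list[tuple] = []
    seen: dict[int, int] = {}
    for ci, (R, shift, spin) in enumerate(cands):
        key = id(R)
        if key not in seen:
            seen[key] = len(rot_groups)
            rot_groups.append((R, spin, []))
        rot_groups[seen[key]][2].append((ci, shift))

    table = ensure_residual_columns(stack.table.copy()).reset_index(drop=True)
    norms = np.empty((len(table), b**3), dtype=np.float32)
    ok = np.ones(len(table), dtype=bool)
    for i in range(len(table)):
        v = _normalize_under_mask(stack.boxes[i], mask)
        if v is None:
            ok[i] = False
            norms[i] = 0.0
        else:
            norms[i] = v

    wm = None
    if wedge_aware:
        # picking frames standardize the wedge azimuth, so a single mask from
        # the stack's median orientation serves every particle
        row = table.iloc[len(table) // 2]
        M = euler_to_matrix(row.phi, row.theta, row.psi)
        wm = _wedge_mask_for((b,) * 3, tilt_range, M)

    bnorm = np.empty((len(cands), b**3), dtype=np.float32)
    for R, spin, members in rot_groups:
        rot = _transform_volume(reference.data, R, (0.0, 0.0, 0.0), voxel)
        if wm is not None:
            rot = np.real(np.fft.ifftn(np.fft.fftn(rot) * wm))
        for ci, shift in members:
            if any(shift):
                sh = _ndshift(rot, np.asarray(shift, dtype=float)[::-1] / voxel,
                              order=1, mode="constant", cval=0.0)
            else:
                sh = rot
            v = _normalize_under_mask(sh.astype(np.float32), mask)
            bnorm[ci] = 0.0 if v is None else v

    cc = norms @ bnorm.T  # (n_particles, n_candidates)
    best = np.argmax(cc, axis=1)
    from .geometry import matrix_to_euler

    for i, ci in enumerate(best):
        if not ok[i]:
            continue
        R, shift, spin = cands[ci]
        table.loc[i, "cc_score"] = float(np.clip(cc[i, ci], -1.0, 1.0))
        if spin is not None:
            table.loc[i, ["rphi", "rtheta", "rpsi"]] = [0.0, 0.0, spin]
        else:
            table.loc[i, ["rphi", "rtheta", "rpsi"]] = matrix_to_euler(R)
        table.loc[i, ["sx", "sy", "sz"]] = shift
    table.loc[~ok, "cc_score"] = -1.0
    table.loc[~ok, "keep_flag"] = False
    return table


def cc_clean(table: pd.DataFrame, fraction: float = 0.8,
             group_by: str = "filament_id") -> pd.DataFrame:
    """Keep the ceil(fraction*n) best-scoring particles per filament (ties kept)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    kept = []
    for _, grp in table.groupby(group_by):
        if len(grp) == 0:
            continue
        k = int(np.ceil(fraction * len(grp)))
        thr = np.sort(grp["cc_score"].to_numpy())[::-1][k - 1]
        kept.append(grp[grp["cc_score"] >= thr])
    if not kept:
        return table.iloc[0:0]
    return pd.concat(kept).sort_index()


def distance_clean(table: pd.DataFrame, min_dist: float = 3.5,
                   min_angle: float = 25.0) -> pd.DataFrame:
    """Remove the lower-scoring particle of pairs violating BOTH thresholds.

    A pair offends only if it is closer than ``min_dist`` nm AND its in-plane
    angular difference is below ``min_angle`` degrees (the conjunctive rule).
    Greedy from the highest score: an accepted particle eliminates offending
    lower-scoring neighbours.
    """
    t = ensure_residual_columns(table).reset_index(drop=True)
    pos = t[["x", "y", "z"]].to_numpy()
    spin = (t["psi"].to_numpy() + t["rpsi"].to_numpy())
    order = np.argsort(-t["cc_score"].to_numpy())
    alive = np.ones(len(t), dtype=bool)
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    for i in order:
        if not alive[i]:
            continue
        for j in tree.query_ball_point(pos[i], min_dist):
            if j == i or not alive[j]:
                continue
            d_ang = abs(wrap_angle(spin[i] - spin[j]))
            if np.linalg.norm(pos[i] - pos[j]) < min_dist and d_ang < min_angle:
                alive[j] = False
    return table.reset_index(drop=True)[alive]


def symmetry_expand(table: pd.DataFrame, rot: float = 27.69, rise: float = 0.92,
                    copies: int = 12) -> pd.DataFrame:
    """Helical symmetry expansion: cumulative in-plane rot + axial rise.

    The 13-pf MT parameters are 27.69 degrees (360/13) and 0.92 nm; with the
    default 12 copies each input row becomes 13 rows (original + 12).
    """
    t = ensure_residual_columns(table).reset_index(drop=True)
    out = [t]
    for k in range(1, copies + 1):
        c = t.copy()
        c["rpsi"] = c["rpsi"] + k * rot
        c["sz"] = c["sz"] + k * rise
        c["particle_id"] = c["particle_id"] + k * (t["particle_id"].max() + 1)
        out.append(c)
    return pd.concat(out, ignore_index=True)


def _residual_matrix(row):
    return euler_to_matrix(row.rphi, row.rtheta, row.rpsi)


def average(stack: SubtomogramStack, table: Optional[pd.DataFrame] = None,
            wedge_compensation: bool = False, tilt_range: float = 60.0) -> Volume:
    """Average kept particles after undoing each one's residual transform.

    With ``wedge_compensation`` the Fourier sum is divided by the summed
    per-particle wedge coverage (floored at 10% of its max) instead of N,
    the standard missing-wedge normalization.
    """
    t = ensure_residual_columns(table if table is not None else stack.table)
    t = t[t["keep_flag"]] if "keep_flag" in t else t
    if len(t) == 0:
        raise ValueError("average of zero kept particles")
    b = stack.box_size
    voxel = stack.voxel_size
    id_by_pid = {pid: i for i, pid in enumerate(stack.table["particle_id"])}
    acc = np.zeros((b,) * 3, dtype=np.float64)
    cov = np.zeros((b,) * 3, dtype=np.float64) if wedge_compensation else None
    n = 0
    for _, row in t.iterrows():
        i = id_by_pid.get(row.particle_id)
        if i is None:  # symmetry-expanded copy: recover the source box
            i = id_by_pid[row.particle_id % (stack.table["particle_id"].max() + 1)]
        R = _residual_matrix(row)
        shift = np.array([row.sx, row.sy, row.sz])
        # box == T(ref); apply T^-1: rotate by R^-1 after removing the shift
        aligned = _transform_volume(stack.boxes[i], R.T, -R.T @ shift, voxel)
        acc += aligned
        n += 1
        if wedge_compensation:
            M = euler_to_matrix(row.phi, row.theta, row.psi) @ R
            cov += _wedge_mask_for((b,) * 3, tilt_range, M)
    if wedge_compensation:
        f = np.fft.fftn(acc)
        floor = 0.1 * cov.max()
        f /= np.maximum(cov, floor)
        out = np.fft.ifftn(f).real
    else:
        out = acc / n
    return Volume(out.astype(np.float32), voxel)


def apply_residuals(stack: SubtomogramStack, table: Optional[pd.DataFrame] = None
                    ) -> SubtomogramStack:
    """Fold residual transforms into the boxes; returns a registered stack.

    Each box is resampled by the inverse of its residual rotation/shift and
    the residual columns are zeroed, so downstream eigenanalysis and
    averaging see registered particles.
    """
    t = ensure_residual_columns(table if table is not None else stack.table)
    t = t.reset_index(drop=True)
    out = np.empty_like(stack.boxes)
    for i, row in t.iterrows():
        R = _residual_matrix(row)
        shift = np.array([row.sx, row.sy, row.sz])
        out[i] = _transform_volume(stack.boxes[i], R.T, -R.T @ shift, stack.voxel_size)
    t2 = t.copy()
    t2[RESIDUAL_COLUMNS] = 0.0
    # keep the consumed transform on the crop angles so wedge masks stay right
    return SubtomogramStack(out, stack.voxel_size, t2)


def register_filaments(stack: SubtomogramStack, pf_number: int = 13,
                       wall_radius: float = 10.6, repeat: float = 4.0) -> pd.DataFrame:
    """Register the lattice phase of different filaments to a common frame.

    Particles within one filament share a picking frame and are already
    mutually coherent; across filaments the azimuthal lattice phase and the
    axial register are arbitrary.  Both are measured directly on each
    per-filament average -- the axial phase of the monomer-repeat harmonic
    of the wall z-profile, and the angular phase of the pf harmonic of the
    repeat-layer cross-section (which survives the missing wedge) -- and
    folded into the particles' residual transforms.  Registration modulo one
    pf spacing and one monomer repeat is sufficient: the lattice is
    invariant under those steps.
    """
    from .classify import _angular_profile, _harmonic_fit, cross_section, layer_plane

    table = ensure_residual_columns(stack.table.copy()).reset_index(drop=True)
    b = stack.box_size
    voxel = stack.voxel_size
    c = (b - 1) / 2.0
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    fids = list(table.groupby("filament_id").indices)

    # 1) azimuthal register: pf-harmonic phase of the layer-plane magnitude
    for fid in fids:
        sub = table[table["filament_id"] == fid]
        avg = average(stack, sub)
        img = cross_section(avg, repeat=repeat)
        prof = _angular_profile(img, np.array([c, c]), wall_radius / voxel)
        _, ph = _harmonic_fit(prof - prof.mean(), theta, None, pf_number)
        table.loc[table["filament_id"] == fid, "rpsi"] += np.degrees(ph)

    # 2) axial register: global layer-plane phase against the pooled average.
    # A z-shift multiplies the whole repeat-layer plane by a unit phasor, so
    # the argument of the inner product with the pooled reference measures
    # the per-filament axial offset modulo one repeat.  Opposite-polarity
    # layers are near-orthogonal (opposite phase windings), so each filament
    # effectively registers against its own polarity class in the pool.
    for _ in range(2):
        layers = {}
        for fid in fids:
            sub = table[table["filament_id"] == fid]
            layers[fid] = layer_plane(average(stack, sub), repeat=repeat)
        pooled = np.sum(list(layers.values()), axis=0)
        for fid in fids:
            ip = np.vdot(pooled, layers[fid])
            dz = -np.angle(ip) / (2 * np.pi) * repeat
            table.loc[table["filament_id"] == fid, "sz"] += dz
    return table


def project(volume: Volume, n_slices: int = 5, axis: str = "z") -> np.ndarray:
    """Sum of n central slices perpendicular to ``axis``.

    For axis 'z' the result is image[y, x]; displayed x-right / y-up this is
    the cross-section as seen by a viewer on the +z side of the box.
    """
    ax = {"z": 0, "y": 1, "x": 2}[axis]
    dim = volume.data.shape[ax]
    if n_slices > dim:
        raise ValueError("n_slices exceeds the volume dimension")
    c = dim // 2
    lo = c - n_slices // 2
    sl = [slice(None)] * 3
    sl[ax] = slice(lo, lo + n_slices)
    return volume.data[tuple(sl)].sum(axis=ax)


def fsc(vol_a: Volume, vol_b: Volume) -> pd.DataFrame:
    """Fourier shell correlation between two equally shaped volumes.

    Returns a tidy frame with shell index, spatial frequency (1/A) and the
    per-shell normalized correlation.
    """
    if vol_a.data.shape != vol_b.data.shape:
        raise ValueError("FSC requires equal shapes")
    fa = np.fft.fftn(vol_a.data)
    fb = np.fft.fftn(vol_b.data)
    shape = vol_a.data.shape
    grids = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij")
    r = np.sqrt(sum(g * g for g in grids))
    nshell = min(shape) // 2
    edges = np.arange(nshell + 1) / min(shape)
    idx = np.clip(np.digitize(r.ravel(), edges) - 1, 0, nshell - 1)
    num = np.bincount(idx, weights=np.real(fa * np.conj(fb)).ravel(), minlength=nshell)
    den_a = np.bincount(idx, weights=(np.abs(fa) ** 2).ravel(), minlength=nshell)
    den_b = np.bincount(idx, weights=(np.abs(fb) ** 2).ravel(), minlength=nshell)
    den = np.sqrt(den_a * den_b)
    corr = np.divide(num, den, out=np.ones_like(num), where=den > 1e-30)
    freq_nm = (np.arange(nshell) + 0.5) / min(shape) / vol_a.voxel_size
    return pd.DataFrame({
        "shell": np.arange(nshell),
        "frequency_A": freq_nm / 10.0,
        "fsc": corr,
    })


def resolution_at(curve: pd.DataFrame, threshold: float) -> tuple[float, bool]:
    """Resolution (A) at the first crossing below ``threshold``.

    Linear interpolation between shells; when the curve never crosses the
    threshold the Nyquist bound is returned with ``crossed=False``.
    """
    f = curve["frequency_A"].to_numpy()
    c = curve["fsc"].to_numpy()
    for i in range(1, len(c)):
        if c[i] < threshold <= c[i - 1]:
            frac = (c[i - 1] - threshold) / (c[i - 1] - c[i])
            freq = f[i - 1] + frac * (f[i] - f[i - 1])
            return 1.0 / freq, True
    return 1.0 / f[-1], False
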