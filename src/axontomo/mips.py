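"""Luminal particle (MIP) detection, cluster cleaning, density statistics
and low-resolution averaging.

Detection samples the MT lumen densely (every 2 voxels), scores each sample
against a rotation-averaged ring-particle template by normalized
cross-correlation over the whole volume (with a spherically symmetric
template the free-rotation alignment is degenerate, so translation-only
refinement is exact), and lets nearby samples converge onto the same
particle; cluster cleaning (single linkage, e.g. at least two particles
within 5 nm) then keeps the best-scoring detection per cluster and discards
isolated hits, mirroring the picking-every-2-pixels / cluster-clean flow
used for real tomograms.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import match_template

from .align import AlignmentLimits, align, average, fsc, gaussian_sphere, resolution_at
from .extract import SubtomogramStack
from .geometry import path_arclength, resample_path
from .io import FilamentModel, Volume, new_particle_table
from .stats import SummaryStat, summarize, ttest

__all__ = [
    "mip_template",
    "detect_mips",
    "cluster_clean",
    "mip_density",
    "break_end_mip_stats",
    "average_mips",
]

# NCC acceptance threshold for candidate positions, chosen once on a
# synthetic receiver-operating curve (see docs/methods.md) and frozen.
DEFAULT_CC_THRESHOLD = 0.03


def mip_template(box_size: int = 15, voxel: float = 1.0, ring_radius: float = 3.2,
                 blob_sigma: float = 1.2, n_orient: int = 120) -> np.ndarray:
    """Rotation-averaged luminal ring particle: the matched-filter template."""
    from .synthetic import _add_blobs, mip_motif_points

    rng = np.random.default_rng(0)
    data = np.zeros((box_size,) * 3, dtype=np.float32)
    c = (box_size - 1) / 2.0 * voxel
    for _ in range(n_orient):
        pts = mip_motif_points(rng, ring_radius=ring_radius) + c
        _add_blobs(data, pts, voxel, blob_sigma, amplitude=1.0 / n_orient)
    return data


def detect_mips(volume: Volume, mt_models: list, spacing: float = 2.0,
                lumen_radius: float = 4.0, wall_radius: float = 10.6,
                cc_threshold: float = DEFAULT_CC_THRESHOLD,
                refine_radius: float = 4.0, dog_sigma: float = 2.0,
                template: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Candidate MIP positions inside each MT lumen.

    ``spacing`` is in voxels (default 2, the dense picking step).  Each
    sample position is refined to the best normalized-cross-correlation voxel
    within ``refine_radius`` nm, constrained to ``lumen_radius`` nm of the MT
    axis; samples scoring below ``cc_threshold`` are dropped.  Run
    :func:`cluster_clean` on the result.
    """
    if lumen_radius >= wall_radius:
        raise ValueError("lumen_radius must be smaller than the wall radius")
    if template is None:
        template = mip_template(voxel=volume.voxel_size)
    ncc = match_template(volume.data, template, pad_input=True, mode="reflect")
    # candidate positions come from a difference-of-Gaussians sharpened map:
    # neighbouring particles near the ~9-nm packing limit fuse into a single
    # ridge in the raw correlation, which would merge their clusters
    from scipy.ndimage import gaussian_filter

    sharp = ncc - gaussian_filter(ncc, dog_sigma) if dog_sigma > 0 else ncc
    vx = volume.voxel_size
    nz, ny, nx = volume.shape
    rows = []
    rr = int(np.ceil(refine_radius / vx))
    for model in mt_models:
        L = float(path_arclength(model.points)[-1])
        s_vals = np.arange(0.0, L + 1e-9, spacing * vx)
        centers = resample_path(model.points, s_vals)
        dense_s = np.linspace(0.0, L, max(2, int(L)))
        dense_p = resample_path(model.points, dense_s)
        axis_tree = cKDTree(dense_p)
        for s, c in zip(s_vals, centers):
            cv = (c - volume.origin) / vx  # (x, y, z) voxels
            ix, iy, iz = int(round(cv[0])), int(round(cv[1])), int(round(cv[2]))
            z0, z1 = max(0, iz - rr), min(nz, iz + rr + 1)
            y0, y1 = max(0, iy - rr), min(ny, iy + rr + 1)
            x0, x1 = max(0, ix - rr), min(nx, ix + rr + 1)
            if z0 >= z1 or y0 >= y1 or x0 >= x1:
                continue
            patch = sharp[z0:z1, y0:y1, x0:x1]
            k = np.unravel_index(np.argmax(patch), patch.shape)
            cc = float(ncc[z0 + k[0], y0 + k[1], x0 + k[2]])
            if cc < cc_threshold:
                continue
            # keep only converged candidates: an argmax on the search-window
            # boundary is sliding toward a particle centred elsewhere and
            # would bridge neighbouring clusters
            if any(ki == 0 or ki == s - 1 for ki, s in zip(k, patch.shape)):
                continue
            pos = np.array([x0 + k[2], y0 + k[1], z0 + k[0]],
                           dtype=float) * vx + volume.origin
            d_axis, j = axis_tree.query(pos)
            if d_axis > lumen_radius:
                continue
            rows.append({
                "filament_id": model.filament_id,
                "x": pos[0], "y": pos[1], "z": pos[2],
                "cc_score": cc, "arclength": float(dense_s[j]),
            })
    out = new_particle_table(len(rows))
    if rows:
        df = pd.DataFrame(rows)
        for col in df.columns:
            out[col] = df[col].to_numpy()
    return out


def _single_linkage_clusters(pos: np.ndarray, radius: float) -> np.ndarray:
    """Cluster ids by single linkage at a pairwise radius (union-find closure)."""
    n = len(pos)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(pos)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return np.array([find(i) for i in range(n)])


def cluster_clean(candidates: pd.DataFrame, radius: float = 5.0,
                  min_size: int = 2) -> pd.DataFrame:
    """Keep the best-scoring candidate of every cluster of >= min_size.

    A cluster is the single-linkage closure of "within ``radius`` nm" (the
    pairwise definition used for real data: at least two particles within
    5 nm, or at least six within 7 nm for the noisier search); smaller
    groups are discarded as isolated false positives.
    """
    if radius <= 0 or min_size < 1:
        raise ValueError("radius must be positive and min_size >= 1")
    if len(candidates) == 0:
        return candidates
    pos = candidates[["x", "y", "z"]].to_numpy()
    cid = _single_linkage_clusters(pos, radius)
    keep = []
    out = candidates.reset_index(drop=True).copy()
    out["cluster_id"] = cid
    for c, grp in out.groupby("cluster_id"):
        if len(grp) >= min_size:
            keep.append(grp["cc_score"].idxmax())
    return out.loc[sorted(keep)].reset_index(drop=True)


def mip_density(table: pd.DataFrame, mt_lengths: dict) -> tuple[pd.DataFrame, SummaryStat]:
    """Per-MT luminal particle density: count divided by MT length (per um)."""
    rows = []
    for fid, L in mt_lengths.items():
        if not L > 0:
            raise ValueError("MT lengths must be positive")
        n = int((table["filament_id"] == fid).sum()) if len(table) else 0
        rows.append({"filament_id": fid, "n_mips": n, "length_um": L / 1000.0,
                     "per_um": n / (L / 1000.0)})
    df = pd.DataFrame(rows)
    return df, summarize(df["per_um"].to_numpy())


def break_end_mip_stats(table: pd.DataFrame, mt_lengths: dict,
                        breaks: Optional[dict] = None, ends: Optional[dict] = None,
                        window: float = 100.0) -> dict:
    """Expected vs observed MIP density at lattice breaks and MT ends.

    Expected is each MT's whole-length density; observed is the density
    inside a break, in the 100-nm windows adjacent to a break (mean of the
    two sides, truncated at the MT ends), or in the 100-nm window adjacent to
    an end.  Paired two-tailed t-tests compare expected and observed across
    MTs.  Breaks of zero length are excluded with a flag.
    """
    breaks = breaks or {}
    ends = ends or {}
    arcs = {fid: table.loc[table["filament_id"] == fid, "arclength"].to_numpy()
            for fid in set(list(breaks) + list(ends))}

    def dens(fid, a, b):
        a, b = max(0.0, a), min(mt_lengths[fid], b)
        if b <= a:
            return None
        n = int(((arcs[fid] >= a) & (arcs[fid] <= b)).sum())
        return n / ((b - a) / 1000.0)

    rows, excluded = [], []
    for fid, intervals in breaks.items():
        L = mt_lengths[fid]
        exp = (table["filament_id"] == fid).sum() / (L / 1000.0)
        for (a, b) in intervals:
            if b <= a:
                excluded.append((fid, a, b))
                continue
            within = dens(fid, a, b)
            adj = [d for d in (dens(fid, a - window, a), dens(fid, b, b + window))
                   if d is not None]
            rows.append({"filament_id": fid, "feature": "break", "expected": exp,
                         "observed_within": within,
                         "observed_adjacent": float(np.mean(adj)) if adj else np.nan})
    for fid, sides in ends.items():
        L = mt_lengths[fid]
        exp = (table["filament_id"] == fid).sum() / (L / 1000.0)
        for side in sides:
            adj = dens(fid, 0.0, window) if side == "start" else dens(fid, L - window, L)
            rows.append({"filament_id": fid, "feature": "end", "expected": exp,
                         "observed_within": np.nan, "observed_adjacent": adj})
    df = pd.DataFrame(rows)
    tests = {}
    if len(df):
        b = df[df["feature"] == "break"].dropna(subset=["observed_within"])
        if len(b) >= 2:
            tests["within_break"] = ttest(b["expected"], b["observed_within"], mode="paired")
        ba = df[df["feature"] == "break"].dropna(subset=["observed_adjacent"])
        if len(ba) >= 2:
            tests["adjacent_break"] = ttest(ba["expected"], ba["observed_adjacent"], mode="paired")
        e = df[df["feature"] == "end"].dropna(subset=["observed_adjacent"])
        if len(e) >= 2:
            tests["adjacent_end"] = ttest(e["expected"], e["observed_adjacent"], mode="paired")
    return {"table": df, "tests": tests, "excluded_zero_length": excluded}


def average_mips(stack: SubtomogramStack, rounds: int = 3,
                 mask: Optional[tuple] = None, max_shift: float = 1.5,
                 fsc_threshold: float = 0.5):
    """Free-angle iterative alignment and averaging of luminal particles.

    Starts from the data's own rotational smear (the average of all boxes),
    aligns with unrestricted orientations inside a Gaussian spherical mask,
    and re-averages.  With >= 50 particles the two MT-split half-set averages
    are compared by FSC and the resolution at the 0.5 cutoff is reported;
    below that the average is still produced with a warning and no
    resolution claim.
    """
    b = stack.box_size
    voxel = stack.voxel_size
    if mask is None:
        mask = ("sphere", 4.5, 2.0)
    limits = AlignmentLimits(max_inplane=360.0, max_axial_shift=max_shift,
                             max_lateral_shift=max_shift, cone=180.0, mask=mask,
                             shift_step=voxel)
    ref = Volume(stack.boxes.mean(axis=0), voxel)
    table = stack.table
    for _ in range(rounds):
        table = align(SubtomogramStack(stack.boxes, voxel, table), ref, limits)
        ref = average(stack, table)
    result = {"average": ref, "table": table, "resolution_A": None, "fsc": None}
    if len(table) >= 50:
        fids = np.sort(table["filament_id"].unique())
        half1 = table[table["filament_id"].isin(fids[::2])]
        half2 = table[table["filament_id"].isin(fids[1::2])]
        if len(half1) and len(half2):
            v1, v2 = average(stack, half1), average(stack, half2)
            curve = fsc(v1, v2)
            res, crossed = resolution_at(curve, fsc_threshold)
            result["fsc"] = curve
            result["resolution_A"] = res if crossed else None
    else:
        warnings.warn("fewer than 50 particles: no resolution estimate")
    return result
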