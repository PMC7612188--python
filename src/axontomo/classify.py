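"""Polarity and protofilament-number classification of MT subtomograms.

The polarity route: multivariate statistical analysis (PCA of masked,
wedge-filled aligned boxes) produces ~40 eigenimages; clustering particles on
each top eigen-coordinate alone finds the one whose two class averages show
opposite tubulin slew in cross-section (the "polarity eigenvector"); those
class averages seed one round of multireference alignment (MRA); per-MT
voting assigns a polarity when strictly more than 70% of the MT's particles
(after retaining the best-scoring 80% per MT) fall in one class.

The pf-number route: three rounds of MRA against 12- and 13-pf references;
MTs with over 95% of particles in one class are auto-assigned, the rest pass
through per-class per-MT average quality gating and the >20-particle patch
rule that detects pf-number transition sites.

Slew convention: cross-sections are image[y, x] as seen from the +z (path
forward) side of the box.  Anti-clockwise slew means the plus end faces the
viewer, i.e. the plus end lies along the path direction; clockwise means the
viewer looks at the minus end face (plus end away).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import center_of_mass, map_coordinates
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .align import AlignmentLimits, align, average, cc_clean, ensure_residual_columns, project
from .extract import SubtomogramStack
from .geometry import euler_to_matrix
from .io import Volume

__all__ = [
    "EigenDecomposition",
    "ClassResult",
    "msa",
    "find_polarity_eigenvector",
    "mra",
    "vote_polarity",
    "slew_sign",
    "polarity_from_slew",
    "count_pfs",
    "assign_pf",
]


@dataclass
class EigenDecomposition:
    components: np.ndarray  # (n, b, b, b) eigenimages
    eigenvalues: np.ndarray
    coords: np.ndarray  # (N, n) per-particle projections
    mean: np.ndarray
    rank_deficient: bool = False


@dataclass
class ClassResult:
    """Per-particle class labels plus per-filament bookkeeping."""

    table: pd.DataFrame
    class_averages: list
    proportions: pd.DataFrame = field(default_factory=pd.DataFrame)
    assignments: dict = field(default_factory=dict)

    def filament_proportions(self) -> pd.DataFrame:
        rows = []
        n_classes = len(self.class_averages)
        for fid, grp in self.table.groupby("filament_id"):
            counts = np.bincount(grp["class_label"].clip(lower=0), minlength=n_classes)
            p = counts / counts.sum() if counts.sum() else counts.astype(float)
            rows.append({"filament_id": fid, "n": len(grp),
                         **{f"p_class{c}": p[c] for c in range(n_classes)}})
        return pd.DataFrame(rows)


def msa(stack: SubtomogramStack, n_components: int = 40,
        mask: Optional[np.ndarray] = None, wedge_fill: bool = True,
        tilt_range: float = 60.0, seed: int = 0) -> EigenDecomposition:
    """PCA of masked, wedge-filled aligned subtomograms.

    Missing-wedge Fourier coefficients of every box are replaced by those of
    the stack mean (mean imputation) before decomposition, so the wedge does
    not dominate the variance.  Rank-deficient stacks return fewer
    components with a flag.
    """
    from .align import _wedge_mask_for

    boxes = stack.boxes.astype(np.float64)
    n, b = len(boxes), stack.box_size
    if mask is None:
        mask = np.ones((b,) * 3, dtype=np.float64)
    if wedge_fill:
        mean_f = np.fft.fftn(boxes.mean(axis=0))
        filled = np.empty_like(boxes)
        for fid, idx in stack.table.groupby("filament_id").indices.items():
            row = stack.table.iloc[idx[len(idx) // 2]]
            M = euler_to_matrix(row.phi, row.theta, row.psi)
            wm = _wedge_mask_for((b,) * 3, tilt_range, M)
            for i in idx:
                f = np.fft.fftn(boxes[i])
                f[~wm] = mean_f[~wm]
                filled[i] = np.fft.ifftn(f).real
        boxes = filled
    flat = (boxes * mask).reshape(n, -1)
    k = min(n_components, n - 1, flat.shape[1])
    rank_deficient = k < n_components
    if rank_deficient:
        warnings.warn(f"stack supports only {k} components (requested {n_components})")
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(flat)
    return EigenDecomposition(
        components=pca.components_.reshape(k, b, b, b),
        eigenvalues=pca.explained_variance_,
        coords=coords,
        mean=pca.mean_.reshape(b, b, b),
        rank_deficient=rank_deficient,
    )


def _two_means_1d(x: np.ndarray, seed: int = 0) -> np.ndarray:
    km = KMeans(n_clusters=2, n_init=4, random_state=seed)
    return km.fit_predict(x.reshape(-1, 1))


def _angular_profile(image: np.ndarray, center, radius_vox: float, band_vox: float = 1.0,
                     n_theta: int = 720) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    prof = np.zeros(n_theta)
    radii = np.linspace(radius_vox - band_vox, radius_vox + band_vox, 3)
    for r in radii:
        ys = center[0] + r * np.sin(theta)
        xs = center[1] + r * np.cos(theta)
        prof += map_coordinates(image.astype(float), [ys, xs], order=1, mode="nearest")
    return prof / len(radii)


def wall_visibility_weights(theta: np.ndarray, orientation: np.ndarray,
                            tilt_range: float = 60.0, floor: float = 0.02) -> np.ndarray:
    """Missing-wedge visibility of the MT wall at each cross-section angle.

    A wall sector is resolved only when its outward normal (frequency
    direction) lies inside the sampled wedge of the tilt series.  ``theta``
    is in radians in the box cross-section; ``orientation`` is the box-to-
    tomogram rotation matrix.  Returns weights in [floor, 1].
    """
    r_box = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    r_tomo = orientation @ r_box
    ang = np.degrees(np.arctan2(np.abs(r_tomo[2]), np.abs(r_tomo[0])))
    # smooth rolloff over a few degrees around the wedge boundary
    w = np.clip((tilt_range + 2.0 - ang) / 6.0, 0.0, 1.0)
    return np.maximum(w, floor)


def _harmonic_fit(prof: np.ndarray, theta: np.ndarray, weights: Optional[np.ndarray],
                  n: int):
    """Weighted LS fit of a single angular harmonic: returns (power, phase)."""
    w = np.ones_like(prof) if weights is None else weights
    A = np.column_stack([np.cos(n * theta), np.sin(n * theta), np.ones_like(theta)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], prof * sw, rcond=None)
    a, b = coef[0], coef[1]
    return a * a + b * b, np.arctan2(b, a) / n


def _dominant_harmonic(prof: np.ndarray, weights: Optional[np.ndarray] = None,
                       candidates=range(11, 16), theta: Optional[np.ndarray] = None):
    """Strongest wall harmonic by (wedge-)weighted least squares.

    Returns (n, phase, peak/runner-up power ratio, power-vs-background SNR).
    """
    if theta is None:
        theta = np.linspace(0.0, 2 * np.pi, len(prof), endpoint=False)
    p = prof - prof.mean()
    powers = {}
    phases = {}
    for nh in candidates:
        powers[nh], phases[nh] = _harmonic_fit(p, theta, weights, nh)
    nh = max(powers, key=powers.get)
    ranked = sorted(powers.values())[::-1]
    ratio = ranked[0] / ranked[1] if ranked[1] > 0 else np.inf
    bg = [_harmonic_fit(p, theta, weights, m)[0]
          for m in range(5, 31) if m not in powers]
    mbg = float(np.mean(bg))
    snr = powers[nh] / mbg if mbg > 0 else np.inf
    return nh, phases[nh], ratio, snr


def layer_plane(volume: Volume, repeat: float = 4.0) -> np.ndarray:
    """Complex Fourier layer plane of the monomer axial repeat.

    Returns the 2D inverse transform of the kz = 1/repeat plane of the box
    spectrum (the plane with the most energy among the nearest three).  This
    sideband of the lattice repeat lies outside the missing wedge for any
    filament orientation; its magnitude shows the pf ring and its phase
    winds with the helical-start handedness, i.e. with MT polarity.
    """
    b = volume.data.shape[0]
    f = np.fft.fftn(volume.data)
    j0 = int(round(b * volume.voxel_size / repeat))
    best = None
    for j in (j0 - 1, j0, j0 + 1):
        if not 1 <= j < b:
            continue
        img = np.fft.ifft2(f[j])
        e = float(np.abs(img).sum())
        if best is None or e > best[0]:
            best = (e, img)
    return best[1]


def cross_section(volume: Volume, mode: str = "layer", repeat: float = 4.0,
                  n_slices: int = 5) -> np.ndarray:
    """2D cross-section image of an MT average for angular analysis.

    mode 'projection' sums ``n_slices`` central z-slices.  mode 'layer'
    (default) extracts the Fourier plane at the monomer axial repeat
    (kz = 1/repeat) and returns its 2D inverse-transform magnitude: this
    sideband of the lattice repeat lies outside the missing wedge for any
    filament orientation, so the full pf ring survives wedge corruption that
    blanks most of the plain projection.
    """
    if mode == "projection":
        return project(volume, n_slices=min(n_slices, volume.data.shape[0]), axis="z")
    return np.abs(layer_plane(volume, repeat=repeat))


def _ring_winding(volume: Volume, r_wall: float = 10.6, repeat: float = 4.0):
    """Winding number of the repeat-layer phase around the MT wall.

    For a lattice with per-pf helical rise dz the layer-plane phase advances
    by 2*pi*dz/repeat per pf, i.e. winds ~3 full turns per revolution for
    the 13-pf MT; the winding sign flips with polarity.  Returns (winding,
    coherence in [0, 1]).
    """
    Lc = layer_plane(volume, repeat=repeat)
    b = Lc.shape[0]
    c = (b - 1) / 2.0
    voxel = volume.voxel_size
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    v = np.zeros(720, dtype=complex)
    for r in (r_wall - 1.0, r_wall, r_wall + 1.0):
        ys = c + (r / voxel) * np.sin(theta)
        xs = c + (r / voxel) * np.cos(theta)
        re = map_coordinates(Lc.real, [ys, xs], order=1, mode="nearest")
        im = map_coordinates(Lc.imag, [ys, xs], order=1, mode="nearest")
        v += re + 1j * im
    steps = np.conj(v) * np.roll(v, -1)
    W = steps.sum()
    denom = np.sum(np.abs(v) * np.abs(np.roll(v, -1)))
    coherence = float(np.abs(W) / denom) if denom > 0 else 0.0
    winding = float(np.angle(W) * len(v) / (2 * np.pi))
    return winding, coherence


def slew_sign(section, r_inner: float = 8.0, r_outer: float = 13.0,
              voxel: float = 1.0, min_lag: float = 0.5,
              min_power_snr: float = 8.0, weights: Optional[np.ndarray] = None,
              r_wall: float = 10.6):
    """Clockwise/anti-clockwise tubulin slew of an MT cross-section.

    ``section`` is a 2D cross-section image (or a Volume, from which the
    repeat-layer cross-section is taken).  The dominant pf harmonic's phase
    is fitted at several radii between ``r_inner`` and ``r_outer`` (nm) and
    regressed against radius; the slope's sign gives the handedness, its
    integral over the radial band the lag in degrees.  Returns (label,
    lag_degrees) with label in {'cw', 'ccw', 'undetermined'}; off-centre
    images (centre of mass more than 2 voxels out) are recentred first.
    """
    if isinstance(section, Volume):
        # primary cue: helical-start phase winding of the repeat layer
        winding, coherence = _ring_winding(section, r_wall=r_wall)
        if coherence >= 0.2 and 0.5 <= abs(winding) <= 4.5:
            # calibrated once on rendered references: plus end toward the
            # viewer (anti-clockwise slew) gives a negative measured winding
            return ("ccw" if winding < 0 else "cw"), -winding
        # fall back to the radial lag of the wall pattern (monomer tilt cue)
        voxel = section.voxel_size
        img = cross_section(section)
    else:
        img = np.asarray(section, dtype=float)
    ny, nx = img.shape
    center = np.array([(ny - 1) / 2.0, (nx - 1) / 2.0])
    w = img - img.min()
    if w.sum() > 0:
        com = np.asarray(center_of_mass(w))
        if np.linalg.norm(com - center) > 2.0:
            center = com
    radii = np.linspace(r_inner, r_outer, 6)
    profs = [_angular_profile(img, center, r / voxel) for r in radii]
    mid = _dominant_harmonic(profs[len(profs) // 2], weights)
    nh = mid[0]
    if mid[3] < min_power_snr:
        return "undetermined", 0.0
    phases, powers = [], []
    for p in profs:
        pw, ph = _harmonic_fit(p - p.mean(),
                               np.linspace(0, 2 * np.pi, len(p), endpoint=False),
                               weights, nh)
        phases.append(ph)
        powers.append(pw)
    phases = np.asarray(phases)
    powers = np.asarray(powers)
    if powers.max() <= 0:
        return "undetermined", 0.0
    # unwrap the n-fold-periodic phases about the strongest radius
    half = np.pi / nh
    ref = phases[np.argmax(powers)]
    phases = ref + ((phases - ref + half) % (2 * half) - half)
    slope, intercept = np.polyfit(radii, phases, 1, w=np.sqrt(powers))
    resid = phases - (slope * radii + intercept)
    # a real wall pattern drifts smoothly with radius; incoherent phases
    # across radii mean the harmonic is noise
    if np.degrees(np.sqrt(np.mean(resid**2))) > 3.0:
        return "undetermined", 0.0
    lag_deg = float(np.degrees(slope * (r_outer - r_inner)))
    if abs(lag_deg) < min_lag:
        return "undetermined", lag_deg
    return ("ccw" if lag_deg > 0 else "cw"), lag_deg


def polarity_from_slew(label: str) -> str:
    """Map a slew label of a box-frame cross-section to filament polarity.

    Anti-clockwise slew (viewer on the path-forward side) means the plus end
    points along the path.
    """
    return {"ccw": "plus_along_path", "cw": "minus_along_path"}.get(label, "unclear")


def mean_orientation(table: pd.DataFrame) -> np.ndarray:
    """Representative box-to-tomogram rotation: the median particle's."""
    row = table.iloc[len(table) // 2]
    return euler_to_matrix(row.phi, row.theta, row.psi)


def count_pfs(mt_average: Volume, r_wall: float = 10.6, band: float = 3.0,
              min_ratio: float = 1.5, min_power_snr: float = 3.0,
              mode: str = "layer", weights: Optional[np.ndarray] = None):
    """Protofilament count from the angular power of the wall annulus.

    The cross-section (wedge-robust repeat layer by default, or the 5-slice
    projection with ``mode='projection'``) is unwrapped to polar coordinates
    over ``r_wall +- band`` nm; the pf count is the harmonic (11..15) with
    maximal fitted power.  'ND' when the peak-to-runner-up power ratio is
    below ``min_ratio`` or the peak does not stand above the spectral
    background.
    """
    img = cross_section(mt_average, mode=mode)
    voxel = mt_average.voxel_size
    ny, nx = img.shape
    center = np.array([(ny - 1) / 2.0, (nx - 1) / 2.0])
    radii = np.linspace((r_wall - band) / voxel, (r_wall + band) / voxel, 7)
    prof = np.zeros(720)
    for r in radii:
        prof += _angular_profile(img, center, r, band_vox=0.0)
    nh, _, ratio, snr = _dominant_harmonic(prof, weights)
    if ratio < min_ratio or snr < min_power_snr:
        return "ND"
    return int(nh)


def find_polarity_eigenvector(decomp: EigenDecomposition, stack: SubtomogramStack,
                              r_inner: float = 8.0, r_outer: float = 13.0,
                              top: int = 20, seed: int = 0,
                              tilt_range: float = 60.0):
    """Scan the top eigen-coordinates for the one separating the two polarities.

    Each coordinate is 2-means clustered on its own; the component whose two
    cluster averages show opposite slew signs, with the largest slew-score
    difference, is the polarity eigenvector.  Returns (component_index,
    cluster_labels, (vol_a, vol_b)).
    """
    n_comp = decomp.coords.shape[1]
    best = None
    for c in range(min(top, n_comp)):
        labels = _two_means_1d(decomp.coords[:, c], seed=seed)
        if labels.min() == labels.max():
            continue
        vols, signs, scores = [], [], []
        for g in (0, 1):
            avg = stack.boxes[labels == g].mean(axis=0)
            vols.append(Volume(avg, stack.voxel_size))
            s, lag = slew_sign(vols[-1], r_inner, r_outer)
            signs.append(s)
            scores.append(lag)
        if {"cw", "ccw"} == set(signs):
            sep = abs(scores[0] - scores[1])
            if best is None or sep > best[0]:
                best = (sep, c, labels, tuple(vols))
    if best is None:
        raise ValueError("polarity eigenvector not found: no component separates slew signs")
    return best[1], best[2], best[3]


def register_to_references(stack: SubtomogramStack, references: list,
                           angle_step: float = 3.0, max_axial_shift: float = 2.2,
                           wedge_aware: bool = True, tilt_range: float = 60.0) -> list:
    """Pre-rotate references into the register of this filament's particles.

    The pooled particle average (far less noisy than any single particle) is
    aligned to each reference over the full in-plane range; each reference
    is then resampled by the recovered spin/shift so that a subsequent MRA
    can run within the constrained refinement limits.  This mirrors the
    initial-alignment stage that precedes classification in subtomogram
    pipelines, and is required here because the helical lattice phase is
    only determined modulo 360 degrees, not modulo one pf spacing.
    """
    from .align import _transform_volume
    from .io import new_particle_table

    avg = average(stack)
    mini = new_particle_table(1)
    mini.loc[0, ["phi", "theta", "psi"]] = stack.table.iloc[len(stack.table) // 2][
        ["phi", "theta", "psi"]].to_numpy()
    one = SubtomogramStack(avg.data[None], stack.voxel_size, mini)
    full = AlignmentLimits(max_inplane=180.0, angle_step=angle_step,
                           max_axial_shift=max_axial_shift)
    out = []
    for ref in references:
        t = align(one, ref, full, wedge_aware=wedge_aware, tilt_range=tilt_range)
        R = euler_to_matrix(t.loc[0, "rphi"], t.loc[0, "rtheta"], t.loc[0, "rpsi"])
        shift = t.loc[0, ["sx", "sy", "sz"]].to_numpy(dtype=float)
        out.append(Volume(
            _transform_volume(ref.data, R, shift, ref.voxel_size).astype(np.float32),
            ref.voxel_size))
    return out


def mra(stack: SubtomogramStack, references: list, rounds: int = 1,
        limits: Optional[AlignmentLimits] = None, wedge_aware: bool = False,
        tilt_range: float = 60.0,
        first_round_limits: Optional[AlignmentLimits] = None) -> ClassResult:
    """Multireference alignment: align against every reference, assign argmax.

    References are re-averaged from their members between rounds and
    particles may switch classes each round; a class that empties keeps its
    frozen reference with a warning.  ``first_round_limits`` allows a wider
    (e.g. full in-plane) search in round one when particles are not yet
    phase-registered to the external references; later rounds use
    ``limits`` since the re-averaged references sit in the data's register.
    """
    if len(references) < 2:
        raise ValueError("MRA needs at least 2 references")
    if limits is None:
        limits = AlignmentLimits()
    refs = [r.copy() for r in references]
    table = ensure_residual_columns(stack.table.copy()).reset_index(drop=True)
    for rnd in range(rounds):
        lim = first_round_limits if (rnd == 0 and first_round_limits is not None) else limits
        per_ref = [align(stack, ref, lim, wedge_aware=wedge_aware,
                         tilt_range=tilt_range) for ref in refs]
        ccs = np.stack([t["cc_score"].to_numpy() for t in per_ref])
        winner = np.argmax(ccs, axis=0)
        for i in range(len(table)):
            w = winner[i]
            table.loc[i, "class_label"] = w
            table.loc[i, "cc_score"] = ccs[w, i]
            for col in ("rphi", "rtheta", "rpsi", "sx", "sy", "sz"):
                table.loc[i, col] = per_ref[w].loc[i, col]
        for ci in range(len(refs)):
            members = table[table["class_label"] == ci]
            if len(members) == 0:
                warnings.warn(f"class {ci} emptied; reference frozen")
                continue
            refs[ci] = average(stack, members, wedge_compensation=False)
    result = ClassResult(table=table, class_averages=refs)
    result.proportions = result.filament_proportions()
    return result


def vote_polarity(result: ClassResult, threshold: float = 0.70,
                  pre_clean: float = 0.80, r_inner: float = 8.0,
                  r_outer: float = 13.0, tilt_range: float = 60.0) -> dict:
    """Per-filament polarity votes after per-MT cross-correlation cleaning.

    Class polarity labels are attached by the slew sign of the class
    averages; a filament is assigned iff strictly more than ``threshold`` of
    its retained particles share a class.  Returns {filament_id: 'plus' |
    'minus' | 'unclear'} where plus/minus mean plus/minus end along the
    picking direction.
    """
    class_pol = {}
    for ci, ref in enumerate(result.class_averages):
        s, _ = slew_sign(ref, r_inner, r_outer)
        class_pol[ci] = polarity_from_slew(s)
    votes = {}
    for fid, grp in result.table.groupby("filament_id"):
        grp = cc_clean(grp, fraction=pre_clean)
        if len(grp) == 0:
            votes[fid] = "unclear"
            continue
        counts = grp["class_label"].value_counts()
        top_class = counts.idxmax()
        if counts.max() / len(grp) > threshold and class_pol.get(top_class) not in (None, "unclear"):
            votes[fid] = "plus" if class_pol[top_class] == "plus_along_path" else "minus"
        else:
            votes[fid] = "unclear"
    result.assignments = votes
    return votes


def _smooth_labels(labels: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Absorb isolated flips shorter than ``min_run`` into their neighbours."""
    lab = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(lab)
        for k, (a, b, v) in enumerate(runs):
            if b - a < min_run and len(runs) > 1:
                left = runs[k - 1][2] if k > 0 else None
                right = runs[k + 1][2] if k + 1 < len(runs) else None
                fill = left if left is not None else right
                lab[a:b] = fill
                changed = True
                break
    return lab


def _runs(labels: np.ndarray):
    out = []
    a = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[a]:
            out.append((a, i, labels[a]))
            a = i
    return out


def assign_pf(result: ClassResult, stack: SubtomogramStack,
              class_pf: Optional[dict] = None, auto_threshold: float = 0.95,
              min_patch: int = 20, min_particles: int = 5,
              r_wall: float = 10.6, smooth_run: int = 3,
              tilt_range: float = 60.0) -> pd.DataFrame:
    """Per-filament pf architecture: 12, 13, ND or a transition with position.

    MTs with over ``auto_threshold`` of particles in one class are assigned
    automatically.  Otherwise the per-class per-MT averages are quality-gated
    with :func:`count_pfs`; if both classes pass and each forms a contiguous
    run of strictly more than ``min_patch`` particles (after absorbing
    isolated flips shorter than ``smooth_run``), the MT carries a pf-number
    transition, located at the arclength midpoint between the facing run
    ends.
    """
    if class_pf is None:
        class_pf = {}
        for ci, ref in enumerate(result.class_averages):
            class_pf[ci] = count_pfs(ref, r_wall=r_wall)
    rows = []
    for fid, grp in result.table.groupby("filament_id"):
        grp = grp.sort_values("arclength")
        labels = grp["class_label"].to_numpy()
        arcs = grp["arclength"].to_numpy()
        counts = pd.Series(labels).value_counts()
        p_top = counts.max() / len(grp)
        top = counts.idxmax()
        entry = {"filament_id": fid, "n": len(grp), "transition_nm": np.nan}
        for ci in class_pf:
            entry[f"p_class{ci}"] = float((labels == ci).mean())
        if p_top > auto_threshold:
            entry["assignment"] = str(class_pf.get(top, "ND"))
            rows.append(entry)
            continue
        passing = {}
        for ci in sorted(class_pf):
            members = grp[grp["class_label"] == ci]
            if len(members) < min_particles:
                continue
            avg = average(stack, members)
            if (count_pfs(avg, r_wall=r_wall) == class_pf[ci]
                    and class_pf[ci] != "ND"):
                passing[ci] = True
        if len(passing) == 2:
            lab = _smooth_labels(labels, min_run=smooth_run)
            runs = _runs(lab)
            best_run = {}
            for a, b, v in runs:
                if v in passing and (v not in best_run or b - a > best_run[v][1] - best_run[v][0]):
                    best_run[v] = (a, b)
            if len(best_run) == 2 and all(b - a > min_patch for a, b in best_run.values()):
                (a0, b0), (a1, b1) = sorted(best_run.values())
                entry["assignment"] = "transition"
                entry["transition_nm"] = 0.5 * (arcs[b0 - 1] + arcs[a1])
                rows.append(entry)
                continue
            entry["assignment"] = str(class_pf[top]) if top in passing else str(class_pf[max(passing)])
        elif len(passing) == 1:
            entry["assignment"] = str(class_pf[next(iter(passing))])
        else:
            entry["assignment"] = "ND"
        rows.append(entry)
    return pd.DataFrame(rows)
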