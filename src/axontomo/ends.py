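"""Protofilament behaviour at MT ends from traced per-pf contours.

Each end is a set of per-pf point paths; the first two points of every
contour lie on the straight MT wall and define the local axis.  From these
the deviation path of each pf after it leaves the wall (axial advance vs
outward radial deviation), the taper length (axial spread of the pf
terminal points) and the polarity-resolved end census are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import summarize, ttest

__all__ = ["EndContours", "pf_deviation_paths", "taper_length", "end_census",
           "read_end_contours"]


@dataclass
class EndContours:
    """Per-pf traced 3D point paths (nm) at one MT end."""

    contours: list  # of (k, 3) arrays, first two points on the straight wall
    end_id: int = 0
    filament_id: int = 0
    end_side: str = "path_end"  # or "path_start"

    def __post_init__(self):
        self.contours = [np.asarray(c, dtype=float).reshape(-1, 3) for c in self.contours]
        for c in self.contours:
            if len(c) < 2:
                raise ValueError("every contour needs at least 2 points")
        if self.end_side not in ("path_start", "path_end"):
            raise ValueError("end_side must be path_start or path_end")
        dirs = self._wall_dirs()
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                ang = np.degrees(np.arccos(np.clip(abs(np.dot(dirs[i], dirs[j])), -1, 1)))
                if ang >= 15.0:
                    raise ValueError(
                        f"wall segments of contours {i} and {j} diverge by {ang:.1f} deg"
                    )

    def _wall_dirs(self) -> np.ndarray:
        d = np.array([c[1] - c[0] for c in self.contours])
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(origin, unit direction): mean wall-segment direction through the
        centroid of the contour start points."""
        u = self._wall_dirs().mean(axis=0)
        u /= np.linalg.norm(u)
        c0 = np.mean([c[0] for c in self.contours], axis=0)
        return c0, u

    def wall_radius(self) -> float:
        c0, u = self.axis()
        r = []
        for c in self.contours:
            for p in c[:2]:
                v = p - c0
                r.append(np.linalg.norm(v - np.dot(v, u) * u))
        return float(np.mean(r))


def pf_deviation_paths(end: EndContours, threshold: float = 2.0) -> list:
    """Per-pf (axial advance s, radial deviation d) paths after leaving the wall.

    For each contour, points whose radial distance from the wall cylinder
    exceeds ``threshold`` nm (one monomer radius by default) are emitted as
    (s, d) pairs in nm.  The departure origin s=0 is estimated by
    extrapolating sqrt(d) linearly back to d=0 over the first deviating
    points, which recovers the tangency point of a smoothly curving pf.  A
    contour that never deviates yields an empty path (a straight pf).
    """
    c0, u = end.axis()
    r_wall = end.wall_radius()
    paths = []
    for c in end.contours:
        v = c - c0
        ax = v @ u
        rad = np.linalg.norm(v - np.outer(ax, u), axis=1)
        dev = rad - r_wall
        over = np.nonzero(dev[1:] > threshold)[0] + 1
        if len(over) == 0:
            paths.append(np.empty((0, 2)))
            continue
        first = over[0]
        # estimate the tangency point from the first few points with real deviation
        fit_idx = [i for i in range(1, len(c)) if dev[i] > 0.05][:4]
        if len(fit_idx) >= 2:
            s_fit = ax[fit_idx]
            q_fit = np.sqrt(dev[fit_idx])
            slope, intercept = np.polyfit(s_fit, q_fit, 1)
            s0 = -intercept / slope if slope > 1e-9 else ax[first - 1]
            s0 = min(s0, ax[first])
        else:
            s0 = ax[first - 1]
        pts = np.column_stack([ax[first:] - s0, dev[first:]])
        if end.end_side == "path_start":
            # advance is measured in the growth direction of this end
            pts[:, 0] = np.abs(pts[:, 0])
        paths.append(pts)
    return paths


def taper_length(end: EndContours) -> float:
    """Axial distance between the longest and shortest pf terminal points (nm)."""
    if len(end.contours) < 2:
        raise ValueError("taper length needs at least two traced pfs")
    c0, u = end.axis()
    term = np.array([np.dot(c[-1] - c0, u) for c in end.contours])
    return float(term.max() - term.min())


def end_census(ends: list, polarity_assignments: dict) -> dict:
    """Polarity-resolved end bookkeeping with taper summaries and t-tests.

    ``polarity_assignments`` maps filament_id to 'plus'/'minus'/'unclear'
    (plus = plus end along the picking path).  An end at path_end of a 'plus'
    filament is a plus end; at path_start a minus end; 'unclear' or missing
    filaments give ND with a warning.  Returns the per-end table, per-label
    taper summaries, and unpaired two-tailed t-tests between labels.
    """
    rows = []
    for e in ends:
        pol = polarity_assignments.get(e.filament_id)
        if pol is None:
            warnings.warn(f"filament {e.filament_id} missing from polarity table; ND")
            label = "ND"
        elif pol == "unclear":
            label = "ND"
        else:
            at_end = e.end_side == "path_end"
            if pol == "plus":
                label = "plus" if at_end else "minus"
            else:
                label = "minus" if at_end else "plus"
        rows.append({"end_id": e.end_id, "filament_id": e.filament_id,
                     "side": e.end_side, "polarity_label": label,
                     "taper": taper_length(e), "n_pf_traced": len(e.contours)})
    table = pd.DataFrame(rows)
    summaries = {lab: summarize(grp["taper"])
                 for lab, grp in table.groupby("polarity_label")}
    tests = {}
    labs = sorted(summaries)
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            a = table.loc[table["polarity_label"] == labs[i], "taper"]
            b = table.loc[table["polarity_label"] == labs[j], "taper"]
            if len(a) >= 2 and len(b) >= 2:
                tests[f"{labs[i]}_vs_{labs[j]}"] = ttest(a, b, mode="unpaired")
    return {"table": table, "summaries": summaries, "tests": tests}


def read_end_contours(path, voxel_size: float, filament_id: int = 0,
                      end_side: str = "path_end") -> list:
    """Read ends from model2point text: one object per end, one contour per pf."""
    groups: dict[int, dict[int, list]] = {}
    with open(path) as f:
        for line in f:
            parts = line.split()
            if not parts:
                continue
            obj, cont = int(parts[0]), int(parts[1])
            xyz = [float(v) * voxel_size for v in parts[2:5]]
            groups.setdefault(obj, {}).setdefault(cont, []).append(xyz)
    ends = []
    for obj in sorted(groups):
        contours = [np.asarray(groups[obj][c]) for c in sorted(groups[obj])]
        ends.append(EndContours(contours=contours, end_id=obj - 1,
                                filament_id=filament_id, end_side=end_side))
    return ends
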