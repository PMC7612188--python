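"""Measurement arithmetic and statistics shared by all quantification stages.

Summary statistics are mean +- SD (n-1 denominator) with n; t-tests are
classic Student tests (pooled variance for unpaired, scipy backends).
Rounding to the 2-3 significant figures used in reports happens only at the
report layer; internals keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .geometry import path_arclength
from .io import FilamentModel

__all__ = [
    "SummaryStat",
    "summarize",
    "round_sig",
    "diameter_peak_to_peak",
    "visible_length",
    "layer_line_spectrum",
    "densities",
    "ttest",
    "wall_thickness_ratio",
]


@dataclass
class SummaryStat:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def __str__(self):
        return f"{self.mean:.3g} ± {self.sd:.3g} (n = {self.n})"


def summarize(values) -> SummaryStat:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return SummaryStat(mean=float(v.mean()), sd=sd, n=int(v.size))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to significant figures (report layer only)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def diameter_peak_to_peak(profile: np.ndarray, voxel: float) -> float:
    """Separation of the two dominant intensity peaks in a wall-crossing profile.

    Peaks are refined to sub-voxel precision by parabolic interpolation, the
    way wall-to-wall diameters are measured on line profiles across an MT or
    membrane compartment.  Fewer than two peaks above the noise floor is an
    error.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 5:
        raise ValueError("profile too short")
    floor = p.mean() + 0.1 * (p.max() - p.mean()) if p.max() > p.mean() else np.inf
    peaks, props = _signal.find_peaks(p, height=floor)
    if len(peaks) < 2:
        raise ValueError("fewer than two peaks above the noise floor")
    order = np.argsort(props["peak_heights"])[::-1][:2]
    i, j = sorted(peaks[order])
    return abs(_parabolic_refine(p, j) - _parabolic_refine(p, i)) * voxel


def visible_length(model) -> float:
    """Polyline arclength (nm) of a traced filament -- its visible length."""
    pts = model.points if isinstance(model, FilamentModel) else np.asarray(model, float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("visible_length needs at least 2 points")
    return float(path_arclength(pts)[-1])


def layer_line_spectrum(image: np.ndarray, voxel: float, axial_axis: int = 1,
                        min_spacing: float = 3.0, z_cut: float = 6.0):
    """Axial repeat of a filament from its 2D Fourier layer lines.

    The filament axis must run along ``axial_axis`` of the image (1 = rows
    run along the filament).  Returns (spectrum DataFrame, spacing_nm or
    None): the power summed over transverse frequency, its axial-frequency
    axis, and the real-space spacing of the strongest off-equator layer line,
    or None when no line stands ``z_cut`` SDs above the spectral background.
    """
    img = np.asarray(image, dtype=float)
    f = np.fft.fft2(img - img.mean())
    power = np.abs(f) ** 2
    collapsed = power.sum(axis=1 - axial_axis)
    n = img.shape[axial_axis]
    freqs = np.fft.fftfreq(n, d=voxel)
    half = slice(1, n // 2)
    freq_pos = freqs[half]
    pw = collapsed[half]
    spec = pd.DataFrame({"frequency_per_nm": freq_pos, "power": pw})
    valid = freq_pos <= 1.0 / min_spacing
    # exclude the near-equator bins that hold the filament envelope
    valid &= freq_pos > 0.03
    if not valid.any():
        return spec, None
    i = np.argmax(np.where(valid, pw, -np.inf))
    bg = pw[valid & (np.arange(len(pw)) != i)]
    if len(bg) and pw[i] < bg.mean() + z_cut * bg.std():
        return spec, None
    return spec, float(1.0 / freq_pos[i])


def densities(count: float, length_um: float, width_um: float) -> dict:
    """Linear and areal feature densities (per um and per um^2)."""
    if length_um <= 0 or width_um <= 0:
        raise ValueError("length and width must be positive")
    per_um = count / length_um
    return {"per_um": per_um, "per_um2": per_um / width_um}


def ttest(a, b, mode: str = "unpaired", tails: int = 2) -> dict:
    """Student's t-test: pooled-variance unpaired, or paired; two-tailed.

    Returns {t, df, p} plus a ``degenerate`` flag for the zero-variance,
    equal-mean case where p is 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if mode == "paired":
        if len(a) != len(b):
            raise ValueError("paired test requires equal n")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return {"t": 0.0, "df": len(a) - 1, "p": 1.0, "degenerate": True}
            return {"t": np.inf * np.sign(d.mean()), "df": len(a) - 1, "p": 0.0,
                    "degenerate": True}
        r = _stats.ttest_rel(a, b)
        df = len(a) - 1
    elif mode == "unpaired":
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            if np.allclose(a.mean(), b.mean()):
                return {"t": 0.0, "df": len(a) + len(b) - 2, "p": 1.0, "degenerate": True}
            return {"t": np.inf * np.sign(a.mean() - b.mean()),
                    "df": len(a) + len(b) - 2, "p": 0.0, "degenerate": True}
        r = _stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    else:
        raise ValueError("mode must be 'unpaired' or 'paired'")
    p = float(r.pvalue)
    if tails == 1:
        p /= 2.0
    return {"t": float(r.statistic), "df": df, "p": p, "degenerate": False}


def wall_thickness_ratio(widths_a, widths_b) -> dict:
    """Paired comparison of two wall thicknesses measured per tomogram.

    ``widths_a`` and ``widths_b`` are per-tomogram mean thicknesses of the
    two structures (e.g. vault wall vs adjacent lipid bilayer).  Returns the
    per-tomogram ratios, their mean, and a paired two-tailed t-test (a single
    pair returns the ratio without a test).
    """
    a = np.asarray(widths_a, dtype=float)
    b = np.asarray(widths_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measurements must align")
    ratios = a / b
    out = {"ratios": ratios, "mean_ratio": float(ratios.mean())}
    if len(a) >= 2:
        out["test"] = ttest(a, b, mode="paired")
    return out
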