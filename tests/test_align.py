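"""Alignment, cleaning, symmetry expansion, averaging, projections, FSC."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import shift as ndshift

from axontomo.align import (
    AlignmentLimits,
    align,
    average,
    cc_clean,
    distance_clean,
    fsc,
    project,
    resolution_at,
    symmetry_expand,
    _radial_grids,
)
from axontomo.extract import SubtomogramStack
from axontomo.io import Volume, new_particle_table


def one_box_stack(data, voxel=1.0):
    return SubtomogramStack(np.asarray(data, dtype=np.float32)[None], voxel,
                            new_particle_table(1))


class TestAlign:
    def test_self_alignment_perfect(self, ref13):
        t = align(one_box_stack(ref13.data), ref13, AlignmentLimits(max_inplane=4))
        assert t.cc_score[0] == pytest.approx(1.0, abs=1e-6)
        assert abs(t.rpsi[0]) < 1e-9 and abs(t.sz[0]) < 1e-9

    def test_planted_axial_shift_recovered(self, ref13):
        shifted = ndshift(ref13.data, (1.5, 0, 0), order=1)
        t = align(one_box_stack(shifted), ref13, AlignmentLimits(max_inplane=4))
        assert t.sz[0] == pytest.approx(1.5, abs=0.5)

    def test_shift_beyond_limit_clamped(self, ref13):
        shifted = ndshift(ref13.data, (5.0, 0, 0), order=1)
        t = align(one_box_stack(shifted), ref13, AlignmentLimits(max_inplane=4))
        assert abs(t.sz[0]) <= 2.2

    def test_all_zero_box_flagged(self, ref13):
        t = align(one_box_stack(np.zeros((33, 33, 33))), ref13, AlignmentLimits())
        assert t.cc_score[0] == -1.0
        assert not t.keep_flag[0]


class TestCCClean:
    def test_keeps_80_percent_per_filament(self):
        t = new_particle_table(10)
        t["cc_score"] = np.arange(1, 11) / 10.0
        kept = cc_clean(t, fraction=0.8)
        assert len(kept) == 8
        assert kept["cc_score"].min() == pytest.approx(0.3)

    def test_fraction_one_is_identity(self):
        t = new_particle_table(7)
        t["cc_score"] = np.random.default_rng(0).uniform(size=7)
        assert len(cc_clean(t, fraction=1.0)) == 7

    def test_ceil_never_empties_small_groups(self):
        t = new_particle_table(5)
        t["cc_score"] = [0.1, 0.2, 0.3, 0.4, 0.5]
        assert len(cc_clean(t, fraction=0.8)) == 4


class TestDistanceClean:
    def _pair(self, dist, dspin, scores=(0.8, 0.6)):
        t = new_particle_table(2)
        t[["x", "y", "z"]] = [[0.0, 0.0, 0.0], [dist, 0.0, 0.0]]
        t["psi"] = [0.0, dspin]
        t["cc_score"] = scores
        return t

    def test_close_and_parallel_removes_lower_score(self):
        out = distance_clean(self._pair(2.0, 10.0))
        assert len(out) == 1 and out["cc_score"].iloc[0] == 0.8

    def test_close_but_divergent_kept(self):
        assert len(distance_clean(self._pair(2.0, 30.0))) == 2

    def test_far_but_parallel_kept(self):
        assert len(distance_clean(self._pair(5.0, 10.0))) == 2


class TestSymmetryExpand:
    def test_copy_count_and_cumulative_rotation(self):
        t = new_particle_table(1)
        out = symmetry_expand(t)
        assert len(out) == 13
        assert out["rpsi"].max() == pytest.approx(12 * 27.69)
        assert out["sz"].max() == pytest.approx(12 * 0.92)

    def test_symmetric_phantom_average_unchanged(self):
        # a z-invariant 13-fold tube is invariant under the helical step, so
        # expansion must not change its average (away from the box edges)
        z, y, x = _radial_grids(33, 1.0)
        th = np.arctan2(y, x)
        r = np.hypot(x, y)
        phantom = (np.exp(-0.5 * ((r - 10.6) / 2.0) ** 2)
                   * (1 + np.cos(13 * th))).astype(np.float32)
        stack = one_box_stack(phantom)
        plain = average(stack).data
        expanded = average(stack, symmetry_expand(stack.table)).data
        # the cumulative rise shifts content one way; compare inside the
        # region every expanded copy still covers
        core = (slice(4, 19), slice(10, 23), slice(10, 23))
        cc = np.corrcoef(plain[core].ravel(), expanded[core].ravel())[0, 1]
        # trilinear interpolation of the 13 resampled copies sets the floor
        assert cc > 0.99


class TestAverage:
    def test_copies_with_identity_residuals_average_to_box(self, ref13):
        boxes = np.repeat(ref13.data[None], 4, axis=0)
        stack = SubtomogramStack(boxes, 1.0, new_particle_table(4))
        assert np.allclose(average(stack).data, ref13.data, atol=1e-6)

    def test_zero_kept_particles_errors(self, ref13):
        stack = one_box_stack(ref13.data)
        t = stack.table.copy()
        t["keep_flag"] = False
        with pytest.raises(ValueError):
            average(stack, t)

    def test_wedge_compensation_beats_naive(self, ref13):
        from axontomo.align import _wedge_mask_for
        from axontomo.geometry import euler_to_matrix

        phantom = ref13.data

        def limited(R):
            wm = _wedge_mask_for(phantom.shape, 60.0, R)
            return np.real(np.fft.ifftn(np.fft.fftn(phantom) * wm)).astype(np.float32)

        R0, R1 = np.eye(3), euler_to_matrix(0, 90, 0)
        t = new_particle_table(2)
        t.loc[1, ["phi", "theta", "psi"]] = [0.0, 90.0, 0.0]
        stack = SubtomogramStack(np.stack([limited(R0), limited(R1)]), 1.0, t)

        def corr(v):
            return np.corrcoef(v.ravel(), phantom.ravel())[0, 1]

        naive = corr(average(stack, wedge_compensation=False).data)
        comp = corr(average(stack, wedge_compensation=True).data)
        assert comp > naive


class TestProject:
    def test_single_slice_is_central(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(9, 9, 9)).astype(np.float32), 1.0)
        assert np.allclose(project(v, 1, "z"), v.data[4])

    def test_full_projection_sums_all(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(9, 9, 9)).astype(np.float32), 1.0)
        assert np.allclose(project(v, 9, "z"), v.data.sum(axis=0), atol=1e-5)

    def test_13fold_power_in_cross_section(self, ref13):
        from axontomo.classify import count_pfs

        assert count_pfs(ref13) == 13


class TestFSC:
    def test_identical_volumes_fsc_is_one(self, ref13):
        curve = fsc(ref13, ref13)
        assert np.all(curve["fsc"] > 0.999)
        res, crossed = resolution_at(curve, 0.143)
        assert not crossed  # Nyquist bound flagged

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        a = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.0)
        b = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.0)
        curve = fsc(a, b)
        assert np.all(np.abs(curve["fsc"][3:]) < 0.25)

    def test_band_limited_pair_crosses_at_cutoff(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(48, 48, 48))
        grids = np.meshgrid(*[np.fft.fftfreq(48)] * 3, indexing="ij")
        rr = np.sqrt(sum(g * g for g in grids))
        lp = rr < 0.25  # cutoff 0.25 cycles/nm -> 40 A
        mk = lambda arr: Volume(np.fft.ifftn(np.fft.fftn(arr) * lp).real.astype(np.float32), 1.0)
        a = mk(base + 1.0 * rng.normal(size=base.shape))
        b = mk(base + 1.0 * rng.normal(size=base.shape))
        res, crossed = resolution_at(fsc(a, b), 0.143)
        assert crossed
        assert res == pytest.approx(40.0, abs=4.0)
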