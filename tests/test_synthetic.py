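"""Ground-truth scene generator: lattice geometry, MIP placement, corruption."""

import numpy as np
import pytest

from axontomo import synthetic as syn
from axontomo.io import Volume


def straight_filament(length=100.0, **kw):
    return syn.FilamentSpec(path=np.array([[50.0, 50.0, 30.0],
                                           [50.0, 50.0, 30.0 + length]]), **kw)


class TestLattice:
    def test_one_dimer_layer_has_26_monomers(self):
        spec = syn.LatticeSpec()
        fil = straight_filament(16.0)
        pts, dirs, meta = syn.build_lattice_points(spec, fil)
        assert len(pts) == 26
        angles = np.unique(np.round(meta["angle"], 6))
        assert len(angles) == 13
        assert np.allclose(np.diff(sorted(angles)), 360.0 / 13, atol=1e-9)

    def test_pf_segments_change_angular_count(self):
        spec = syn.LatticeSpec()
        fil = straight_filament(1000.0, pf_segments=[(0, 500, 12), (500, 1000, 13)])
        _, _, meta = syn.build_lattice_points(spec, fil)
        before = meta["pf_index"][meta["arclength"] < 500]
        after = meta["pf_index"][meta["arclength"] > 500]
        assert before.max() == 11 and after.max() == 12

    def test_break_interval_empties_lattice(self):
        spec = syn.LatticeSpec()
        fil = straight_filament(300.0, break_intervals=[(100.0, 150.0)])
        _, _, meta = syn.build_lattice_points(spec, fil)
        s = meta["arclength"]
        assert not np.any((s > 100) & (s < 150))
        ref = syn.build_lattice_points(spec, straight_filament(300.0))[2]["arclength"]
        outside = ref[(ref <= 100) | (ref >= 150)]
        assert len(s) == len(outside)

    def test_thirteen_fold_rotation_maps_lattice_onto_itself(self):
        # rotate monomer centres by one pf spacing about the axis combined
        # with the helical rise: the point set maps onto itself away from ends
        spec = syn.LatticeSpec()
        fil = straight_filament(400.0)
        pts, _, meta = syn.build_lattice_points(spec, fil)
        mid = (meta["arclength"] > 100) & (meta["arclength"] < 300)
        p = pts[mid] - np.array([50.0, 50.0, 0.0])
        a = np.radians(360.0 / 13)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        rotated = p @ R.T + np.array([0.0, 0.0, spec.rise_per_pf])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts - np.array([50.0, 50.0, 0.0])).query(rotated)
        assert np.median(d) < 0.05

    def test_degenerate_path_rejected(self):
        spec = syn.LatticeSpec()
        fil = syn.FilamentSpec(path=np.array([[50, 50, 30], [50, 50, 30.0],
                                              [50, 50, 60.0]], dtype=float))
        with pytest.raises(ValueError, match="degenerate|zero tangent"):
            syn.build_lattice_points(spec, fil)

    def test_13pf_supertwist_must_close(self):
        with pytest.raises(ValueError):
            syn.LatticeSpec(pf_number=13, skew_per_pf=28.5)


class TestMIPPlacement:
    def test_zero_rate_empty(self):
        fil = straight_filament(1000.0, mip_rate=0.0)
        assert syn.place_mips(fil, seed=1) == []

    def test_deterministic(self):
        fil = straight_filament(1000.0, mip_rate=72.0)
        assert syn.place_mips(fil, seed=5) == syn.place_mips(fil, seed=5)

    def test_poisson_mean_at_printed_rate(self):
        # 72/um on a 1-um lumen: the count distribution must be Poisson(72)
        fil = straight_filament(1000.0, mip_rate=72.0)
        counts = [len(syn.place_mips(fil, seed=s)) for s in range(300)]
        se = np.sqrt(72.0 / len(counts))
        assert abs(np.mean(counts) - 72.0) < 3 * se

    def test_minimum_spacing_enforced(self):
        fil = straight_filament(1000.0, mip_rate=72.0)
        pos = np.array(syn.place_mips(fil, seed=2))
        assert np.diff(np.sort(pos)).min() >= 9.0


class TestRenderCorrupt:
    def test_empty_scene_is_zero(self):
        man = syn.GroundTruthManifest([], [], snr=None, tilt_range=90, seed=0)
        vol = syn.render_scene(man, shape=(24, 24, 24))
        assert np.all(vol.data == 0)

    def test_undersampled_voxel_rejected(self):
        fil = straight_filament(100.0)
        man = syn.GroundTruthManifest([fil], [[]], snr=None, tilt_range=90, seed=0)
        with pytest.raises(ValueError, match="voxel"):
            syn.render_scene(man, voxel=3.0)

    def test_rendered_wall_diameter_matches_geometry(self, ref13):
        from axontomo.align import project
        from axontomo.stats import diameter_peak_to_peak

        img = project(ref13, 5, "z")
        d = diameter_peak_to_peak(img[16, :], 1.0)
        assert d == pytest.approx(21.2, abs=1.0)

    def test_actin_axial_repeat_is_6nm(self):
        fil = syn.FilamentSpec(path=np.array([[30.0, 30.0, 10.0], [30.0, 30.0, 240.0]]),
                               kind="actin")
        man = syn.GroundTruthManifest([fil], [[]], snr=None, tilt_range=90, seed=3)
        vol = syn.render_scene(man, shape=(256, 60, 60))
        from axontomo.stats import layer_line_spectrum

        _, spacing = layer_line_spectrum(vol.data[:, 30, :], 1.0, axial_axis=0)
        assert spacing == pytest.approx(6.0, abs=0.3)

    def test_corrupt_identity_when_disabled(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(16, 16, 16)).astype(np.float32), 1.0)
        out = syn.corrupt(v, snr=None, tilt_range=90.0, seed=0)
        assert np.allclose(out.data, v.data)

    def test_wedge_zeroes_missing_region(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(32, 32, 32)).astype(np.float32), 1.0)
        out = syn.corrupt(v, snr=None, tilt_range=60.0, seed=0)
        f = np.abs(np.fft.fftn(out.data))
        mask = syn.missing_wedge_mask(v.data.shape, 60.0)
        assert f[~mask].mean() < 1e-6 * f[mask].mean()

    def test_corrupt_bit_reproducible(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(16, 16, 16)).astype(np.float32), 1.0)
        a = syn.corrupt(v, 0.5, 60.0, seed=9)
        b = syn.corrupt(v, 0.5, 60.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_snr_definition_on_support_mask(self):
        fil = straight_filament(150.0)
        man = syn.GroundTruthManifest([fil], [[]], snr=None, tilt_range=90, seed=0)
        clean = syn.render_scene(man)
        noisy = syn.corrupt(clean, snr=2.0, tilt_range=90.0, seed=4)
        support = clean.data > 0.1 * clean.data.max()
        noise_var = np.var(noisy.data - clean.data)
        assert clean.data[support].var() / noise_var == pytest.approx(2.0, rel=0.05)


class TestManifest:
    def test_json_roundtrip_identity(self, tmp_path):
        fil = straight_filament(200.0, polarity="minus_along_path", mip_rate=30.0,
                                break_intervals=[(50.0, 80.0)], phase_deg=123.0)
        mips = syn.place_mips(fil, seed=8)
        man = syn.GroundTruthManifest([fil], [mips], snr=0.5, tilt_range=60, seed=8)
        p = tmp_path / "man.json"
        man.save(p)
        back = syn.GroundTruthManifest.load(p)
        assert back.snr == man.snr and back.seed == man.seed
        assert np.allclose(back.filaments[0].path, fil.path)
        assert back.filaments[0].polarity == fil.polarity
        assert np.allclose(back.mip_positions[0], mips)

    def test_render_deterministic_given_seed(self):
        fil = straight_filament(120.0, mip_rate=40.0)
        mips = syn.place_mips(fil, seed=3)
        man = syn.GroundTruthManifest([fil], [mips], snr=None, tilt_range=90, seed=3)
        assert np.array_equal(syn.render_scene(man).data, syn.render_scene(man).data)

    def test_mip_off_filament_rejected(self):
        fil = straight_filament(100.0)
        with pytest.raises(ValueError):
            syn.GroundTruthManifest([fil], [[150.0]], snr=1.0, tilt_range=60, seed=0)


class TestMirrorSymmetry:
    def test_polarity_flip_equals_mirror_for_slew(self):
        # negating polarity and reflecting through a plane containing the
        # axis must flip the apparent slew handedness
        from axontomo.classify import slew_sign

        plus = syn.render_reference(13, 33, polarity="plus_along_path")
        minus = syn.render_reference(13, 33, polarity="minus_along_path")
        s_plus, _ = slew_sign(plus)
        s_minus, _ = slew_sign(minus)
        assert {s_plus, s_minus} == {"cw", "ccw"}
        mirrored = Volume(plus.data[:, ::-1, :].copy(), 1.0)
        s_mirror, _ = slew_sign(mirrored)
        assert s_mirror == s_minus
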