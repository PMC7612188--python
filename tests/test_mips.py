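"""Luminal particle detection, cluster cleaning, density statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axontomo import synthetic as syn
from axontomo.io import new_particle_table
from axontomo.mips import (
    average_mips,
    break_end_mip_stats,
    cluster_clean,
    detect_mips,
    mip_density,
)


@pytest.fixture(scope="module")
def planted_mt():
    vol, manifest, model = syn.make_mt_tomogram(
        length=800.0, snr=None, tilt_range=60.0, seed=321, mip_rate=50.0,
        tilt_max_deg=0.0)
    return vol, manifest, model


class TestDetect:
    def test_planted_mips_recovered_noiselessly(self, planted_mt):
        vol, manifest, model = planted_mt
        truth = np.array(manifest.mip_positions[0])
        clean = cluster_clean(detect_mips(vol, [model]), radius=5.0, min_size=2)
        det = clean["arclength"].to_numpy()
        hits = sum(1 for t in truth if np.min(np.abs(det - t)) <= 2.0)
        assert hits >= len(truth) - 1
        assert len(det) <= len(truth) + 1

    def test_zero_mip_mt_detects_nothing(self):
        vol, _, model = syn.make_mt_tomogram(length=400.0, snr=None, seed=99,
                                             mip_rate=0.0, tilt_max_deg=0.0)
        clean = cluster_clean(detect_mips(vol, [model]), radius=5.0, min_size=2)
        assert len(clean) == 0

    def test_candidates_confined_to_lumen(self, planted_mt):
        vol, manifest, model = planted_mt
        cands = detect_mips(vol, [model], lumen_radius=4.0)
        from axontomo.geometry import resample_path

        axis = resample_path(model.points, cands["arclength"].to_numpy())
        d = np.linalg.norm(cands[["x", "y", "z"]].to_numpy() - axis, axis=1)
        assert np.all(d <= 4.0 + 1e-6)

    def test_lumen_radius_must_be_inside_wall(self, planted_mt):
        vol, _, model = planted_mt
        with pytest.raises(ValueError):
            detect_mips(vol, [model], lumen_radius=12.0)


class TestClusterClean:
    def _cands(self, positions, scores):
        t = new_particle_table(len(positions))
        t[["x", "y", "z"]] = np.asarray(positions, dtype=float)
        t["cc_score"] = scores
        return t

    def test_pair_within_radius_keeps_best(self):
        out = cluster_clean(self._cands([[0, 0, 0], [4, 0, 0]], [0.9, 0.7]),
                            radius=5.0, min_size=2)
        assert len(out) == 1 and out["cc_score"].iloc[0] == 0.9

    def test_singleton_discarded(self):
        out = cluster_clean(self._cands([[0, 0, 0]], [0.9]), radius=5.0, min_size=2)
        assert len(out) == 0

    def test_linkage_radius_is_pairwise(self):
        pos = [[0, 0, 0], [6, 0, 0], [3, 5.2, 0]]
        out = cluster_clean(self._cands(pos, [0.9, 0.8, 0.7]), radius=5.0, min_size=2)
        assert len(out) == 0  # three mutual singletons at ~6 nm spacing

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 40, size=(n, 3))
        scores = rng.uniform(0, 1, size=n)
        t = self._cands(pos, scores)
        out = cluster_clean(t, radius=5.0, min_size=2)
        # oracle: all-pairs adjacency, connected components, best score each
        adj = np.linalg.norm(pos[:, None] - pos[None, :], axis=2) <= 5.0
        labels = -np.ones(n, dtype=int)
        cid = 0
        for i in range(n):
            if labels[i] >= 0:
                continue
            frontier = [i]
            labels[i] = cid
            while frontier:
                j = frontier.pop()
                for k in np.nonzero(adj[j])[0]:
                    if labels[k] < 0:
                        labels[k] = cid
                        frontier.append(k)
            cid += 1
        expect = set()
        for c in range(cid):
            members = np.nonzero(labels == c)[0]
            if len(members) >= 2:
                expect.add(members[np.argmax(scores[members])])
        assert len(out) == len(expect)
        if expect:
            assert np.allclose(sorted(out["cc_score"]), sorted(scores[sorted(expect)]))


class TestDensity:
    def test_simple_arithmetic(self):
        t = new_particle_table(36)
        t["filament_id"] = 0
        df, summary = mip_density(t, {0: 500.0})
        assert df["per_um"].iloc[0] == pytest.approx(72.0)

    def test_zero_count(self):
        df, _ = mip_density(new_particle_table(0), {0: 1000.0})
        assert df["per_um"].iloc[0] == 0.0

    def test_density_estimator_unbiased(self):
        # plant Poisson counts analytically; the per-MT estimator must be
        # unbiased over many simulated MTs
        rate = 72.0
        rng = np.random.default_rng(0)
        means = []
        for _ in range(1000):
            fil = syn.FilamentSpec(path=np.array([[50.0, 50, 30], [50, 50, 1030.0]]),
                                   mip_rate=rate)
            means.append(len(syn.place_mips(fil, seed=int(rng.integers(2**31)))))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - rate) < 3 * se


class TestBreakEndStats:
    def _table(self, arcs, fid=0):
        t = new_particle_table(len(arcs))
        t["filament_id"] = fid
        t["arclength"] = arcs
        return t

    def test_observed_vs_expected_arithmetic(self):
        # 69 particles on 1 um; 9 of them inside a 0.1-um window next to a break
        arcs = np.concatenate([np.linspace(0, 480, 60),
                               np.linspace(501, 599, 9),
                               np.linspace(700, 999, 0)])
        t = self._table(arcs)
        out = break_end_mip_stats(t, {0: 1000.0}, breaks={0: [(481.0, 500.0)]})
        row = out["table"].iloc[0]
        assert row.expected == pytest.approx(69.0)
        # right-hand 100-nm window holds the 9 particles: 90/um on that side
        assert row.observed_adjacent == pytest.approx((90.0 + 130.0) / 2.0, rel=0.05)

    def test_zero_length_break_excluded(self):
        t = self._table(np.linspace(0, 900, 50))
        out = break_end_mip_stats(t, {0: 1000.0}, breaks={0: [(300.0, 300.0)]})
        assert out["excluded_zero_length"] == [(0, 300.0, 300.0)]
        assert len(out["table"]) == 0

    def test_null_pvalues_uniform(self):
        # uniform placement with no break effect: the paired test's p-values
        # across replicate cohorts must be uniform on [0, 1]
        from scipy import stats as ss

        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(120):
            tables, lengths, breaks = [], {}, {}
            for fid in range(12):
                L = 1000.0
                n = rng.poisson(40)
                arcs = np.sort(rng.uniform(0, L, n))
                tt = self._table(arcs, fid)
                tables.append(tt)
                lengths[fid] = L
                breaks[fid] = [(450.0, 550.0)]
            import pandas as pd

            t = pd.concat(tables, ignore_index=True)
            t["particle_id"] = np.arange(len(t))
            out = break_end_mip_stats(t, lengths, breaks=breaks)
            pvals.append(out["tests"]["within_break"]["p"])
        assert ss.kstest(pvals, "uniform").pvalue > 0.01


class TestAverageMips:
    def test_ring_phantom_average_has_central_pore(self):
        from axontomo.align import _radial_grids
        from axontomo.extract import SubtomogramStack
        from axontomo.synthetic import _add_blobs, mip_motif_points

        rng = np.random.default_rng(1)
        boxes = []
        for _ in range(120):
            d = np.zeros((15, 15, 15), dtype=np.float32)
            _add_blobs(d, mip_motif_points(rng) + 7.0, 1.0, 1.2)
            d += rng.normal(0, 0.3, size=d.shape).astype(np.float32)
            boxes.append(d)
        t = new_particle_table(120)
        t["filament_id"] = np.arange(120) % 6
        stack = SubtomogramStack(np.asarray(boxes), 1.0, t)
        out = average_mips(stack, rounds=2)
        avg = out["average"].data
        z, y, x = _radial_grids(15, 1.0)
        r = np.sqrt(x * x + y * y + z * z)
        shells = [avg[(r >= a) & (r < a + 1)].mean() for a in range(5)]
        # central pore: the innermost shell is well below the ring maximum
        assert shells[0] < 0.6 * max(shells)
        assert np.argmax(shells) in (2, 3)
        assert out["resolution_A"] is not None

    def test_identical_particles_average_to_particle(self, ref13):
        from axontomo.extract import SubtomogramStack

        small = ref13.data[9:24, 9:24, 9:24].copy()
        boxes = np.repeat(small[None], 60, axis=0)
        t = new_particle_table(60)
        t["filament_id"] = np.arange(60) % 4
        stack = SubtomogramStack(boxes, 1.0, t)
        out = average_mips(stack, rounds=1, max_shift=0.0)
        # identical inputs: the average correlates near-perfectly with one box
        cc = np.corrcoef(out["average"].data.ravel(), small.ravel())[0, 1]
        assert cc > 0.99
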