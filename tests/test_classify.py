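"""MSA, polarity eigenvector scan, MRA, voting, slew and pf counting."""

import numpy as np
import pytest

from axontomo.align import AlignmentLimits, average
from axontomo.classify import (
    ClassResult,
    assign_pf,
    count_pfs,
    find_polarity_eigenvector,
    mra,
    msa,
    polarity_from_slew,
    register_to_references,
    slew_sign,
    vote_polarity,
    _two_means_1d,
)
from axontomo.extract import SubtomogramStack
from axontomo.io import Volume, new_particle_table

from conftest import build_mt_stack, pool_stacks


class TestMSA:
    def test_identical_boxes_have_zero_variance(self, ref13):
        boxes = np.repeat(ref13.data[None], 8, axis=0)
        stack = SubtomogramStack(boxes, 1.0, new_particle_table(8))
        with pytest.warns(UserWarning):  # rank-deficient: 8 particles < 40
            d = msa(stack, n_components=40, wedge_fill=False)
        assert d.rank_deficient
        assert np.all(d.eigenvalues < 1e-6)

    def test_components_orthonormal(self, polarity_cohort):
        stack, _ = polarity_cohort
        d = msa(stack, n_components=10, wedge_fill=False, seed=0)
        G = d.components.reshape(len(d.components), -1)
        assert np.allclose(G @ G.T, np.eye(len(G)), atol=1e-6)

    def test_two_population_stack_separates(self, polarity_cohort):
        stack, truth = polarity_cohort
        d = msa(stack, n_components=40, seed=0)
        lab_true = np.array([0 if truth[f] == "plus_along_path" else 1
                             for f in stack.table["filament_id"]])
        best = 0.0
        for c in range(d.coords.shape[1]):
            km = _two_means_1d(d.coords[:, c], 0)
            best = max(best, max((km == lab_true).mean(), (km != lab_true).mean()))
        assert best >= 0.95


class TestPolarityEigenvector:
    def test_scan_recovers_polarity_split(self, polarity_cohort):
        stack, truth = polarity_cohort
        d = msa(stack, n_components=40, seed=0)
        _, labels, refs = find_polarity_eigenvector(d, stack, seed=0)
        lab_true = np.array([0 if truth[f] == "plus_along_path" else 1
                             for f in stack.table["filament_id"]])
        purity = max((labels == lab_true).mean(), (labels != lab_true).mean())
        assert purity >= 0.95
        signs = {slew_sign(v)[0] for v in refs}
        assert signs == {"cw", "ccw"}

    def test_single_polarity_stack_raises(self):
        stacks = [build_mt_stack(polarity="plus_along_path", snr=1.0,
                                 seed=60 + i, filament_id=i)[0] for i in range(3)]
        from axontomo.align import apply_residuals, register_filaments

        stack = pool_stacks(stacks)
        stack = apply_residuals(stack, register_filaments(stack))
        d = msa(stack, n_components=30, seed=0)
        with pytest.raises(ValueError, match="polarity eigenvector"):
            find_polarity_eigenvector(d, stack, seed=0)


class TestSlew:
    def test_reference_polarities_give_opposite_signs(self, ref13):
        from axontomo import synthetic as syn

        minus = syn.render_reference(13, 33, polarity="minus_along_path")
        assert slew_sign(ref13)[0] == "ccw"
        assert slew_sign(minus)[0] == "cw"
        assert polarity_from_slew("ccw") == "plus_along_path"
        assert polarity_from_slew("cw") == "minus_along_path"

    def test_mirror_flip_reverses_sign_on_images(self, ref13):
        from axontomo.classify import cross_section

        img = cross_section(ref13)
        s, lag = slew_sign(img)
        s_m, lag_m = slew_sign(img[::-1, :])
        assert {s, s_m} == {"cw", "ccw"}
        assert lag_m == pytest.approx(-lag, abs=0.2)

    def test_noise_image_undetermined(self):
        img = np.random.default_rng(0).normal(size=(33, 33))
        assert slew_sign(img)[0] == "undetermined"


class TestCountPfs:
    def test_clean_references(self, ref13, ref12):
        assert count_pfs(ref13) == 13
        assert count_pfs(ref12) == 12

    def test_noise_only_is_nd(self):
        v = Volume(np.random.default_rng(0).normal(size=(33, 33, 33)).astype(np.float32), 1.0)
        assert count_pfs(v) == "ND"


class TestMRA:
    def test_particle_identical_to_reference(self, ref12, ref13):
        stack = SubtomogramStack(ref12.data[None], 1.0, new_particle_table(1))
        res = mra(stack, [ref12, ref13], rounds=1,
                  limits=AlignmentLimits(max_inplane=4))
        assert res.table["class_label"].iloc[0] == 0
        assert res.table["cc_score"].iloc[0] == pytest.approx(1.0, abs=1e-5)

    def test_noiseless_12pf_particles_all_class_12(self, ref12, ref13):
        stack, _, _ = build_mt_stack(length=200.0, snr=None, seed=77, pf_number=12,
                                     tilt_range=90.0)
        refs = register_to_references(stack, [ref12, ref13], wedge_aware=False)
        res = mra(stack, refs, rounds=1, limits=AlignmentLimits())
        assert (res.table["class_label"] == 0).all()


class TestVote:
    def _result(self, labels, ref_plus, ref_minus):
        t = new_particle_table(len(labels))
        t["class_label"] = labels
        t["cc_score"] = 0.9
        return ClassResult(table=t, class_averages=[ref_plus, ref_minus])

    def test_80_percent_majority_assigned(self, ref13):
        from axontomo import synthetic as syn

        minus = syn.render_reference(13, 33, polarity="minus_along_path")
        res = self._result([0] * 8 + [1] * 2, ref13, minus)
        assert vote_polarity(res)[0] == "plus"

    def test_exactly_70_percent_is_unclear(self, ref13):
        from axontomo import synthetic as syn

        minus = syn.render_reference(13, 33, polarity="minus_along_path")
        res = self._result([0] * 7 + [1] * 3, ref13, minus)
        assert vote_polarity(res)[0] == "unclear"


class TestAssignPf:
    def _stack_and_result(self, labels, ref12, ref13):
        labels = np.asarray(labels)
        boxes = np.where(labels[:, None, None, None] == 0,
                         ref12.data[None], ref13.data[None]).astype(np.float32)
        t = new_particle_table(len(labels))
        t["arclength"] = np.arange(len(labels)) * 8.0
        t["class_label"] = labels
        t["cc_score"] = 0.9
        stack = SubtomogramStack(boxes, 1.0, t)
        return stack, ClassResult(table=t, class_averages=[ref12, ref13])

    def test_balanced_runs_give_transition_at_boundary(self, ref12, ref13):
        stack, res = self._stack_and_result([0] * 30 + [1] * 30, ref12, ref13)
        out = assign_pf(res, stack, class_pf={0: 12, 1: 13})
        row = out.iloc[0]
        assert row.assignment == "transition"
        assert row.transition_nm == pytest.approx((29 * 8 + 30 * 8) / 2.0)

    def test_short_patch_is_not_a_transition(self, ref12, ref13):
        stack, res = self._stack_and_result([0] * 15 + [1] * 45, ref12, ref13)
        out = assign_pf(res, stack, class_pf={0: 12, 1: 13})
        assert out.iloc[0].assignment == "13"

    def test_97_percent_auto_assigned(self, ref12, ref13):
        labels = [1] * 58 + [0] * 2
        stack, res = self._stack_and_result(labels, ref12, ref13)
        out = assign_pf(res, stack, class_pf={0: 12, 1: 13})
        assert out.iloc[0].assignment == "13"
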