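"""Segmentation pipeline: masks, clustering stages, edits, volumetry."""

import numpy as np
import pytest
from scipy import stats as sps

from plexus.errors import MaskError, ParameterError, SegmentationError
from plexus.gmm import GMMConfig, _hard_assign, select_component
from plexus.image import LabelMap, VENTRICULAR_SYSTEM_CODES, VolumeImage
from plexus.phantom import PhantomSpec, generate_phantom, true_volume_mm3
from plexus.segment import (
    ManualEdits,
    apply_manual_edits,
    build_initial_mask,
    compute_volume,
    segment_cp,
    stage1_cluster,
    stage2_cluster,
)
from plexus.susan import susan_smooth


def _label_map(shape=(20, 20, 20), blocks=()):
    labels = np.zeros(shape, dtype=np.int16)
    for code, sl in blocks:
        labels[sl] = code
    return LabelMap(labels, code_table=dict(VENTRICULAR_SYSTEM_CODES))


class TestInitialMask:
    def test_union_of_disjoint_structures(self):
        lm = _label_map(blocks=[(4, np.s_[0:5, 0:10, 0:10]),
                                (43, np.s_[10:15, 0:10, 0:10])])
        mask, count = build_initial_mask(lm)
        assert count == 1000 == mask.sum()

    def test_count_equals_sum_of_per_code_counts(self, noisy_phantom):
        _, _, labels, _ = noisy_phantom
        mask, count = build_initial_mask(labels)
        per_code = sum(int((labels.labels == c).sum())
                       for c in VENTRICULAR_SYSTEM_CODES)
        assert count == per_code

    def test_empty_union_raises(self):
        lm = _label_map()
        with pytest.raises(MaskError):
            build_initial_mask(lm)

    def test_missing_code_in_table_raises(self):
        labels = np.zeros((5, 5, 5), dtype=np.int16)
        labels[0, 0, 0] = 4
        lm = LabelMap(labels, code_table={4: "Left-Lateral-Ventricle"})
        with pytest.raises(MaskError):
            build_initial_mask(lm)


class TestStage1:
    def test_high_mask_covers_ground_truth_cp(self, noiseless_phantom):
        """The 2-class split puts every true CP voxel in the bright class
        (the decision boundary sits between the CSF and wall means)."""
        _, image, labels, truth = noiseless_phantom
        initial, _ = build_initial_mask(labels)
        low, high, fit = stage1_cluster(image, initial)
        assert np.all(high[truth])
        assert not (low & high).any()
        assert np.array_equal(low | high, initial)

    def test_tiny_mask_raises_sample_size_guard(self):
        img = VolumeImage(np.random.default_rng(0).normal(size=(5, 5, 5)))
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, :4] = True
        mask[1, 1, :5] = True  # 9 voxels < 10 * k
        with pytest.raises(Exception) as exc:
            stage1_cluster(img, mask)
        assert "observations" in str(exc.value)


class TestStage2:
    def test_three_gaussians_near_bayes_optimal(self):
        """Hard assignments misclassify at most twice the analytic Bayes
        rate for three equally weighted Gaussians (40/70/110, sigma 5)."""
        rng = np.random.default_rng(42)
        means, sigma, n = np.array([40.0, 70.0, 110.0]), 5.0, 300
        values = np.concatenate([rng.normal(m, sigma, n) for m in means])
        origin = np.repeat([0, 1, 2], n)
        grid = np.zeros((30, 30, 1))
        grid[..., 0] = values.reshape(30, 30)
        mask = np.ones_like(grid, bool)
        final, fit = stage2_cluster(grid, mask)
        order = np.argsort(fit.means)
        remap = np.empty(3, int)
        remap[order] = np.arange(3)
        got = remap[fit.hard_assignment()]
        err = np.mean(got != origin)
        # analytic Bayes error under the true generative model
        dens = np.array([sps.norm.pdf(values, m, sigma) for m in means])
        bayes = dens.argmax(axis=0)
        per_class = [
            sps.norm.sf((means[0] + means[1]) / 2, means[0], sigma),
            sps.norm.cdf((means[0] + means[1]) / 2, means[1], sigma)
            + sps.norm.sf((means[1] + means[2]) / 2, means[1], sigma),
            sps.norm.cdf((means[1] + means[2]) / 2, means[2], sigma),
        ]
        analytic_bayes_error = float(np.mean(per_class))
        assert err <= max(2 * analytic_bayes_error, 2 / len(values))
        assert np.mean(got != bayes) <= max(2 * analytic_bayes_error,
                                            2 / len(values))

    def test_final_mask_is_highest_mean_component(self, noiseless_phantom):
        _, image, labels, truth = noiseless_phantom
        initial, _ = build_initial_mask(labels)
        _, high, _ = stage1_cluster(image, initial)
        smoothed = susan_smooth(image, high)
        final, fit = stage2_cluster(smoothed, high)
        hi = select_component(fit.means, fit.variances, "highest")
        assert fit.means[hi] == fit.means.max()
        inter = (final & truth).sum()
        dice = 2 * inter / (final.sum() + truth.sum())
        assert dice >= 0.9

    def test_small_domain_raises(self):
        grid = np.zeros((5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, :3] = True
        with pytest.raises(MaskError):
            stage2_cluster(grid, mask)


class TestManualEdits:
    def test_empty_edit_list_is_identity(self):
        mask = np.random.default_rng(0).random((6, 6, 6)) > 0.5
        out = apply_manual_edits(mask, ManualEdits())
        assert np.array_equal(out, mask)

    def test_add_and_remove_disjoint_sets(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[0, 0, :] = True  # 10 voxels
        mask[1, 1, :] = True  # 10 more
        mask[2, 2, :] = True  # 10 more => 30
        add = [(5, 5, k) for k in range(10)]
        remove = [(0, 0, k) for k in range(4)]
        out = apply_manual_edits(mask, ManualEdits(add=add, remove=remove))
        assert out.sum() == 30 + 10 - 4

    def test_sequential_add_then_remove_leaves_voxel_absent(self):
        mask = np.zeros((4, 4, 4), bool)
        step1 = apply_manual_edits(mask, ManualEdits(add=[(1, 1, 1)]))
        step2 = apply_manual_edits(step1, ManualEdits(remove=[(1, 1, 1)]))
        assert not step2[1, 1, 1]

    def test_same_voxel_in_both_lists_ends_present(self):
        """Within one application removals run first, so 'add' wins."""
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        out = apply_manual_edits(
            mask, ManualEdits(add=[(1, 1, 1)], remove=[(1, 1, 1)])
        )
        assert out[1, 1, 1]

    def test_idempotent(self):
        mask = np.zeros((5, 5, 5), bool)
        edits = ManualEdits(add=[(0, 0, 0), (1, 2, 3)], remove=[(4, 4, 4)])
        once = apply_manual_edits(mask, edits)
        twice = apply_manual_edits(once, edits)
        assert np.array_equal(once, twice)

    def test_out_of_grid_index_raises(self):
        mask = np.zeros((4, 4, 4), bool)
        with pytest.raises(MaskError):
            apply_manual_edits(mask, ManualEdits(add=[(4, 0, 0)]))


class TestVolume:
    @pytest.mark.parametrize(
        "count,voxel,expected",
        [(1000, (1, 1, 1), 1000.0), (0, (1, 1, 1), 0.0),
         (100, (1, 1, 6), 600.0)],
    )
    def test_volume_formula(self, count, voxel, expected):
        mask = np.zeros(2000, bool)
        mask[:count] = True
        assert compute_volume(mask.reshape(10, 10, 20), voxel) == expected

    def test_non_boolean_mask_rejected(self):
        with pytest.raises(ParameterError):
            compute_volume(np.zeros((3, 3, 3)), (1, 1, 1))


class TestPipeline:
    def test_noiseless_volume_within_ten_percent(self, noiseless_phantom):
        spec, image, labels, truth = noiseless_phantom
        res = segment_cp(image, labels)
        tv = true_volume_mm3(truth, spec.voxel_size)
        assert abs(res.cp_volume_mm3 - tv) / tv <= 0.10

    def test_mask_nesting_invariant(self, noisy_segmentation):
        res, _ = noisy_segmentation
        assert np.all(res.initial_mask[res.stage1_high_mask])
        assert np.all(res.stage1_high_mask[res.final_cp_mask])
        assert res.cp_volume_mm3 == res.final_cp_mask.sum() * 1.0

    def test_rerun_is_bit_identical(self, noisy_phantom, noisy_segmentation):
        _, image, labels, _ = noisy_phantom
        first, _ = noisy_segmentation
        second = segment_cp(image, labels)
        assert np.array_equal(first.final_cp_mask, second.final_cp_mask)
        assert first.cp_volume_mm3 == second.cp_volume_mm3

    def test_relabeling_invariance(self, noisy_segmentation):
        """Permuting mixture component order does not change which voxels
        are selected as CP."""
        res, _ = noisy_segmentation
        fit = res.stage2_fit
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            p = np.array(perm)
            means, variances = fit.means[p], fit.variances[p]
            resp = fit.responsibilities[:, p]
            assign = _hard_assign(resp, means)
            hi = select_component(means, variances, "highest")
            domain = res.stage1_high_mask
            permuted_final = np.zeros_like(domain)
            permuted_final[domain] = assign == hi
            assert np.array_equal(permuted_final, res.final_cp_mask)

    def test_volume_monotone_in_blob_radius(self):
        """Estimated volume increases with true volume across blob radii
        (noiseless phantoms; Spearman rho exactly 1)."""
        true_v, est_v = [], []
        for r in (2.0, 2.5, 3.0, 3.5, 4.0):
            spec = PhantomSpec(cp_blob_radius_mm=r, noise_sd=0.0)
            image, labels, truth = generate_phantom(spec)
            res = segment_cp(image, labels)
            true_v.append(true_volume_mm3(truth, spec.voxel_size))
            est_v.append(res.cp_volume_mm3)
        rho = sps.spearmanr(true_v, est_v).statistic
        assert rho == pytest.approx(1.0)

    def test_edits_are_applied_and_nesting_kept(self, noisy_phantom,
                                                noisy_segmentation):
        _, image, labels, _ = noisy_phantom
        base, _ = noisy_segmentation
        inside = tuple(np.argwhere(base.final_cp_mask)[0])
        outside = (0, 0, 0)  # far from the ventricular system
        edits = ManualEdits(add=[outside], remove=[inside])
        res = segment_cp(image, labels, edits=edits)
        assert not res.final_cp_mask[inside]
        assert not res.final_cp_mask[outside]  # nesting clamps outside adds
        assert np.all(res.stage1_high_mask[res.final_cp_mask])

    def test_stage_tagged_error_on_empty_labels(self):
        img = VolumeImage(np.zeros((6, 6, 6)))
        lm = _label_map(shape=(6, 6, 6))
        with pytest.raises(SegmentationError) as exc:
            segment_cp(img, lm)
        assert exc.value.stage == "initial_mask"

    def test_shape_mismatch_rejected(self):
        img = VolumeImage(np.zeros((6, 6, 6)))
        lm = _label_map(shape=(5, 5, 5),
                        blocks=[(4, np.s_[0:2, 0:2, 0:2])])
        with pytest.raises(ParameterError):
            segment_cp(img, lm)
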