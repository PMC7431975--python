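import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from ihmt.metrics import compute_ratio_maps
from ihmt.orientation import head_angle
from ihmt.roi import roi_means
from ihmt.simulate import (
    PhantomSpec,
    TissueTruth,
    add_rician,
    iter_study,
    make_phantom,
    ratios_from_truth,
    roi_voxel_counts,
    signals_from_truth,
    simulate_icc_table,
    simulate_roi_table,
    simulate_study,
    study_truth_table,
)
from ihmt.volumes import Volume3D


class TestPhantom:
    def test_expected_label_set(self, small_spec):
        lab = make_phantom(small_spec)
        assert sorted(lab.counts()) == [0, 1, 2, 3] + list(range(11, 21))

    def test_roi_voxel_counts_match_box_volumes(self, small_spec):
        lab = make_phantom(small_spec)
        counts = lab.counts()
        expected = roi_voxel_counts(small_spec)
        for label, name in small_spec.roi_labels.items():
            assert counts[label] == expected[name]

    def test_overlapping_boxes_rejected(self, small_spec):
        boxes = dict(small_spec.roi_boxes)
        first = next(iter(boxes))
        boxes["clone"] = boxes[first]
        with pytest.raises(ValueError, match="overlap"):
            make_phantom(replace(small_spec, roi_boxes=boxes))


class TestSignalInversion:
    def test_reference_wm_signals_and_round_trip(self):
        sig = signals_from_truth(100, 0.20, 0.26, 0.0, 0.9)
        assert sig == (100, 80, 80, 74, 74, 90)
        # feeding them through the forward ratio formulas recovers the truths
        vals = ratios_from_truth(TissueTruth(100, 0.20, 0.26, 0.0, 0.9))
        assert vals["mtr"] == 0.20
        assert vals["emtr"] == 0.26
        assert vals["ihmtr"] == pytest.approx(0.12, rel=1e-12)
        assert vals["ihmtr_inv"] == pytest.approx(180 * (2 / 74 - 2 / 80), rel=1e-12)

    def test_zero_truths_give_flat_signals(self):
        s0, sp, sm, spm, smp, _ = signals_from_truth(50, 0, 0, 0, 0.5)
        assert sp == sm == spm == smp == s0 == 50

    def test_asymmetry_inversion(self):
        _, sp, sm, *_ = signals_from_truth(100, 0.2, 0.26, 0.04, 0.9)
        assert sp - sm == pytest.approx(4.0)

    def test_nonphysical_truth_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            signals_from_truth(100, 0.2, 1.5, 0.0, 0.9)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, unit_volume):
        out = add_rician(unit_volume, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, unit_volume.data)

    def test_same_seed_same_output(self, unit_volume):
        a = add_rician(unit_volume, 0.5, seed=42)
        b = add_rician(unit_volume, 0.5, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_signal_mean_is_rayleigh(self):
        v = Volume3D(np.zeros((25, 25, 25)), np.eye(4))  # >10^4 voxels
        sigma = 2.0
        out = add_rician(v, sigma, seed=3)
        expected = sigma * math.sqrt(math.pi / 2.0)
        assert out.data.mean() == pytest.approx(expected, rel=0.02)


class TestStudySimulation:
    def test_noise_free_roi_means_match_truth(self, small_spec):
        lab = make_phantom(small_spec)
        truth = study_truth_table(small_spec)
        for scan in iter_study(small_spec):
            maps = compute_ratio_maps(scan.volumes)
            rm = roi_means(maps.ihmtr, lab).set_index("roi")["value"]
            sub = truth[
                (truth.subject == scan.subject)
                & (truth.session == scan.session)
                & (truth.repeat == scan.repeat)
            ].set_index("roi")["ihmtr"]
            for roi in sub.index:
                assert rm[roi] == pytest.approx(sub[roi], abs=1e-10)

    def test_transform_encodes_session_angle(self, small_spec):
        spec = replace(small_spec, angle_sd=4.0)
        for scan in iter_study(spec):
            assert head_angle(scan.transform) == pytest.approx(scan.angle, abs=1e-9)
            assert scan.angle >= 0

    def test_rotate_grid_mode_rotates_labels_consistently(self, small_spec):
        """With the grid rotated, pulling the atlas labels through the
        emitted transform lands back on the scan's own geometry, so ROI
        means still recover the truth exactly in the noise-free case."""
        from ihmt.volumes import Volume3D, resample_labels

        spec = replace(small_spec, rotate_grid=True, angle_mean=12.0, angle_sd=0.0)
        atlas = make_phantom(spec)
        scan = next(iter_study(spec))
        assert scan.angle == pytest.approx(12.0)
        target = Volume3D(np.zeros(spec.grid_shape), atlas.voxel_to_mm)
        native_labels = resample_labels(atlas, scan.transform, target)
        # the rotation visibly moved the labels
        assert (native_labels.labels != atlas.labels).any()
        maps = compute_ratio_maps(scan.volumes)
        rm = roi_means(maps.ihmtr, native_labels).set_index("roi")["value"]
        for roi in spec.roi_names:
            truth = ratios_from_truth(spec.tissue_truths[roi])["ihmtr"]
            assert rm[roi] == pytest.approx(truth, abs=1e-10)

    def test_determinism_bit_identical(self, small_spec):
        a = simulate_study(replace(small_spec, noise_sigma=0.5))
        b = simulate_study(replace(small_spec, noise_sigma=0.5))
        for sa, sb in zip(a.scans, b.scans):
            np.testing.assert_array_equal(sa.volumes.s0.data, sb.volumes.s0.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_adding_subjects_keeps_existing_draws(self, small_spec):
        spec2 = replace(small_spec, noise_sigma=0.3, n_subjects=2)
        spec3 = replace(small_spec, noise_sigma=0.3, n_subjects=3)
        t2, _ = simulate_roi_table(spec2)
        t3, _ = simulate_roi_table(spec3)
        keep = t3[t3.subject.isin(["sub-01", "sub-02"])].reset_index(drop=True)
        pd.testing.assert_frame_equal(t2.reset_index(drop=True), keep)


class TestRoiTableSimulation:
    def test_schema_and_determinism(self):
        spec = PhantomSpec(n_subjects=3, seed=5)
        t1, a1 = simulate_roi_table(spec)
        t2, a2 = simulate_roi_table(spec)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(a1, a2)
        assert set(t1.columns) == {"subject", "session", "repeat", "roi", "metric", "value"}
        assert len(a1) == 3 * spec.n_sessions

    def test_noise_free_table_equals_truth(self):
        spec = PhantomSpec(
            n_subjects=2, noise_sigma=0.0, sd_subject=0.0, sd_scan=0.0,
            angle_slope=0.0, seed=1,
        )
        table, _ = simulate_roi_table(spec)
        wide = table[table.metric == "ihmtr"]
        for roi, grp in wide.groupby("roi"):
            expected = ratios_from_truth(spec.tissue_truths[roi])["ihmtr"]
            np.testing.assert_allclose(grp.value, expected, atol=1e-12)

    def test_empirical_icc_matches_variance_ratio(self):
        # ICC of simulated ROI means should converge to the component ratio
        from ihmt.reliability import anova_components

        spec = PhantomSpec(seed=3, angle_slope=0.0, n_subjects=12)
        sens = 2.0  # d(ihmtr)/d(emtr)
        var_s = (sens * spec.sd_subject) ** 2
        var_w = (sens * spec.sd_scan) ** 2
        vals = []
        resid_vars = []
        for rep in range(50):
            t, _ = simulate_roi_table(replace(spec, seed=300 + rep))
            sub = t[(t.metric == "ihmtr") & (t.roi == "genu_cc")]
            y = sub.pivot_table(
                index="subject", columns=["session", "repeat"], values="value"
            ).to_numpy()
            comps = anova_components(y)
            vals.append(comps[0] / (comps[0] + comps[1] + comps[2]))
            resid_vars.append(comps[1] + comps[2])
        expected = var_s / (var_s + np.mean(resid_vars))
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)


class TestIccTableSimulation:
    def test_shape_and_determinism(self):
        y = simulate_icc_table(12, 4, 0.7, 0.1, 0.2, mu=12, seed=9)
        y2 = simulate_icc_table(12, 4, 0.7, 0.1, 0.2, mu=12, seed=9)
        assert y.shape == (12, 4)
        np.testing.assert_array_equal(y, y2)

    def test_zero_variances_give_constant(self):
        y = simulate_icc_table(5, 4, 0.0, 0.0, 0.0, mu=3.0, seed=0)
        np.testing.assert_allclose(y, 3.0)
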