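import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihmt.roi import (
    cov_between,
    cov_map,
    cov_table,
    cov_within,
    read_roi_table,
    roi_means,
    summarize_table,
)
from ihmt.volumes import LabelVolume, Volume3D


def _labels():
    lab = np.zeros((4, 4, 4), dtype=np.int32)
    lab[0, 0, :2] = 1
    lab[1, 1, 1] = 2
    return LabelVolume(lab, np.eye(4), {1: "a", 2: "b"})


def _table(rows):
    return pd.DataFrame(
        rows, columns=["subject", "session", "repeat", "roi", "metric", "value"]
    )


class TestRoiMeans:
    def test_constant_map(self):
        v = Volume3D(np.full((4, 4, 4), 0.7), np.eye(4))
        out = roi_means(v, _labels()).set_index("roi")["value"]
        assert out["a"] == pytest.approx(0.7) and out["b"] == pytest.approx(0.7)

    def test_map_equal_to_label_value(self):
        lab = _labels()
        v = Volume3D(lab.labels.astype(float), np.eye(4))
        out = roi_means(v, lab).set_index("roi")["value"]
        assert out["a"] == 1.0 and out["b"] == 2.0

    def test_two_voxel_mean(self):
        lab = _labels()
        data = np.zeros((4, 4, 4))
        data[0, 0, 0], data[0, 0, 1] = 0.10, 0.14
        out = roi_means(Volume3D(data, np.eye(4)), lab).set_index("roi")
        assert out.loc["a", "value"] == pytest.approx(0.12)

    def test_nan_voxels_dropped_and_empty_roi_missing(self):
        lab = _labels()
        data = np.full((4, 4, 4), 0.5)
        data[0, 0, 0] = np.nan
        data[1, 1, 1] = np.nan  # whole ROI 'b' masked
        out = roi_means(Volume3D(data, np.eye(4)), lab).set_index("roi")
        assert out.loc["a", "value"] == pytest.approx(0.5)
        assert np.isnan(out.loc["b", "value"])

    def test_grid_mismatch_and_empty_labels(self):
        v = Volume3D(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="grid mismatch"):
            roi_means(Volume3D(np.zeros((5, 4, 4)), np.eye(4)), _labels())
        empty = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), np.eye(4))
        with pytest.raises(ValueError, match="no non-zero labels"):
            roi_means(v, empty)


class TestCov:
    def test_cov_between_hand_value(self):
        assert cov_between([8, 10, 12, 10]) == pytest.approx(1.63299 / 10, abs=1e-5)

    def test_cov_between_edge_cases(self):
        assert cov_between([5.0, 5.0, 5.0]) == 0.0
        assert np.isnan(cov_between([1.0, -1.0]))  # non-positive mean undefined
        with pytest.raises(ValueError):
            cov_between([1.0])

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_cov_between_scale_invariant(self, c):
        base = np.array([8.0, 10.0, 12.0, 10.0])
        assert cov_between(c * base) == pytest.approx(cov_between(base), rel=1e-9)

    def test_cov_within_identical_scans_zero(self):
        rows = [
            (s, ses, rep, "a", "ihmtr", 0.12)
            for s in ("s1", "s2")
            for ses in (1, 2)
            for rep in (1, 2)
        ]
        out = cov_within(_table(rows))
        assert out["cov_within"].iloc[0] == 0.0

    def test_cov_within_averages_subject_covs(self):
        # subject 1 constant (CoV 0), subject 2 has CoV 0.16330
        rows = [("s1", ses, rep, "a", "ihmtr", 10.0) for ses in (1, 2) for rep in (1, 2)]
        vals = iter([8.0, 10.0, 12.0, 10.0])
        rows += [("s2", ses, rep, "a", "ihmtr", next(vals)) for ses in (1, 2) for rep in (1, 2)]
        out = cov_within(_table(rows))
        assert out["cov_within"].iloc[0] == pytest.approx(0.163299 / 2, abs=1e-5)

    def test_subject_with_single_scan_excluded_with_warning(self):
        rows = [("s1", ses, rep, "a", "ihmtr", v)
                for (ses, rep), v in zip([(1, 1), (1, 2), (2, 1), (2, 2)], [8, 10, 12, 10])]
        rows += [("s2", 1, 1, "a", "ihmtr", 11.0)]
        with pytest.warns(UserWarning, match="excluded"):
            out = cov_within(_table(rows))
        # only s1 contributes after the exclusion
        assert out["cov_within"].iloc[0] == pytest.approx(0.163299, abs=1e-5)

    def test_cov_structure_follows_variance_decomposition(self):
        """With scan variance dominating, within- and between-subject CoV
        agree; with subject variance dominating, within < between."""
        from dataclasses import replace

        from ihmt.simulate import PhantomSpec, simulate_roi_table

        def mean_covs(spec):
            within, between = [], []
            for rep in range(20):
                t, _ = simulate_roi_table(replace(spec, seed=400 + rep))
                ct = cov_table(t[t.metric == "ihmtr"])
                within.append(ct["cov_within"].mean())
                between.append(ct["cov_between"].mean())
            return np.mean(within), np.mean(between)

        scan_dominated = PhantomSpec(sd_subject=0.0, sd_scan=2e-3, angle_slope=0.0)
        w, b = mean_covs(scan_dominated)
        assert w == pytest.approx(b, rel=0.15)

        subject_dominated = PhantomSpec(sd_subject=4e-3, sd_scan=2e-4, angle_slope=0.0)
        w, b = mean_covs(subject_dominated)
        assert w < b

    def test_cov_table_between_and_within(self):
        rows = [("s1", ses, rep, "a", "ihmtr", v)
                for (ses, rep), v in zip([(1, 1), (1, 2), (2, 1), (2, 2)], [8, 10, 12, 10])]
        out = cov_table(_table(rows))
        assert out.loc[0, "cov_between"] == pytest.approx(0.163299, abs=1e-5)


class TestCovMap:
    def test_identical_volumes_give_zero_map(self):
        v = Volume3D(np.full((3, 3, 3), 2.0), np.eye(4))
        out = cov_map([v, v, v])
        np.testing.assert_allclose(out.data, 0.0)

    def test_voxelwise_hand_value_and_nan_propagation(self):
        vols = []
        for val in (8.0, 10.0, 12.0, 10.0):
            d = np.full((3, 3, 3), val)
            vols.append(Volume3D(d, np.eye(4)))
        vols[0].data[0, 0, 0] = np.nan
        out = cov_map(vols)
        assert out.data[1, 1, 1] == pytest.approx(0.163299, abs=1e-5)
        assert np.isnan(out.data[0, 0, 0])

    def test_within_grouping(self):
        mk = lambda val: Volume3D(np.full((2, 2, 2), val), np.eye(4))
        out = cov_map([mk(8), mk(12), mk(5), mk(5)], grouping="within",
                      subjects=["s1", "s1", "s2", "s2"])
        # s1 CoV = sd(8,12)/10 = 0.28284; s2 CoV = 0 -> mean 0.14142
        assert out.data[0, 0, 0] == pytest.approx(0.141421, abs=1e-5)

    def test_fewer_than_two_volumes_rejected(self):
        v = Volume3D(np.zeros((2, 2, 2)), np.eye(4))
        with pytest.raises(ValueError, match="at least 2"):
            cov_map([v])


class TestSummarizeTable:
    def test_mean_and_scan_occasion_sd(self):
        # two subjects, four scan occasions; value = subject base + occasion offset
        offs = {(1, 1): 0.0, (1, 2): 0.01, (2, 1): -0.01, (2, 2): 0.0}
        rows = []
        for s, base in (("s1", 0.10), ("s2", 0.14)):
            for (ses, rep), o in offs.items():
                rows.append((s, ses, rep, "a", "ihmtr", base + o))
        out = summarize_table(_table(rows), percent=True).set_index("roi")
        assert out.loc["a", "mean"] == pytest.approx(12.0)
        # occasion means are 0.12 + offset; their sample SD on the percent scale
        expected_sd = 100 * pd.Series([0.12, 0.13, 0.11, 0.12]).std(ddof=1)
        assert out.loc["a", "sd"] == pytest.approx(expected_sd, rel=1e-9)

    def test_roundtrip_via_read(self, tmp_path):
        rows = [("s1", 1, 1, "a", "ihmtr", 0.1), ("s1", 1, 2, "a", "ihmtr", 0.2)]
        p = tmp_path / "roi.csv"
        _table(rows).to_csv(p, index=False)
        back = read_roi_table(p)
        assert len(back) == 2

    def test_read_rejects_missing_columns_and_duplicates(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"subject": ["s1"], "value": [1.0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="lacks columns"):
            read_roi_table(p)
        rows = [("s1", 1, 1, "a", "ihmtr", 0.1)] * 2
        _table(rows).to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_roi_table(p)
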