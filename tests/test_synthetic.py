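"""Synthetic cohort generator: planted structure, determinism, outliers."""

import numpy as np
import pytest

from jackfc import (
    SyntheticSpec,
    build_target_covariance,
    correlation_matrix,
    disjoint_planted_edges,
    make_cohort,
    masked_edge_series,
    nearest_psd,
    simulate_subject,
)
from jackfc.timeseries import RoiTimeSeries


class TestTargetCovariance:
    def test_no_edges_gives_identity(self):
        spec = SyntheticSpec(n_rois=5, n_timepoints=20)
        np.testing.assert_array_equal(build_target_covariance(spec), np.eye(5))

    def test_single_edge_direct_construction(self):
        spec = SyntheticSpec(n_rois=3, n_timepoints=20, planted_edges=[(0, 1, 0.8)])
        C = build_target_covariance(spec)
        expected = np.eye(3)
        expected[0, 1] = expected[1, 0] = 0.8
        np.testing.assert_array_equal(C, expected)

    def test_non_psd_triangle_rejected(self):
        # brute-force eigendecomposition oracle: this triangle is indefinite
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]])
        assert np.linalg.eigvalsh(bad)[0] < 0
        spec = SyntheticSpec(
            n_rois=3,
            n_timepoints=20,
            planted_edges=[(0, 1, 0.9), (1, 2, 0.9), (0, 2, -0.9)],
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            build_target_covariance(spec)
        repaired = build_target_covariance(spec, repair=True)
        assert np.linalg.eigvalsh(repaired)[0] >= -1e-10
        np.testing.assert_allclose(np.diag(repaired), 1.0)

    def test_nearest_psd_fixes_hub(self):
        hub = np.eye(4)
        hub[0, 1:] = hub[1:, 0] = 0.8  # 1 - 0.8*sqrt(3) < 0
        out = nearest_psd(hub)
        assert np.linalg.eigvalsh(out)[0] >= -1e-10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"planted_edges": [(0, 0, 0.5)]},
            {"planted_edges": [(0, 9, 0.5)]},
            {"planted_edges": [(0, 1, 1.0)]},
            {"outliers": [(50, [0], 5.0)]},
            {"outliers": [(0, [9], 5.0)]},
            {"noise_sd": 0.0},
            {"n_timepoints": 3},
            {"ar_coeff": 1.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = {"n_rois": 4, "n_timepoints": 20}
        base.update(kwargs)
        with pytest.raises(ValueError):
            SyntheticSpec(**base)


class TestSimulateSubject:
    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_rois=4, n_timepoints=30, master_seed=9)
        a = simulate_subject(spec, 0)
        b = simulate_subject(spec, 0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_subjects_differ_and_are_stable_under_cohort_growth(self):
        small = SyntheticSpec(n_rois=4, n_timepoints=30, master_seed=9, n_subjects=2)
        big = SyntheticSpec(n_rois=4, n_timepoints=30, master_seed=9, n_subjects=5)
        cohort_small = make_cohort(small)
        cohort_big = make_cohort(big)
        for a, b in zip(cohort_small, cohort_big):
            np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(cohort_big[0].data, cohort_big[1].data)

    def test_planted_correlation_within_sampling_error(self):
        # Fisher-z SE is 1/sqrt(T-3) ~ 0.059 at T=294; +-0.1 on r is > 1.6 SE
        spec = SyntheticSpec(
            n_rois=4, n_timepoints=294, planted_edges=[(0, 1, 0.8)], master_seed=3
        )
        ts = simulate_subject(spec, 0)
        r = np.corrcoef(ts.data[:, 0], ts.data[:, 1])[0, 1]
        assert abs(r - 0.8) < 0.1

    def test_shared_outlier_dominates_correlation(self):
        spec = SyntheticSpec(
            n_rois=4,
            n_timepoints=100,
            outliers=[(10, [0, 1], 50.0)],
            master_seed=5,
        )
        ts = simulate_subject(spec, 0)
        r = np.corrcoef(ts.data[:, 0], ts.data[:, 1])[0, 1]
        assert r > 0.9

    def test_noise_sd_scales_signal(self):
        base = SyntheticSpec(n_rois=3, n_timepoints=50, master_seed=2)
        loud = SyntheticSpec(n_rois=3, n_timepoints=50, master_seed=2, noise_sd=3.0)
        np.testing.assert_allclose(
            3.0 * simulate_subject(base, 0).data, simulate_subject(loud, 0).data
        )

    def test_ar_coefficient_induces_autocorrelation(self):
        spec = SyntheticSpec(n_rois=2, n_timepoints=500, master_seed=4, ar_coeff=0.8)
        x = simulate_subject(spec, 0).data[:, 0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 > 0.6


class TestCohort:
    def test_empty_cohort(self):
        spec = SyntheticSpec(n_rois=4, n_timepoints=20, n_subjects=0)
        assert make_cohort(spec) == []

    def test_cohort_labels_shared_data_distinct(self):
        spec = SyntheticSpec(n_rois=4, n_timepoints=20, n_subjects=5, master_seed=1)
        cohort = make_cohort(spec)
        assert len(cohort) == 5
        assert all(ts.roi_labels == cohort[0].roi_labels for ts in cohort)
        for a, b in zip(cohort, cohort[1:]):
            assert not np.array_equal(a.data, b.data)

    def test_cohort_mean_recovers_planted_value(self):
        spec = SyntheticSpec(
            n_rois=4,
            n_timepoints=294,
            planted_edges=[(0, 1, 0.5)],
            n_subjects=20,
            master_seed=6,
        )
        rs = [
            np.corrcoef(ts.data[:, 0], ts.data[:, 1])[0, 1] for ts in make_cohort(spec)
        ]
        assert abs(np.mean(rs) - 0.5) < 0.05

    def test_disjoint_planted_edges_always_positive_definite(self):
        edges = disjoint_planted_edges(68, 30, 0.6)
        assert len({k for i, j, _ in edges for k in (i, j)}) == 60
        spec = SyntheticSpec(n_rois=68, n_timepoints=20, planted_edges=edges)
        C = build_target_covariance(spec)
        assert np.linalg.eigvalsh(C)[0] > 0


class TestSerialization:
    def test_tsv_round_trip_exact(self, tmp_path):
        spec = SyntheticSpec(n_rois=4, n_timepoints=20, master_seed=8)
        ts = simulate_subject(spec, 0)
        path = tmp_path / "sub.tsv"
        ts.to_tsv(path)
        back = RoiTimeSeries.from_tsv(path)
        np.testing.assert_array_equal(ts.data, back.data)
        assert back.roi_labels == ts.roi_labels

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = SyntheticSpec(
            n_rois=4,
            n_timepoints=20,
            planted_edges=[(0, 1, 0.5)],
            outliers=[(3, [0, 2], 10.0)],
            master_seed=8,
            n_subjects=2,
        )
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = SyntheticSpec.from_yaml(path)
        assert back.to_dict() == spec.to_dict()
        np.testing.assert_array_equal(
            simulate_subject(back, 0).data, simulate_subject(spec, 0).data
        )

    def test_malformed_tsv_reports_context(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("lh_a\tlh_b\n1.0\t2.0\n3.0\t\n4.0\t5.0\n5.0\t6.0\n")
        with pytest.raises(ValueError, match="lh_b"):
            RoiTimeSeries.from_tsv(path)


class TestMaskedEdgeFixture:
    def test_calibration_deterministic(self):
        a = masked_edge_series(seed=3)
        b = masked_edge_series(seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_masked_pair_not_statically_significant(self):
        ts = masked_edge_series(n_rois=6, n_timepoints=294, seed=3)
        res = correlation_matrix(ts)
        m = 15
        assert res.p[2, 3] * m > 0.05  # masked edge just misses Bonferroni
        assert res.p[0, 1] * m < 0.01  # strong edge is comfortable

    def test_theta_too_strict_rejected(self):
        with pytest.raises(RuntimeError, match="masked edge"):
            masked_edge_series(n_timepoints=60, theta=0.95)
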