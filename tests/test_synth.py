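"""Ground-truth construction and the synthetic BOLD generator."""

import numpy as np
import pytest

from fcreliab import (
    SyntheticSpec,
    build_ground_truth,
    simulate_dataset,
    simulate_edge_table,
    simulate_run,
)


def spec12(**kw):
    base = dict(n_subjects=2, n_sessions=2, n_parcels=12, n_networks=3,
                frames_per_run={"rest": 100}, runs_per_state={"rest": 1}, seed=3)
    base.update(kw)
    return SyntheticSpec(**base)


class TestBuildGroundTruth:
    def test_equal_within_between_gives_uniform_matrix(self):
        gt = build_ground_truth(spec12(within_network_r=0.3, between_network_r=0.3))
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(gt.base_covariance[off], 0.3)

    def test_zero_subject_sd_copies_base(self):
        gt = build_ground_truth(spec12(subject_edge_sd=0.0))
        for cov in gt.subject_covariances:
            assert np.array_equal(cov, gt.base_covariance)

    def test_subject_covariances_positive_definite_unit_diagonal(self):
        gt = build_ground_truth(spec12(subject_edge_sd=0.2))
        for cov in gt.subject_covariances:
            assert np.linalg.eigvalsh(cov).min() > 0
            assert np.allclose(np.diag(cov), 1.0)
            assert np.allclose(cov, cov.T)

    def test_nonpositive_definite_target_rejected_with_eigenvalue(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            build_ground_truth(spec12(within_network_r=0.1, between_network_r=-0.4))

    def test_partition_has_expected_groups(self):
        gt = build_ground_truth(spec12())
        assert np.bincount(gt.partition)[1:].tolist() == [4, 4, 4]

    def test_planted_partition_maximizes_modularity_brute_force(self):
        """On the noiseless 12-parcel correlation matrix, the planted 3-block
        partition attains the global maximum of weighted modularity over all
        3-colorings of the parcels."""
        gt = build_ground_truth(spec12(within_network_r=0.5, between_network_r=0.05))
        A = gt.base_covariance.copy()
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        two_m = A.sum()
        B = A - np.outer(k, k) / two_m

        def modularity(labels):
            same = labels[:, None] == labels[None, :]
            return (B * same).sum() / two_m

        planted_q = modularity(gt.partition)
        # enumerate all 3^12 label vectors in vectorized batches
        n = 12
        best = -np.inf
        powers = 3 ** np.arange(n)
        for start in range(0, 3**n, 3**9):
            idx = np.arange(start, min(start + 3**9, 3**n))
            labels = (idx[:, None] // powers[None, :]) % 3
            same = labels[:, :, None] == labels[:, None, :]
            q = (same * B).sum(axis=(1, 2)) / two_m
            best = max(best, q.max())
        assert planted_q == pytest.approx(best, abs=1e-12)


class TestSimulateRun:
    def test_determinism_bit_identical(self):
        spec = spec12()
        gt = build_ground_truth(spec)
        b1, e1, m1 = simulate_run(gt, 1, 1, "rest", spec, seed=9)
        b2, e2, m2 = simulate_run(gt, 1, 1, "rest", spec, seed=9)
        assert np.array_equal(b1.data, b2.data)
        assert np.array_equal(m1.fd, m2.fd)
        assert e1.equals(e2)

    def test_long_run_correlation_converges_to_subject_covariance(self):
        spec = spec12(frames_per_run={"rest": 50000}, ar1_coef=0.0,
                      motion_spike_prob=0.0)
        gt = build_ground_truth(spec)
        bold, _, _ = simulate_run(gt, 1, 1, "rest", spec, seed=5)
        r = np.corrcoef(bold.data, rowvar=False)
        target = gt.subject_covariances[0]
        off = ~np.eye(12, dtype=bool)
        assert np.max(np.abs(r[off] - target[off])) < 0.02

    def test_sample_tmean_matches_planted_profile(self):
        means = np.full(12, 800.0)
        spec = spec12(frames_per_run={"rest": 5000}, parcel_mean_profile=means,
                      parcel_sd_profile=np.full(12, 10.0))
        gt = build_ground_truth(spec)
        bold, _, _ = simulate_run(gt, 1, 1, "rest", spec, seed=2)
        se = 10.0 / np.sqrt(5000)
        # AR(1) autocorrelation inflates the SE of the mean by
        # sqrt((1+phi)/(1-phi))
        se *= np.sqrt((1 + spec.ar1_coef) / (1 - spec.ar1_coef))
        assert abs(bold.data[:, 0].mean() - 800.0) < 3 * se * 2

    def test_correlation_error_shrinks_with_run_length(self):
        errors = []
        for frames in (500, 5000, 50000):
            spec = spec12(frames_per_run={"rest": frames}, ar1_coef=0.0)
            gt = build_ground_truth(spec)
            bold, _, _ = simulate_run(gt, 1, 1, "rest", spec, seed=7)
            r = np.corrcoef(bold.data, rowvar=False)
            off = ~np.eye(12, dtype=bool)
            errors.append(np.mean(np.abs(r[off] - gt.subject_covariances[0][off])))
        assert errors[0] > errors[1] > errors[2]

    def test_evoked_component_confined_to_engaged_parcels(self):
        common = dict(n_subjects=1, n_sessions=1, n_parcels=12, n_networks=3,
                      frames_per_run={"rest": 100, "motor": 112},
                      runs_per_state={"rest": 1, "motor": 1}, seed=4)
        spec_on = SyntheticSpec(**common)
        spec_off = SyntheticSpec(**common)
        for cond in spec_off.task_designs["motor"].amplitudes:
            spec_off.task_designs["motor"].amplitudes[cond][:] = 0.0
        gt_on = build_ground_truth(spec_on)
        gt_off = build_ground_truth(spec_off)
        b_on, _, _ = simulate_run(gt_on, 1, 1, "motor", spec_on, seed=8)
        b_off, _, _ = simulate_run(gt_off, 1, 1, "motor", spec_off, seed=8)
        engaged = gt_on.engaged_parcels["motor"] - 1
        others = np.setdiff1d(np.arange(12), engaged)
        assert np.array_equal(b_on.data[:, others], b_off.data[:, others])
        assert np.max(np.abs(b_on.data[:, engaged] - b_off.data[:, engaged])) > 0

    def test_unknown_state_rejected(self):
        spec = spec12()
        gt = build_ground_truth(spec)
        with pytest.raises(ValueError, match="unknown state"):
            simulate_run(gt, 1, 1, "naptime", spec)

    def test_fd_recoverable_from_motion_parameters(self):
        from fcreliab import compute_fd

        spec = spec12(motion_spike_prob=0.2)
        gt = build_ground_truth(spec)
        _, _, motion = simulate_run(gt, 2, 1, "rest", spec, seed=6)
        assert np.allclose(compute_fd(motion), motion.fd, atol=1e-9)


class TestSimulateDataset:
    def test_run_count_matches_design(self, tmp_path):
        spec = SyntheticSpec(n_subjects=2, n_sessions=3, n_parcels=12, n_networks=3,
                             frames_per_run={"rest": 60, "motor": 112},
                             runs_per_state={"rest": 1, "motor": 1}, seed=1)
        manifest = simulate_dataset(spec, tmp_path / "ds")
        assert len(manifest["runs"]) == 2 * 3 * 2

    def test_seed_changes_output_bytes(self, tmp_path):
        kw = dict(n_subjects=1, n_sessions=1, n_parcels=12, n_networks=3,
                  frames_per_run={"rest": 60}, runs_per_state={"rest": 1})
        m1 = simulate_dataset(SyntheticSpec(seed=1, **kw), tmp_path / "a")
        m2 = simulate_dataset(SyntheticSpec(seed=2, **kw), tmp_path / "b")
        f1 = (tmp_path / "a" / m1["runs"][0]["bold"]).read_bytes()
        f2 = (tmp_path / "b" / m2["runs"][0]["bold"]).read_bytes()
        assert f1 != f2

    def test_manifest_echoes_variance_components(self, tmp_path):
        spec = SyntheticSpec(n_subjects=1, n_sessions=1, n_parcels=12, n_networks=3,
                             frames_per_run={"rest": 60}, runs_per_state={"rest": 1},
                             subject_edge_sd=0.07, seed=1)
        manifest = simulate_dataset(spec, tmp_path / "ds")
        assert manifest["variance_components"]["sigma_lambda2"] == pytest.approx(0.07**2)

    def test_existing_manifest_requires_overwrite(self, tmp_path):
        spec = SyntheticSpec(n_subjects=1, n_sessions=1, n_parcels=12, n_networks=3,
                             frames_per_run={"rest": 60}, runs_per_state={"rest": 1})
        simulate_dataset(spec, tmp_path / "ds")
        with pytest.raises(FileExistsError):
            simulate_dataset(spec, tmp_path / "ds")
        simulate_dataset(spec, tmp_path / "ds", overwrite=True)


class TestEdgeTable:
    def test_between_total_variance_ratio_recovered(self):
        """Empirical between/total variance ratio tracks the planted ratio."""
        rho = 0.6
        table = simulate_edge_table(rho, n_subjects=20, n_edges=2000, seed=12)
        subj_means = table.mean(axis=2)  # n_edges x n_subjects
        within = table.var(axis=2, ddof=0).mean()  # estimates sigma_eps^2 / 2
        between = subj_means.var(axis=1, ddof=1).mean() - within  # sigma_lambda^2
        ratio = between / (between + 2 * within)
        assert ratio == pytest.approx(rho, abs=0.05)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            simulate_edge_table(1.5, 5, 10, 0)
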