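"""Censoring, framewise displacement, temporal cleaning, parcellation."""

import numpy as np
import pytest

from fcreliab import (
    censor_frames,
    clean_timeseries,
    compute_fd,
    concat_mean_centered,
    parcellate,
    pearson_connectome,
    volume_match,
)
from fcreliab.datatypes import MotionTrace, Parcellation

from conftest import make_run


class TestComputeFD:
    def test_zero_motion_gives_zero_fd(self):
        m = MotionTrace(np.zeros((10, 3)), np.zeros((10, 3)))
        assert np.array_equal(compute_fd(m), np.zeros(10))

    def test_single_translation_step(self):
        trans = np.zeros((8, 3))
        trans[4:, 0] = 0.2  # step between frames 3 and 4
        fd = compute_fd(MotionTrace(trans, np.zeros((8, 3))))
        expected = np.zeros(8)
        expected[4] = 0.2
        assert np.allclose(fd, expected)

    def test_rotation_arc_length_at_head_radius(self):
        rot = np.zeros((5, 3))
        rot[2:, 1] = 0.01
        fd = compute_fd(MotionTrace(np.zeros((5, 3)), rot), head_radius=50.0)
        assert fd[2] == pytest.approx(0.01 * 50.0)
        assert fd[[0, 1, 3, 4]].sum() == 0

    def test_nonfinite_motion_rejected(self):
        trans = np.zeros((4, 3))
        trans[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_fd(MotionTrace(trans, np.zeros((4, 3))))


class TestCensorFrames:
    def test_threshold_masks_exactly_where_exceeded(self, rng):
        run = make_run(rng.normal(size=(3, 4)))
        out = censor_frames(run, np.array([0.0, 0.3, 0.15]), threshold=0.20)
        assert out.censor_mask.tolist() == [True, False, True]
        assert np.array_equal(out.data, run.data)  # data untouched

    def test_infinite_threshold_retains_all(self, rng):
        run = make_run(rng.normal(size=(5, 2)))
        out = censor_frames(run, rng.uniform(0, 10, 5), threshold=np.inf)
        assert out.censor_mask.all()

    def test_retained_count_matches_independent_recount(self, rng):
        fd = np.abs(rng.normal(0.05, 0.02, 1000))
        spikes = rng.random(1000) < 0.1
        fd[spikes] += 0.5
        run = make_run(rng.normal(size=(1000, 3)))
        out = censor_frames(run, fd, threshold=0.20)
        assert out.n_retained == 1000 - int((fd > 0.20).sum())

    def test_censoring_is_idempotent(self, rng):
        fd = rng.uniform(0, 0.5, 50)
        run = make_run(rng.normal(size=(50, 2)))
        once = censor_frames(run, fd)
        twice = censor_frames(once, fd)
        assert np.array_equal(once.censor_mask, twice.censor_mask)


class TestCleanTimeseries:
    def test_constant_series_removed(self):
        run = make_run(np.full((100, 3), 7.0))
        out = clean_timeseries(run, band=None)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_linear_ramp_removed(self):
        t = np.arange(120, dtype=float)
        run = make_run(np.column_stack([3 * t + 2, -t]))
        out = clean_timeseries(run, band=None)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_bandpass_power_via_fft_oracle(self):
        # 0.05 Hz is in the 0.01-0.08 Hz band, 0.2 Hz is well above it
        tr = 1.0
        t = np.arange(2000) * tr
        sig = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.2 * t)
        run = make_run(sig[:, None], tr=tr)
        out = clean_timeseries(run, band=(0.01, 0.08))
        freqs = np.fft.rfftfreq(t.size, tr)
        pin = np.abs(np.fft.rfft(sig)) ** 2
        pout = np.abs(np.fft.rfft(out.data[:, 0])) ** 2
        i_low = np.argmin(np.abs(freqs - 0.05))
        i_high = np.argmin(np.abs(freqs - 0.2))
        assert pout[i_high] / pin[i_high] < 0.01
        assert pout[i_low] / pin[i_low] > 0.90

    def test_projection_idempotent_without_bandpass(self, rng):
        run = make_run(rng.normal(size=(80, 4)))
        conf = rng.normal(size=(80, 2))
        once = clean_timeseries(run, confounds=conf, band=None)
        twice = clean_timeseries(once, confounds=conf, band=None)
        assert np.max(np.abs(once.data - twice.data)) < 1e-10

    def test_rank_deficient_confounds_warn_and_drop(self, rng):
        run = make_run(rng.normal(size=(60, 2)))
        c = rng.normal(size=(60, 1))
        conf = np.column_stack([c, 2 * c])  # dependent pair
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            out = clean_timeseries(run, confounds=conf, band=None)
        assert np.isfinite(out.data).all()

    def test_retained_mean_is_zero(self, rng):
        run = make_run(rng.normal(5.0, 1.0, size=(300, 3)),
                       mask=rng.random(300) > 0.1, tr=2.0)
        out = clean_timeseries(run, band=(0.01, 0.08))
        assert np.max(np.abs(out.retained().mean(axis=0))) < 1e-10


class TestParcellate:
    def test_identical_units_average_to_themselves(self, rng):
        x = rng.normal(size=(20, 1))
        run = make_run(np.hstack([x, x]))
        parc = Parcellation(np.array([1, 1]))
        out = parcellate(run, parc)
        assert np.allclose(out.data[:, 0], x[:, 0])

    def test_opposite_units_cancel(self, rng):
        x = rng.normal(size=(20, 1))
        run = make_run(np.hstack([x, -x]))
        out = parcellate(run, Parcellation(np.array([1, 1])))
        assert np.allclose(out.data, 0)

    def test_matches_bruteforce_per_frame_means(self, rng):
        data = rng.normal(size=(15, 6))
        labels = np.array([1, 2, 2, 3, 1, 3])
        out = parcellate(make_run(data), Parcellation(labels))
        for t in range(15):
            for p in (1, 2, 3):
                members = [u for u in range(6) if labels[u] == p]
                expected = sum(data[t, u] for u in members) / len(members)
                assert out.data[t, p - 1] == pytest.approx(expected, abs=1e-12)

    def test_unit_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="units"):
            parcellate(make_run(rng.normal(size=(5, 4))), Parcellation(np.array([1, 2])))


def _run_with_retained(n_frames, n_retained, rng, **kw):
    mask = np.zeros(n_frames, dtype=bool)
    mask[:n_retained] = True
    return make_run(rng.normal(size=(n_frames, 3)), mask=mask, **kw)


class TestVolumeMatch:
    def test_target_is_minimum_of_reference_state(self, rng):
        runs = {
            "motor": {(s, 1): [_run_with_retained(500, n, rng, state="motor")]
                      for s, n in zip("abc", (400, 380, 420))},
            "rest": {(s, 1): [_run_with_retained(900, 900, rng)] for s in "abc"},
        }
        target, out = volume_match(runs, "motor")
        assert target == 380
        for state in out:
            for key in out[state]:
                assert sum(r.n_retained for r in out[state][key]) == 380

    def test_equal_lengths_noop(self, rng):
        runs = {"rest": {("a", 1): [_run_with_retained(100, 100, rng)],
                         ("a", 2): [_run_with_retained(100, 100, rng)]}}
        target, out = volume_match(runs, "rest")
        assert target == 100
        assert all(r.censor_mask.all() for v in out["rest"].values() for r in v)

    def test_randomized_counts_against_recount_oracle(self, rng):
        # motor (the reference) is the shortest state by design
        states = {"rest": (150, 300), "motor": (80, 140), "language": (150, 300)}
        runs = {
            st: {(s, ses): [_run_with_retained(300, int(rng.integers(lo, hi)), rng, state=st)
                            for _ in range(2)]
                 for s in "ab" for ses in (1, 2)}
            for st, (lo, hi) in states.items()
        }
        oracle = min(sum(r.n_retained for r in v) for v in runs["motor"].values())
        target, out = volume_match(runs, "motor")
        assert target == oracle
        lengths = {sum(r.n_retained for r in v) for st in out for v in out[st].values()}
        assert lengths == {oracle}

    def test_earliest_frames_kept(self, rng):
        run = _run_with_retained(100, 100, rng, state="motor")
        short = _run_with_retained(100, 60, rng, state="motor")
        runs = {"motor": {("a", 1): [run], ("b", 1): [short]}}
        _, out = volume_match(runs, "motor")
        kept = out["motor"][("a", 1)][0].censor_mask
        assert kept[:60].all() and not kept[60:].any()

    def test_floor_violation_rejected(self, rng):
        runs = {"motor": {("a", 1): [_run_with_retained(60, 10, rng, state="motor")]}}
        with pytest.raises(ValueError, match="floor"):
            volume_match(runs, "motor", floor=50)


class TestConcatMeanCentered:
    def test_single_run_centered(self, rng):
        out = concat_mean_centered([make_run(rng.normal(3.0, 1.0, size=(50, 4)))])
        assert np.max(np.abs(out.mean(axis=0))) < 1e-12

    def test_each_segment_centered(self, rng):
        a = make_run(rng.normal(5, 1, size=(30, 2)))
        b = make_run(rng.normal(-5, 1, size=(20, 2)))
        out = concat_mean_centered([a, b])
        assert np.max(np.abs(out[:30].mean(axis=0))) < 1e-12
        assert np.max(np.abs(out[30:].mean(axis=0))) < 1e-12

    def test_connectome_invariant_to_segment_order(self, rng):
        runs = [make_run(rng.normal(size=(40, 5))) for _ in range(3)]
        c1 = pearson_connectome(concat_mean_centered(runs))
        c2 = pearson_connectome(concat_mean_centered(runs[::-1]))
        assert np.allclose(c1.matrix, c2.matrix, atol=1e-12)

    def test_unit_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="unit"):
            concat_mean_centered([make_run(rng.normal(size=(10, 3))),
                                  make_run(rng.normal(size=(10, 4)))])
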