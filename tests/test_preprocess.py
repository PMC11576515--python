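import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from eegoverlap import (
    EventTable,
    Recording,
    baseline_correct,
    build_adjacency,
    epoch_events,
    reject_epochs,
    resample,
)


def make_recording(data, srate=500.0):
    labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(np.asarray(data, dtype=float), srate, labels)


def make_events(stim, resp=None, srate=500.0):
    frame = pd.DataFrame(
        {
            "participant_id": "p",
            "stimulus_sample": stim,
            "response_sample": resp if resp is not None else np.nan,
        }
    )
    return EventTable(frame, srate)


class TestEpochEvents:
    def test_windowing_identity(self, rng):
        rec = make_recording(rng.standard_normal((2, 3000)))
        ev = make_events([1000])
        ep = epoch_events(rec, ev, "stimulus", (0.0, 0.5))
        assert ep.n_times == 250
        np.testing.assert_array_equal(ep.data[0], rec.data[:, 1000:1250])

    def test_standard_stimulus_window_geometry(self, rng):
        # 4.4 s window [-0.2, 4.2) at 500 Hz: 2200 samples, lock at index 100
        rec = make_recording(rng.standard_normal((1, 5000)))
        ep = epoch_events(rec, make_events([500]), "stimulus", (-0.2, 4.2))
        assert ep.n_times == 2200
        assert np.argmin(np.abs(ep.times)) == 100
        assert ep.times[100] == 0.0

    def test_mask_count_matches_bruteforce(self, rng):
        rec = make_recording(rng.standard_normal((2, 4000)))
        rt = 0.8
        ev = make_events([1000], [1000 + int(rt * 500)])
        ep = epoch_events(rec, ev, "stimulus", (0.0, 4.2), mask_outside_trial=True)
        expected = int(np.sum(ep.times > rt))
        assert ep.mask[0, 0].sum() == expected
        assert ep.mask[0, 1].sum() == expected

    def test_response_lock_drops_no_response_trials(self, rng):
        rec = make_recording(rng.standard_normal((1, 5000)))
        ev = make_events([1000, 2000], [1400.0, np.nan])
        ep = epoch_events(rec, ev, "response", (-0.5, 0.2))
        assert ep.n_trials == 1
        assert list(ep.kept_trial_ids) == [0]

    def test_out_of_bounds_trials_excluded(self, rng):
        rec = make_recording(rng.standard_normal((1, 2000)))
        ev = make_events([100, 1000])
        ep = epoch_events(rec, ev, "stimulus", (-0.5, 0.5))
        assert list(ep.kept_trial_ids) == [1]
        with pytest.raises(ValueError, match="no trials"):
            epoch_events(rec, make_events([100]), "stimulus", (-0.5, 0.5))

    def test_mask_monotone_under_window_growth(self, rng):
        rec = make_recording(rng.standard_normal((1, 6000)))
        ev = make_events([1000], [1250.0])
        small = epoch_events(rec, ev, "stimulus", (0.0, 1.0))
        large = epoch_events(rec, ev, "stimulus", (-0.5, 2.0))
        # samples masked in the small window stay masked in the large one
        offset = np.argmin(np.abs(large.times - small.times[0]))
        np.testing.assert_array_equal(
            large.mask[0, :, offset : offset + small.n_times], small.mask[0]
        )

    def test_kernel_average_identity(self):
        # recording = one kernel at each event; epoch + average == kernel
        kernel = np.sin(np.linspace(0, np.pi, 100)) * 4.0
        data = np.zeros((1, 8000))
        stim = [1000, 3000, 5000]
        for s in stim:
            data[0, s : s + 100] += kernel
        ep = epoch_events(make_recording(data), make_events(stim), "stimulus", (0.0, 0.2))
        np.testing.assert_allclose(ep.mean()[0], kernel, atol=1e-12)


class TestBaselineCorrect:
    def test_constant_epoch_goes_to_zero(self, rng):
        rec = make_recording(np.full((2, 3000), 7.0))
        ep = epoch_events(rec, make_events([1000]), "stimulus", (-0.2, 0.5))
        out = baseline_correct(ep, (-0.2, 0.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
        assert out.baseline_window == (-0.2, 0.0)

    def test_post_correction_baseline_mean_is_zero(self, rng):
        rec = make_recording(rng.standard_normal((3, 4000)))
        ep = epoch_events(rec, make_events([1000, 2000]), "stimulus", (-0.2, 0.6))
        out = baseline_correct(ep, (-0.2, 0.0))
        sel = (out.times >= -0.2) & (out.times < 0.0)
        means = out.data[:, :, sel].mean(axis=2)
        np.testing.assert_allclose(means, 0.0, atol=1e-10)

    def test_equals_direct_subtraction_oracle(self, rng):
        rec = make_recording(rng.standard_normal((2, 4000)))
        ep = epoch_events(rec, make_events([1000, 2500]), "stimulus", (-0.1, 0.4))
        out = baseline_correct(ep, (-0.1, 0.0))
        sel = (ep.times >= -0.1) & (ep.times < 0.0)
        expected = ep.data - ep.data[:, :, sel].mean(axis=2, keepdims=True)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_trial_without_baseline_flagged_not_zeroed(self, rng):
        rec = make_recording(rng.standard_normal((1, 4000)))
        ev = make_events([1000], [1100.0])  # rt 0.2 s
        ep = epoch_events(rec, ev, "response", (-0.1, 0.1))
        # mask the whole would-be baseline
        ep.mask[:, :, ep.times < 0] = True
        out = baseline_correct(ep, (-0.1, 0.0))
        assert 0 in out.flags["baseline_missing"]
        np.testing.assert_array_equal(out.data[0], ep.data[0])


class TestRejectEpochs:
    def _epochs(self, data):
        rec = make_recording(data)
        n = data.shape[1]
        stim = list(range(500, n - 500, 500))
        return epoch_events(make_recording(data), make_events(stim), "stimulus", (0.0, 0.5))

    def test_single_sample_over_amplitude_rejected(self, rng):
        data = rng.standard_normal((1, 3000))
        data[0, 1010] = 151.0
        ep = self._epochs(data)
        kept, rejected = reject_epochs(ep, amp_limit=150.0, gradient_limit=1e9)
        assert rejected.sum() == 1
        assert rejected[1]  # sample 1010 falls in the second epoch

    def test_all_zero_epochs_survive(self):
        ep = self._epochs(np.zeros((2, 3000)))
        kept, rejected = reject_epochs(ep, 150.0, 50.0)
        assert not rejected.any()
        assert kept.n_trials == ep.n_trials

    def test_matches_bruteforce_scan(self, rng):
        # random walk (smooth) + sparse jumps so both criteria vary by trial
        data = 8.0 * rng.standard_normal((2, 6000)).cumsum(axis=1) / 10.0
        jumps = rng.integers(0, 6000, size=30)
        data[rng.integers(0, 2, size=30), jumps] += rng.choice([-90.0, 90.0], size=30)
        ep = self._epochs(data)
        kept, rejected = reject_epochs(ep, amp_limit=150.0, gradient_limit=50.0)
        expected = np.zeros(ep.n_trials, dtype=bool)
        for i in range(ep.n_trials):
            for c in range(ep.n_channels):
                row = ep.data[i, c]
                if np.any(np.abs(row) > 150.0) or np.any(np.abs(np.diff(row)) > 50.0):
                    expected[i] = True
        np.testing.assert_array_equal(rejected, expected)

    def test_rejection_order_invariant(self, rng):
        data = 8.0 * rng.standard_normal((1, 6000)).cumsum(axis=1) / 10.0
        data[0, rng.integers(0, 6000, size=15)] += 90.0
        ep = self._epochs(data)
        _, rejected = reject_epochs(ep, 150.0, 50.0)
        perm = rng.permutation(ep.n_trials)
        _, rejected_perm = reject_epochs(ep.subset(perm), 150.0, 50.0)
        np.testing.assert_array_equal(rejected_perm, rejected[perm])

    def test_all_rejected_raises(self):
        ep = self._epochs(np.full((1, 3000), 200.0))
        with pytest.raises(ValueError, match="all trials"):
            reject_epochs(ep, 150.0, 50.0)


class TestBuildAdjacency:
    def test_single_channel_has_no_neighbours(self):
        g = build_adjacency(np.zeros((1, 3)), 1.0)
        assert g.n_edges == 0

    def test_collinear_chain(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        g = build_adjacency(pos, 1.5)
        assert g.matrix[0, 1] and g.matrix[1, 2] and not g.matrix[0, 2]

    def test_matches_distance_matrix_oracle(self, rng):
        pos = rng.standard_normal((10, 3))
        thr = 1.2
        g = build_adjacency(pos, thr)
        d = cdist(pos, pos)
        expected = (d < thr) & ~np.eye(10, dtype=bool)
        np.testing.assert_array_equal(g.matrix, expected)

    def test_duplicate_positions_warn(self):
        pos = np.zeros((2, 3))
        with pytest.warns(UserWarning, match="duplicate"):
            build_adjacency(pos, 1.0)


class TestResample:
    def test_halving_500_to_250(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)), srate=500.0)
        out = resample(rec, 250.0)
        assert out.srate == 250.0
        assert out.n_samples == 500

    def test_factor_one_identity(self, rng):
        rec = make_recording(rng.standard_normal((1, 100)))
        out = resample(rec, rec.srate)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_constant_preserved(self):
        rec = make_recording(np.full((1, 1000), 5.0), srate=500.0)
        out = resample(rec, 250.0)
        np.testing.assert_allclose(out.data, 5.0, atol=1e-9)

    def test_non_integer_factor_rejected(self, rng):
        rec = make_recording(rng.standard_normal((1, 100)), srate=500.0)
        with pytest.raises(ValueError, match="evenly"):
            resample(rec, 300.0)


@settings(deadline=None, max_examples=25)
@given(
    amp=st.floats(min_value=5.0, max_value=300.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_rejection_threshold_is_sharp(amp, seed):
    """A trial is rejected iff its largest unmasked |sample| exceeds the limit."""
    rng = np.random.default_rng(seed)
    data = np.zeros((1, 2000))
    data[0, 600] = amp
    rec = make_recording(data)
    # second, clean trial so rejection of the first never empties the set
    ep = epoch_events(rec, make_events([500, 1200]), "stimulus", (0.0, 0.5))
    _, rejected = reject_epochs(ep, amp_limit=150.0, gradient_limit=1e9)
    assert rejected[0] == (amp > 150.0)
    assert not rejected[1]
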