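import numpy as np
import pandas as pd
import pytest

from eegoverlap import (
    BehaviourConfig,
    EEGSimConfig,
    EventDesignSpec,
    EventTable,
    EventTypeSpec,
    Recording,
    add_rt_modulation,
    correct_overlap,
    epoch_events,
    exclude_artifact_intervals,
    median_split_average,
    simulate_recording,
    simulate_trial_measures,
    solve_deconv,
    time_expand,
)
from eegoverlap.simulate import build_kernel


def make_events(stim, resp=None, srate=250.0, **covariates):
    frame = pd.DataFrame(
        {
            "participant_id": "p",
            "stimulus_sample": stim,
            "response_sample": resp if resp is not None else np.nan,
            **covariates,
        }
    )
    return EventTable(frame, srate)


def make_recording(data, srate=250.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(data, srate, [f"ch{i}" for i in range(data.shape[0])])


class TestTimeExpand:
    def test_single_event_identity_block_recovers_segment(self, rng):
        y = rng.standard_normal(500)
        rec = make_recording(y)
        events = make_events([100])
        spec = EventDesignSpec(
            {"stimulus": EventTypeSpec(window=(0.0, 0.4))}, srate=250.0
        )
        design = time_expand(events, spec, 500)
        model = solve_deconv(design, rec)
        np.testing.assert_allclose(
            model.kernel("stimulus")[:, 0], y[100:200], atol=1e-8
        )

    def test_column_count_by_hand(self):
        events = make_events([100, 300], [150.0, 380.0], rt=[0.2, 0.32])
        spec = EventDesignSpec(
            {
                "stimulus": EventTypeSpec(window=(0.0, 0.2)),         # 50 bins
                "response": EventTypeSpec(predictors=["rt"], window=(-0.2, 0.2)),  # 100 bins x 2
            },
            srate=250.0,
        )
        design = time_expand(events, spec, 600)
        assert design.matrix.shape == (600, 50 + 2 * 100)
        assert len(design.columns) == 250

    def test_nonzero_pattern_matches_stamping_oracle(self, rng):
        stim = np.sort(rng.choice(np.arange(50, 900), size=5, replace=False))
        events = make_events(list(stim))
        spec = EventDesignSpec(
            {"stimulus": EventTypeSpec(window=(-0.04, 0.08))}, srate=250.0
        )
        design = time_expand(events, spec, 1000)
        expected = np.zeros((1000, 30))
        for s in stim:
            for j, lat in enumerate(range(-10, 20)):
                r = s + lat
                if 0 <= r < 1000:
                    expected[r, j] = 1.0
        np.testing.assert_array_equal(design.matrix.toarray(), expected)

    def test_events_clipped_at_recording_edge(self):
        events = make_events([5, 500])
        spec = EventDesignSpec({"stimulus": EventTypeSpec(window=(-0.1, 0.1))}, srate=250.0)
        design = time_expand(events, spec, 600)
        assert design.n_clipped_events == 1
        # no rows below 0
        assert design.matrix[:, 0].nnz == 1


class TestArtifactExclusion:
    def _setup(self, data):
        rec = make_recording(data)
        events = make_events([100, 300])
        spec = EventDesignSpec({"stimulus": EventTypeSpec(window=(0.0, 0.2))}, srate=250.0)
        return rec, time_expand(events, spec, rec.n_samples)

    def test_clean_data_excludes_nothing(self, rng):
        rec, design = self._setup(rng.standard_normal(600))
        out = exclude_artifact_intervals(rec, design, amp_limit=250.0)
        assert not out.excluded.any()

    def test_spike_sample_excluded(self, rng):
        data = rng.standard_normal(600)
        data[130] = 300.0
        rec, design = self._setup(data)
        out = exclude_artifact_intervals(rec, design, amp_limit=250.0)
        assert out.excluded[130] and out.excluded.sum() == 1

    def test_fit_invariant_to_excluded_values(self, rng):
        data = rng.standard_normal(600)
        data[130] = 300.0
        rec, design = self._setup(data)
        out = exclude_artifact_intervals(rec, design, amp_limit=250.0)
        model_a = solve_deconv(out, rec)
        data2 = data.copy()
        data2[130] = -9999.0
        model_b = solve_deconv(out, make_recording(data2))
        np.testing.assert_allclose(
            model_a.kernel("stimulus"), model_b.kernel("stimulus"), atol=1e-9
        )

    def test_mass_exclusion_rejected(self):
        rec, design = self._setup(np.full(600, 400.0))
        with pytest.raises(ValueError, match="excluded"):
            exclude_artifact_intervals(rec, design, amp_limit=250.0)


class TestSolveDeconv:
    def test_zero_data_gives_zero_kernels(self):
        rec = make_recording(np.zeros(500))
        events = make_events([100, 250])
        spec = EventDesignSpec({"stimulus": EventTypeSpec(window=(0.0, 0.3))}, srate=250.0)
        model = solve_deconv(time_expand(events, spec, 500), rec)
        np.testing.assert_allclose(model.kernel("stimulus"), 0.0, atol=1e-12)

    def test_no_overlap_limit_equals_event_locked_average(self, rng):
        # events separated beyond the window length, no noise: deconvolution
        # must coincide with plain event-locked averaging
        srate = 250.0
        kernel = np.sin(np.linspace(0, np.pi, 80)) ** 2 * 4.0
        amps = rng.uniform(0.5, 1.5, size=6)
        stim = 200 + np.arange(6) * 400
        data = np.zeros(3000)
        for s, a in zip(stim, amps):
            data[s : s + 80] += a * kernel
        rec = make_recording(data)
        events = make_events(list(stim))
        spec = EventDesignSpec({"stimulus": EventTypeSpec(window=(-0.2, 0.6))}, srate=srate)
        model = solve_deconv(time_expand(events, spec, 3000), rec)
        ep = epoch_events(rec, events, "stimulus", (-0.2, 0.6), mask_outside_trial=False)
        np.testing.assert_allclose(model.kernel("stimulus")[:, 0], ep.mean()[0], atol=1e-6)

    def test_overlap_only_response_kernel_is_flat(self):
        # high-SNR overlap-only data: the response intercept kernel stays
        # below 10% of the stimulus peak while the naive response-locked
        # average shows a ramp exceeding 50% of it
        m, lat = simulate_trial_measures(
            BehaviourConfig(n_trials=150, rt_shift=0.15, rt_mu0=-0.25, rt_sigma=0.35, seed=31)
        )
        eeg = EEGSimConfig(
            stim_base_amp=5.0, stim_gain_appraisal=0.0, noise_white_sd=0.5, seed=32
        )
        rec, events, _ = simulate_recording(m, lat, eeg)
        spec = EventDesignSpec(
            {
                "stimulus": EventTypeSpec(window=(-0.2, 1.0)),
                "response": EventTypeSpec(window=(-1.0, 0.4)),
            },
            srate=eeg.srate,
        )
        model = solve_deconv(time_expand(events, spec, rec.n_samples), rec)
        topo_peak = 5.0  # stimulus kernel peak at the topography centre
        assert np.abs(model.kernel("response")).max() < 0.10 * topo_peak
        ep = epoch_events(rec, events, "response", (-0.9, 0.1))
        assert np.nanmax(np.abs(ep.mean())) > 0.50 * topo_peak

    def test_solver_determinism(self, rng):
        data = rng.standard_normal(800)
        rec = make_recording(data)
        events = make_events([100, 240, 420, 600])
        spec = EventDesignSpec({"stimulus": EventTypeSpec(window=(0.0, 0.4))}, srate=250.0)
        k1 = solve_deconv(time_expand(events, spec, 800), rec).kernel("stimulus")
        k2 = solve_deconv(time_expand(events, spec, 800), rec).kernel("stimulus")
        np.testing.assert_allclose(k1, k2, atol=1e-10)


class TestRTModulation:
    def _spec(self):
        return EventDesignSpec(
            {
                "stimulus": EventTypeSpec(window=(-0.2, 1.0)),
                "response": EventTypeSpec(predictors=["rt"], window=(-1.0, 0.4)),
            },
            srate=250.0,
        )

    def test_adds_stimulus_rt_column(self):
        spec = add_rt_modulation(self._spec())
        assert spec.event_types["stimulus"].predictors == ["rt"]
        # original untouched
        assert self._spec().event_types["stimulus"].predictors == []

    def test_recovers_generative_rt_slope(self):
        # stimulus amplitude genuinely varies with RT: amplitude = 5 + g*(rt - mean)
        m, lat = simulate_trial_measures(
            BehaviourConfig(n_trials=200, rt_shift=0.15, rt_mu0=-0.25, rt_sigma=0.35, seed=41)
        )
        g = 3.0
        rt = m["rt"].to_numpy()
        fake_lat = np.column_stack([rt - np.nanmean(rt), np.zeros_like(rt)])
        eeg = EEGSimConfig(
            stim_base_amp=5.0, stim_gain_appraisal=g, noise_white_sd=0.5, seed=42
        )
        rec, events, _ = simulate_recording(m, fake_lat, eeg)
        spec = add_rt_modulation(self._spec())
        model = solve_deconv(time_expand(events, spec, rec.n_samples), rec)
        est = model.kernel("stimulus", "rt")
        off, wave = build_kernel(eeg.stim_kernel, eeg.srate)
        truth_peak = g * wave.max()  # at the topography centre (weight 1)
        pz = model.channel_labels.index("Pz")
        assert np.abs(est[:, pz]).max() == pytest.approx(truth_peak, rel=0.10)

    def test_null_rt_kernel_below_permutation_floor(self, rng):
        # no RT dependence in truth: RT kernel indistinguishable from a
        # permuted-RT refit
        m, lat = simulate_trial_measures(
            BehaviourConfig(n_trials=150, rt_shift=0.15, rt_mu0=-0.25, rt_sigma=0.35, seed=51)
        )
        eeg = EEGSimConfig(stim_base_amp=5.0, stim_gain_appraisal=0.0,
                           noise_white_sd=1.0, seed=52)
        rec, events, _ = simulate_recording(m, lat, eeg)
        spec = add_rt_modulation(self._spec())
        model = solve_deconv(time_expand(events, spec, rec.n_samples), rec)
        observed = np.abs(model.kernel("stimulus", "rt")).max()
        perm_events = EventTable(events.frame.copy(), events.srate)
        responded = np.isfinite(perm_events.frame["rt"].to_numpy())
        shuffled = perm_events.frame.loc[responded, "rt"].sample(frac=1.0, random_state=7)
        perm_events.frame.loc[responded, "rt"] = shuffled.to_numpy()
        model_p = solve_deconv(time_expand(perm_events, spec, rec.n_samples), rec)
        floor = np.abs(model_p.kernel("stimulus", "rt")).max()
        assert observed < 2.0 * floor

    def test_requires_stimulus_type(self):
        spec = EventDesignSpec({"response": EventTypeSpec(window=(-1, 1))}, srate=250.0)
        with pytest.raises(ValueError, match="stimulus"):
            add_rt_modulation(spec)


class TestCorrectOverlap:
    def _fitted(self, noise_sd=0.0, seed=61, n=80):
        m, lat = simulate_trial_measures(
            BehaviourConfig(n_trials=n, rt_shift=0.15, rt_mu0=-0.25, rt_sigma=0.35, seed=seed)
        )
        eeg = EEGSimConfig(stim_base_amp=5.0, stim_gain_appraisal=0.0,
                           noise_white_sd=noise_sd, seed=seed + 1)
        rec, events, truth = simulate_recording(m, lat, eeg)
        spec = EventDesignSpec(
            {
                "stimulus": EventTypeSpec(window=(-0.2, 1.0)),
                "response": EventTypeSpec(window=(-1.0, 0.4)),
            },
            srate=eeg.srate,
        )
        model = solve_deconv(time_expand(events, spec, rec.n_samples), rec)
        return rec, events, truth, model

    def test_residual_is_algebraic_identity(self):
        rec, _, _, model = self._fitted()
        out = correct_overlap(rec, model, remove={"stimulus", "response"})
        expected = rec.data - (model.design.matrix @ model.solution).T
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_removing_all_types_on_noiseless_data_leaves_nothing(self):
        rec, _, _, model = self._fitted(noise_sd=0.0)
        out = correct_overlap(rec, model, remove={"stimulus", "response"})
        assert np.abs(out.data).max() < 1e-6 * np.abs(rec.data).max()

    def test_stimulus_removal_abolishes_fast_slow_ordering(self):
        rec, events, truth, model = self._fitted(noise_sd=0.5, n=150)
        pz = rec.channel_index("Pz")

        def pre_response_gap(recording):
            ep = epoch_events(recording, events, "response", (-0.9, 0.1))
            rt = events.rt[ep.kept_trial_ids]
            split = median_split_average(ep, rt)
            sel = (ep.times >= -0.7) & (ep.times < -0.2)
            return abs(
                np.nanmean(split.fast_mean[pz, sel]) - np.nanmean(split.slow_mean[pz, sel])
            )

        before = pre_response_gap(rec)
        after = pre_response_gap(correct_overlap(rec, model, remove={"stimulus"}))
        assert after < 0.2 * before

    def test_unknown_event_type_rejected(self):
        rec, _, _, model = self._fitted()
        with pytest.raises(ValueError, match="unknown event type"):
            correct_overlap(rec, model, remove={"saccade"})
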