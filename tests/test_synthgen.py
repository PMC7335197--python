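"""Generator-level checks: scheduler timing, stimulus waveform, population
statistics and the fluorescence forward model."""

import numpy as np
import pandas as pd
import pytest

import axoncal as ax
from axoncal.config import ClassParams, ConfigurationError
from axoncal.synthgen import GenerationError, gcamp_kernel


class TestTrialSchedule:
    def test_minimum_interstimulus_interval_is_trial_plus_gap(self):
        cfg = ax.SessionConfig(n_trials=50, trial_duration=9.0,
                               min_intertrial_gap=4.5, seed=1)
        trials = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        gaps = np.diff(trials["stim_onset_time_s"].to_numpy())
        assert gaps.min() == pytest.approx(13.5, abs=1e-12)

    def test_jittered_schedule_respects_minimum_gap(self):
        cfg = ax.SessionConfig(n_trials=200, intertrial_jitter=3.0, seed=2)
        trials = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        gaps = np.diff(trials["stim_onset_time_s"].to_numpy())
        assert (gaps >= 13.5).all()

    def test_zero_stim_fraction_gives_only_no_stim_trials(self):
        cfg = ax.SessionConfig(n_trials=30, stim_fraction=0.0, seed=3)
        trials = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        assert (trials["condition"] == "none").all()

    def test_stimulus_fraction_within_binomial_bound(self):
        n = 10_000
        cfg = ax.SessionConfig(n_trials=n, stim_fraction=0.8, seed=4)
        trials = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        frac = (trials["condition"] != "none").mean()
        bound = 3 * np.sqrt(0.8 * 0.2 / n)
        assert abs(frac - 0.8) < bound

    def test_reaction_times_within_response_window(self):
        cfg = ax.SessionConfig(n_trials=500, seed=5)
        trials = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        rt = trials.loc[trials["lick"], "reaction_time_s"]
        assert ((rt > 0) & (rt <= cfg.response_window)).all()
        assert trials.loc[~trials["lick"], "reaction_time_s"].isna().all()

    def test_outcome_labels_follow_condition_and_lick(self):
        cfg = ax.SessionConfig(n_trials=400, seed=6)
        trials = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        got = trials.groupby(["condition", "lick"])["outcome"].unique()
        expect = {("C2", True): "hit", ("C2", False): "miss",
                  ("B2", True): "false_alarm",
                  ("B2", False): "correct_rejection",
                  ("none", True): "no_stim_lick",
                  ("none", False): "no_stim_quiet"}
        for key, label in expect.items():
            if key in got.index:
                assert list(got.loc[key]) == [label]

    def test_same_seed_reproduces_schedule(self):
        cfg = ax.SessionConfig(n_trials=100, seed=7)
        a = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        b = ax.generate_trial_schedule(cfg, ax.BehaviorConfig())
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_config_raises(self):
        with pytest.raises(ConfigurationError):
            ax.SessionConfig(stim_fraction=1.5)
        with pytest.raises(ConfigurationError):
            ax.SessionConfig(trial_duration=3.0)  # < quiet + response
        with pytest.raises(ConfigurationError):
            ax.BehaviorConfig(p_lick={"C2": 2.0, "B2": 0.1, "none": 0.1})


class TestStimulusWaveform:
    def test_default_support_is_200_ms(self):
        t, disp = ax.synthesize_stimulus_waveform(ax.SessionConfig())
        dt = t[1] - t[0]
        assert np.count_nonzero(disp) * dt == pytest.approx(0.2, abs=1e-12)

    def test_single_pulse_support_is_40_ms(self):
        cfg = ax.SessionConfig(n_pulses=1, stim_duration=0.04)
        t, disp = ax.synthesize_stimulus_waveform(cfg)
        dt = t[1] - t[0]
        assert np.count_nonzero(disp) * dt == pytest.approx(0.04, abs=1e-12)

    def test_each_pulse_integrates_to_zero(self):
        cfg = ax.SessionConfig()
        t, disp = ax.synthesize_stimulus_waveform(cfg, sample_rate=2000.0)
        per_pulse = len(t) // cfg.n_pulses
        for k in range(cfg.n_pulses):
            pulse = disp[k * per_pulse:(k + 1) * per_pulse]
            assert pulse.sum() * (t[1] - t[0]) == pytest.approx(0.0, abs=1e-12)


class TestAxonPopulation:
    def test_single_class_proportions(self):
        pop = ax.PopulationConfig(n_axons=20,
                                  class_proportions={"VPM_like": 1.0})
        truth = ax.generate_axon_population(pop, rng=1)
        assert all(a.axon_class == "VPM_like" for a in truth.axons)

    def test_weakly_tuned_class_has_smaller_mean_abs_wsi(self):
        kwargs = dict(n_axons=150)
        vpm = ax.generate_axon_population(ax.PopulationConfig(
            class_proportions={"VPM_like": 1.0}, **kwargs), rng=2)
        ho = ax.generate_axon_population(ax.PopulationConfig(
            class_proportions={"POmHO_like": 1.0}, **kwargs), rng=2)
        mean_abs = lambda t: np.mean([abs(a.true_wsi) for a in t.axons])
        assert mean_abs(ho) < mean_abs(vpm)

    def test_clustered_class_separates_preferred_whiskers_spatially(self):
        pop = ax.PopulationConfig(n_axons=120,
                                  class_proportions={"VPM_like": 1.0})
        truth = ax.generate_axon_population(pop, rng=3)
        c2 = np.array([a.centroid for a in truth.axons if a.true_wsi > 0])
        b2 = np.array([a.centroid for a in truth.axons if a.true_wsi < 0])
        dist = np.linalg.norm(c2.mean(0) - b2.mean(0))
        spread = max(c2.std(axis=0).max(), b2.std(axis=0).max())
        assert dist > spread

    def test_same_seed_gives_identical_population(self):
        pop = ax.PopulationConfig(n_axons=30)
        a = ax.generate_axon_population(pop, rng=9)
        b = ax.generate_axon_population(pop, rng=9)
        assert a.to_json() == b.to_json()

    def test_empty_population_rejected(self):
        with pytest.raises(ConfigurationError):
            ax.PopulationConfig(n_axons=0)


def _single_axon_setup(wsi, noise_sd=1.0, **class_kwargs):
    cfg = ax.SessionConfig(n_trials=20, seed=0)
    pop = ax.PopulationConfig(
        n_axons=1, class_proportions={"VPM_like": 1.0},
        class_params={"VPM_like": ClassParams(
            wsi_mode="bipolar", wsi_range=(abs(wsi), abs(wsi)),
            latency_mean=0.1, latency_jitter=0.0, **class_kwargs)},
        noise_sd=noise_sd, drift_amplitude_range=(0.0, 0.0),
        baseline_offset_range=(0.0, 0.0), neuropil_sd_frac=0.0,
        trial_gain_cv=0.0, spont_event_rate=0.0,
        n_segments_range=(1, 1))
    return cfg, pop


def _noiseless_single_axon(wsi: float, conditions: list[str],
                           latency: float = 0.1):
    """Hand-built one-axon ground truth, zero noise/drift/neuropil, and a
    schedule whose conditions are forced to `conditions`."""
    cfg = ax.SessionConfig(n_trials=len(conditions), seed=0)
    beh = ax.BehaviorConfig(p_lick={"C2": 0, "B2": 0, "none": 0})
    trials = ax.generate_trial_schedule(cfg, beh)
    trials["condition"] = conditions
    spec = ax.AxonSpec(axon_id=0, axon_class="VPM_like", true_wsi=wsi,
                       true_latency=latency, event_amplitude=5.0,
                       lick_transient_gain=0.0, lick_gain_modulation=1.0,
                       n_segments=1, segment_pixel_counts=(10,),
                       centroid=(50.0, 50.0), drift_coefficients=(0.0,),
                       noise_sd=0.0, neuropil_coefficient=0.0)
    truth = ax.GroundTruth(axons=[spec], field_shape=(256, 256),
                           within_axon_corr=0.9, noise_sd=0.0,
                           kernel_tau_rise=0.18, kernel_tau_decay=1.8)
    pop = ax.PopulationConfig(neuropil_sd_frac=0.0, trial_gain_cv=0.0,
                              spont_event_rate=0.0)
    segs = ax.synthesize_traces(truth, trials, cfg, pop, rng=0)
    return cfg, trials, spec, segs


class TestTraceSynthesis:
    def test_noiseless_trace_is_kernel_at_event_onset(self):
        cfg, trials, spec, segs = _noiseless_single_axon(
            wsi=1.0, conditions=["C2", "none", "none"])
        trace = segs[0].raw_trace
        kernel = gcamp_kernel(cfg.frame_rate)
        onset = int(trials["stim_onset_frame"].iloc[0])
        lat = round(spec.true_latency * cfg.frame_rate)
        # amplitude rule: A_C2 = A (1 + w)/2 = A for w = 1
        expect = spec.event_amplitude * kernel[:30]
        assert np.allclose(trace[onset + lat:onset + lat + 30], expect,
                           atol=1e-9)
        peak_err = np.argmax(trace[onset:onset + 60]) - (lat + np.argmax(kernel))
        assert abs(peak_err) <= 1

    def test_full_selectivity_silences_nonpreferred_whisker(self):
        cfg, trials, spec, segs = _noiseless_single_axon(
            wsi=1.0, conditions=["B2", "C2", "none"])
        trace = segs[0].raw_trace
        onsets = trials["stim_onset_frame"].to_numpy()
        b2_peak = trace[int(onsets[0]):int(onsets[0]) + 90].max()
        c2_peak = trace[int(onsets[1]):int(onsets[1]) + 90].max()
        assert b2_peak == pytest.approx(0.0, abs=1e-12)
        assert c2_peak > 0.5 * spec.event_amplitude

    def test_within_axon_segment_correlation_matches_noise_split(self):
        # corr = var_shared / (var_shared + var_seg); transient-free axon
        rho = 0.9
        cfg = ax.SessionConfig(n_trials=200, stim_fraction=0.0, seed=0)
        pop = ax.PopulationConfig(
            n_axons=1, class_proportions={"POmHO_like": 1.0},
            within_axon_corr=rho, drift_amplitude_range=(0.0, 0.0),
            baseline_offset_range=(0.0, 0.0), neuropil_sd_frac=0.0,
            spont_event_rate=0.0, n_segments_range=(2, 2))
        beh = ax.BehaviorConfig(p_lick={"C2": 0, "B2": 0, "none": 0})
        _, _, segs = ax.generate_session(cfg, beh, pop, seed=7)
        assert len(segs) == 2 and len(segs[0].raw_trace) >= 50_000
        r = np.corrcoef(segs[0].raw_trace, segs[1].raw_trace)[0, 1]
        assert abs(r - rho) < 0.05

    def test_transient_free_noise_sd_matches_configuration(self):
        cfg = ax.SessionConfig(n_trials=400, stim_fraction=0.0, seed=0)
        pop = ax.PopulationConfig(
            n_axons=1, class_proportions={"POmHO_like": 1.0}, noise_sd=2.5,
            drift_amplitude_range=(0.0, 0.0), baseline_offset_range=(0.0, 0.0),
            neuropil_sd_frac=0.0, spont_event_rate=0.0,
            n_segments_range=(1, 1))
        beh = ax.BehaviorConfig(p_lick={"C2": 0, "B2": 0, "none": 0})
        _, _, segs = ax.generate_session(cfg, beh, pop, seed=8)
        trace = segs[0].raw_trace
        assert trace.size >= 100_000
        assert abs(trace.std() - 2.5) / 2.5 < 0.02

    def test_latency_beyond_trial_end_raises(self):
        cfg, pop = _single_axon_setup(wsi=1.0)
        pop.class_params["VPM_like"].latency_mean = 8.0  # past trial end
        with pytest.raises(GenerationError):
            ax.generate_session(cfg, ax.BehaviorConfig(), pop, seed=9)

    def test_sessions_are_bit_reproducible(self):
        cfg = ax.SessionConfig(n_trials=10, seed=11)
        pop = ax.PopulationConfig(n_axons=4)
        t1, g1, s1 = ax.generate_session(cfg, pop=pop, seed=11)
        t2, g2, s2 = ax.generate_session(cfg, pop=pop, seed=11)
        pd.testing.assert_frame_equal(t1, t2)
        assert g1.to_json() == g2.to_json()
        for a, b in zip(s1, s2):
            assert np.array_equal(a.raw_trace, b.raw_trace)
            assert np.array_equal(a.pixel_mask, b.pixel_mask)
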