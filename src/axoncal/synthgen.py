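"""Seeded synthetic two-photon sessions with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: trial-based 30 Hz acquisition of 9 s sweeps concatenated into one
session trace, sparse calcium transients shaped by a slow-indicator
double-exponential kernel, class-dependent whisker tuning and onset latency,
slow polynomial baseline drift, a shared neuropil background mixed into every
segment with its own coefficient, and Gaussian noise split into a
within-axon shared component and per-segment independent components so that
segments of one axon correlate above the merge threshold by construction.

Evoked amplitudes follow the rule ``A_C2 = A (1 + w) / 2`` and
``A_B2 = A (1 - w) / 2`` where ``w`` is the axon's true selectivity, so the
selectivity index recomputed from noiseless amplitudes equals ``w`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .config import (AXON_CLASSES, BehaviorConfig, ClassParams,
                     ConfigurationError, PopulationConfig, SessionConfig)

__all__ = [
    "AxonSpec", "GroundTruth", "RoiSegment",
    "generate_trial_schedule", "synthesize_stimulus_waveform",
    "generate_axon_population", "synthesize_traces", "generate_session",
    "gcamp_kernel",
]


class GenerationError(RuntimeError):
    """Raised when a ground-truth specification cannot be realized."""


# ---------------------------------------------------------------------------
# ground-truth containers

@dataclass
class AxonSpec:
    axon_id: int
    axon_class: str
    true_wsi: float
    true_latency: float              # s from stimulus onset
    event_amplitude: float           # peak, in noise-SD units
    lick_transient_gain: float       # peak of lick-locked transient, noise-SD
    lick_gain_modulation: float      # multiplies evoked amplitude in lick trials
    n_segments: int
    segment_pixel_counts: tuple[int, ...]
    centroid: tuple[float, float]    # (row, col) pixels
    drift_coefficients: tuple[float, ...]  # Chebyshev-like coeffs on [-1, 1]
    noise_sd: float                  # fluorescence units
    neuropil_coefficient: float


@dataclass
class GroundTruth:
    axons: list[AxonSpec]
    field_shape: tuple[int, int]
    within_axon_corr: float
    noise_sd: float
    kernel_tau_rise: float
    kernel_tau_decay: float

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        axons = []
        for a in d.pop("axons"):
            a["segment_pixel_counts"] = tuple(a["segment_pixel_counts"])
            a["centroid"] = tuple(a["centroid"])
            a["drift_coefficients"] = tuple(a["drift_coefficients"])
            axons.append(AxonSpec(**a))
        d["field_shape"] = tuple(d["field_shape"])
        return cls(axons=axons, **d)


@dataclass
class RoiSegment:
    """One axonal ROI: pixel mask plus raw and neuropil fluorescence traces."""
    segment_id: int
    parent_axon_id: int              # ground truth only; -1 if unknown
    pixel_mask: np.ndarray           # (n_pixels, 2) int array of (row, col)
    raw_trace: np.ndarray
    neuropil_trace: np.ndarray
    neuropil_coefficient: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_mask)


# ---------------------------------------------------------------------------
# trial schedule and stimulus

def generate_trial_schedule(cfg: SessionConfig, beh: BehaviorConfig,
                            rng: np.random.Generator | None = None
                            ) -> pd.DataFrame:
    """Draw one session's trial table.

    Conditions are i.i.d. draws (stimulus with probability
    ``cfg.stim_fraction``, then C2 vs B2), lick flags are Bernoulli per
    condition, and reaction times come from the truncated normal in *beh*.
    Consecutive trial starts are separated by ``trial_duration +
    min_intertrial_gap`` plus optional uniform jitter, so inter-stimulus-onset
    intervals never fall below their configured minimum.

    Columns: trial, condition, stim_onset_frame (index into the
    trial-concatenated trace), stim_onset_time_s (wall clock), lick,
    reaction_time_s (NaN when lick is False), outcome.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    is_stim = rng.random(n) < cfg.stim_fraction
    is_c2 = rng.random(n) < cfg.c2_fraction_of_stim
    condition = np.where(is_stim, np.where(is_c2, "C2", "B2"), "none")

    p = np.array([beh.p_lick[c] for c in condition])
    lick = rng.random(n) < p

    rt_max = beh.rt_max if beh.rt_max is not None else cfg.response_window
    a = (beh.rt_min - beh.rt_mean) / beh.rt_sd
    b = (rt_max - beh.rt_mean) / beh.rt_sd
    rt = stats.truncnorm.rvs(a, b, loc=beh.rt_mean, scale=beh.rt_sd,
                             size=n, random_state=rng)
    rt = np.where(lick, rt, np.nan)

    gaps = np.full(n, cfg.min_intertrial_gap)
    if cfg.intertrial_jitter > 0:
        gaps = gaps + rng.uniform(0, cfg.intertrial_jitter, size=n)
    trial_start = np.concatenate(
        [[0.0], np.cumsum(cfg.trial_duration + gaps[:-1])])
    onset_time = trial_start + cfg.quiet_window
    onset_frame = (np.arange(n) * cfg.frames_per_trial
                   + cfg.stim_onset_frame_in_trial)

    outcome = np.select(
        [(condition == "C2") & lick, (condition == "C2") & ~lick,
         (condition == "B2") & lick, (condition == "B2") & ~lick,
         (condition == "none") & lick],
        ["hit", "miss", "false_alarm", "correct_rejection", "no_stim_lick"],
        default="no_stim_quiet")

    return pd.DataFrame({
        "trial": np.arange(n),
        "condition": condition,
        "stim_onset_frame": onset_frame,
        "stim_onset_time_s": onset_time,
        "lick": lick,
        "reaction_time_s": rt,
        "outcome": outcome,
    })


def synthesize_stimulus_waveform(cfg: SessionConfig, sample_rate: float = 1000.0
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Piezo command waveform: ``n_pulses`` contiguous single-period sine
    pulses of ``pulse_duration`` each.

    Returns ``(time, displacement)`` sampled at bin midpoints, so every
    sample inside the pulse train is nonzero and the nonzero support measured
    from the samples equals ``n_pulses * pulse_duration`` exactly.
    """
    if cfg.n_pulses < 1:
        raise ConfigurationError("n_pulses must be >= 1")
    dt = 1.0 / sample_rate
    total = cfg.n_pulses * cfg.pulse_duration
    t = (np.arange(int(round(total / dt))) + 0.5) * dt
    disp = np.sin(2 * np.pi * (t % cfg.pulse_duration) / cfg.pulse_duration)
    return t, disp


# ---------------------------------------------------------------------------
# axon population

def _draw_wsi(params: ClassParams, rng: np.random.Generator) -> float:
    if params.wsi_mode == "bipolar":
        lo, hi = params.wsi_range
        mag = rng.uniform(lo, hi)
        return float(mag * rng.choice([-1.0, 1.0]))
    if params.wsi_mode == "central":
        return float(np.clip(rng.normal(0.0, params.wsi_sd), -0.95, 0.95))
    raise ConfigurationError(f"unknown wsi_mode {params.wsi_mode!r}")


def generate_axon_population(pop: PopulationConfig,
                             rng: np.random.Generator | int | None = None
                             ) -> GroundTruth:
    """Draw a ground-truth axon population.

    Tuned axons of a clustered class (VPM-like) are placed in two disjoint
    spatial clusters by preferred whisker (C2-preferring near the first
    cluster center, B2-preferring near the second); non-clustered classes
    are scattered uniformly over the field, so their C2- and B2-preferring
    axons intermingle.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    classes = [c for c in AXON_CLASSES if pop.class_proportions.get(c, 0) > 0]
    probs = np.array([pop.class_proportions[c] for c in classes])
    assignment = rng.choice(len(classes), size=pop.n_axons, p=probs / probs.sum())

    h, w = pop.field_shape
    axons: list[AxonSpec] = []
    for axon_id in range(pop.n_axons):
        cls_name = classes[assignment[axon_id]]
        params = pop.class_params[cls_name]
        wsi = _draw_wsi(params, rng)
        latency = max(1.0 / 30.0 / 2, rng.normal(params.latency_mean,
                                                 params.latency_jitter))
        if params.clustered:
            center = pop.cluster_centers[0] if wsi >= 0 else pop.cluster_centers[1]
            centroid = (
                float(np.clip(rng.normal(center[0], pop.cluster_sd), 2, h - 3)),
                float(np.clip(rng.normal(center[1], pop.cluster_sd), 2, w - 3)))
        else:
            centroid = (float(rng.uniform(2, h - 3)), float(rng.uniform(2, w - 3)))
        n_seg = int(rng.integers(pop.n_segments_range[0],
                                 pop.n_segments_range[1] + 1))
        px = tuple(int(rng.integers(pop.pixels_per_segment_range[0],
                                    pop.pixels_per_segment_range[1] + 1))
                   for _ in range(n_seg))
        # slow drift: random cubic on [-1, 1], range-normalized then scaled
        coeffs = rng.normal(size=4)
        x = np.linspace(-1, 1, 201)
        curve = np.polynomial.polynomial.polyval(x, coeffs)
        span = curve.max() - curve.min()
        amp = rng.uniform(*pop.drift_amplitude_range) * pop.noise_sd
        scale = amp / span if span > 0 else 0.0
        coeffs = coeffs * scale
        coeffs[0] += rng.uniform(*pop.baseline_offset_range)
        axons.append(AxonSpec(
            axon_id=axon_id, axon_class=cls_name, true_wsi=wsi,
            true_latency=float(latency),
            event_amplitude=params.event_amplitude,
            lick_transient_gain=params.lick_transient_gain,
            lick_gain_modulation=params.lick_gain_modulation,
            n_segments=n_seg, segment_pixel_counts=px, centroid=centroid,
            drift_coefficients=tuple(float(c) for c in coeffs),
            noise_sd=pop.noise_sd,
            neuropil_coefficient=float(rng.uniform(*pop.neuropil_coeff_range)),
        ))
    return GroundTruth(axons=axons, field_shape=pop.field_shape,
                       within_axon_corr=pop.within_axon_corr,
                       noise_sd=pop.noise_sd,
                       kernel_tau_rise=pop.kernel_tau_rise,
                       kernel_tau_decay=pop.kernel_tau_decay)


# ---------------------------------------------------------------------------
# fluorescence synthesis

def gcamp_kernel(frame_rate: float, tau_rise: float = 0.18,
                 tau_decay: float = 1.8, duration: float | None = None,
                 frame_integrated: bool = True) -> np.ndarray:
    """Peak-normalized double-exponential calcium-transient kernel
    ``(1 - exp(-t/tau_rise)) * exp(-t/tau_decay)`` sampled at the frame rate.

    With ``frame_integrated`` (default) each sample is the average of the
    continuous kernel over its frame interval, emulating a scanning
    acquisition that integrates photons across the frame period; a transient
    therefore already contributes within its onset frame. Point sampling at
    frame starts is available for analytic comparisons.
    """
    if duration is None:
        duration = 6.0 * tau_decay
    dt = 1.0 / frame_rate
    if frame_integrated:
        sub = 20
        t = np.arange(0.0, duration, dt / sub)
        k_fine = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
        n = t.size // sub
        k = k_fine[: n * sub].reshape(n, sub).mean(axis=1)
    else:
        t = np.arange(0.0, duration, dt)
        k = (1.0 - np.exp(-t / tau_rise)) * np.exp(-t / tau_decay)
    peak = k.max()
    if peak <= 0:
        raise ConfigurationError("degenerate kernel")
    return k / peak


def _segment_mask(centroid: tuple[float, float], count: int,
                  shape: tuple[int, int], rng: np.random.Generator
                  ) -> np.ndarray:
    """Compact blob of `count` pixels around a jittered centroid."""
    h, w = shape
    r0 = np.clip(centroid[0] + rng.normal(0, 2.0), 0, h - 1)
    c0 = np.clip(centroid[1] + rng.normal(0, 2.0), 0, w - 1)
    radius = int(np.ceil(np.sqrt(count / np.pi))) + 2
    rr = np.arange(max(0, int(r0) - radius), min(h, int(r0) + radius + 1))
    cc = np.arange(max(0, int(c0) - radius), min(w, int(c0) + radius + 1))
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    coords = np.column_stack([grid_r.ravel(), grid_c.ravel()])
    d2 = (coords[:, 0] - r0) ** 2 + (coords[:, 1] - c0) ** 2
    order = np.argsort(d2, kind="stable")
    return coords[order[:count]].astype(np.int64)


def _event_train(spec: AxonSpec, trials: pd.DataFrame, cfg: SessionConfig,
                 rng: np.random.Generator, spont_rate: float,
                 trial_gain_cv: float) -> np.ndarray:
    n_frames = cfg.n_frames
    events = np.zeros(n_frames)
    frames_per_trial = cfg.frames_per_trial
    lat_frames = int(round(spec.true_latency * cfg.frame_rate))
    if cfg.stim_onset_frame_in_trial + lat_frames >= frames_per_trial:
        raise GenerationError(
            f"axon {spec.axon_id}: latency {spec.true_latency} s places the "
            "evoked event beyond the trial end")
    if trial_gain_cv > 0:
        sigma2 = np.log1p(trial_gain_cv ** 2)
        gains = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=len(trials))
    else:
        gains = np.ones(len(trials))

    for i, row in enumerate(trials.itertuples(index=False)):
        onset = int(row.stim_onset_frame)
        if row.condition != "none":
            amp = spec.event_amplitude * (
                (1 + spec.true_wsi) / 2 if row.condition == "C2"
                else (1 - spec.true_wsi) / 2)
            if row.lick:
                amp *= spec.lick_gain_modulation
            events[onset + lat_frames] += amp * gains[i]
        if row.lick and spec.lick_transient_gain > 0:
            lick_frame = onset + int(round(row.reaction_time_s * cfg.frame_rate))
            if lick_frame < n_frames:
                events[lick_frame] += spec.lick_transient_gain * gains[i]
    if spont_rate > 0:
        n_spont = rng.poisson(spont_rate * n_frames / cfg.frame_rate)
        if n_spont:
            frames = rng.integers(0, n_frames, size=n_spont)
            np.add.at(events, frames,
                      spec.event_amplitude * rng.lognormal(
                          -0.125, 0.5, size=n_spont))
    return events


def synthesize_traces(truth: GroundTruth, trials: pd.DataFrame,
                      cfg: SessionConfig, pop: PopulationConfig | None = None,
                      rng: np.random.Generator | int | None = None
                      ) -> list[RoiSegment]:
    """Render ROI-segment fluorescence traces from a ground-truth population.

    Per axon: an event train (evoked transients at stimulus onset plus the
    true latency, lick-locked transients at the reaction time, sparse
    spontaneous events) is convolved with the indicator kernel, scaled to
    fluorescence units, and summed with polynomial drift and a shared noise
    component. Each segment then adds its own independent noise and the
    session-wide neuropil trace scaled by its coefficient. The shared versus
    independent noise variances follow the configured within-axon
    correlation: ``var_shared = rho * noise_sd**2``.
    """
    if pop is None:
        pop = PopulationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_frames = cfg.n_frames
    kernel = gcamp_kernel(cfg.frame_rate, truth.kernel_tau_rise,
                          truth.kernel_tau_decay)

    # session-wide neuropil background: offset + slow fluctuation
    np_sd = pop.neuropil_sd_frac * truth.noise_sd
    smooth = gaussian_filter1d(rng.normal(size=n_frames), sigma=30.0)
    sd = smooth.std()
    neuropil = 20.0 + (np_sd / sd) * smooth if sd > 0 else np.full(n_frames, 20.0)

    rho = truth.within_axon_corr
    x = np.linspace(-1, 1, n_frames)
    segments: list[RoiSegment] = []
    seg_id = 0
    for spec in truth.axons:
        events = _event_train(spec, trials, cfg, rng, pop.spont_event_rate,
                              pop.trial_gain_cv)
        # event amplitudes are in noise-SD units; with zero noise the
        # fluorescence scale degenerates to 1
        amp_scale = spec.noise_sd if spec.noise_sd > 0 else 1.0
        transients = sps.fftconvolve(events, kernel)[:n_frames] * amp_scale
        drift = np.polynomial.polynomial.polyval(x, spec.drift_coefficients)
        shared = rng.normal(0.0, np.sqrt(rho) * spec.noise_sd, n_frames)
        axon_common = drift + transients + shared
        seg_sd = np.sqrt(1.0 - rho) * spec.noise_sd
        for count in spec.segment_pixel_counts:
            mask = _segment_mask(spec.centroid, count, truth.field_shape, rng)
            raw = (axon_common + rng.normal(0.0, seg_sd, n_frames)
                   + spec.neuropil_coefficient * neuropil)
            segments.append(RoiSegment(
                segment_id=seg_id, parent_axon_id=spec.axon_id,
                pixel_mask=mask, raw_trace=raw, neuropil_trace=neuropil.copy(),
                neuropil_coefficient=spec.neuropil_coefficient))
            seg_id += 1
    return segments


def generate_session(cfg: SessionConfig, beh: BehaviorConfig | None = None,
                     pop: PopulationConfig | None = None,
                     seed: int | None = None
                     ) -> tuple[pd.DataFrame, GroundTruth, list[RoiSegment]]:
    """One-call synthetic session: schedule, ground truth, segment traces.

    All randomness derives from ``seed`` (default ``cfg.seed``) through
    independent child streams for the schedule, the population, and the
    trace noise, so a session is bit-reproducible from its seed.
    """
    beh = beh or BehaviorConfig()
    pop = pop or PopulationConfig()
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    r_sched, r_pop, r_trace = (np.random.default_rng(s) for s in ss.spawn(3))
    trials = generate_trial_schedule(cfg, beh, rng=r_sched)
    truth = generate_axon_population(pop, rng=r_pop)
    segments = synthesize_traces(truth, trials, cfg, pop, rng=r_trace)
    return trials, truth, segments
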