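"""Configuration objects for synthetic sessions and the analysis pipeline.

The defaults encode the two-whisker go/no-go discrimination protocol the
analysis is built around: 9 s trials acquired at 30 Hz, a 2 s pre-stimulus
quiet window, a 200 ms five-pulse whisker deflection at the start of a 2 s
response window, 80% stimulus trials split evenly between the rewarded (C2)
and non-rewarded (B2) whisker, and at least 4.5 s between trials so that
stimulus onsets are never closer than 13.5 s in wall-clock time.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

CONDITIONS = ("C2", "B2", "none")
AXON_CLASSES = ("VPM_like", "POmFO_like", "POmHO_like")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SessionConfig:
    """Acquisition and task-timing parameters for one imaging session.

    Times are seconds, rates Hz. ``reward_volume`` (µl) and ``timeout`` (s)
    are task bookkeeping only; they do not influence the generated signals.
    """

    n_trials: int = 100
    frame_rate: float = 30.0
    trial_duration: float = 9.0
    quiet_window: float = 2.0
    response_window: float = 2.0
    stim_duration: float = 0.2
    n_pulses: int = 5
    pulse_duration: float = 0.04
    min_intertrial_gap: float = 4.5
    intertrial_jitter: float = 0.0
    stim_fraction: float = 0.8
    c2_fraction_of_stim: float = 0.5
    reward_volume: float = 8.0
    timeout: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        for name in ("frame_rate", "trial_duration", "quiet_window",
                     "response_window", "pulse_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_intertrial_gap < 0 or self.intertrial_jitter < 0:
            raise ConfigurationError("inter-trial gap/jitter must be >= 0")
        if not self.trial_duration > self.quiet_window + self.response_window:
            raise ConfigurationError(
                "trial_duration must exceed quiet_window + response_window")
        if not math.isclose(self.n_pulses * self.pulse_duration,
                            self.stim_duration, rel_tol=1e-9):
            raise ConfigurationError(
                "n_pulses * pulse_duration must equal stim_duration")
        if not 0.0 <= self.stim_fraction <= 1.0:
            raise ConfigurationError("stim_fraction must be in [0, 1]")
        if not 0.0 <= self.c2_fraction_of_stim <= 1.0:
            raise ConfigurationError("c2_fraction_of_stim must be in [0, 1]")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))

    @property
    def stim_onset_frame_in_trial(self) -> int:
        """Frame index of stimulus onset within a trial (end of quiet window)."""
        return int(round(self.quiet_window * self.frame_rate))

    @property
    def n_frames(self) -> int:
        """Total frames of the trial-concatenated session trace."""
        return self.n_trials * self.frames_per_trial


@dataclass
class BehaviorConfig:
    """Licking behavior: per-condition lick probabilities and the first-lick
    reaction-time distribution, a normal truncated to (rt_min, rt_max]."""

    p_lick: Mapping[str, float] = field(
        default_factory=lambda: {"C2": 0.85, "B2": 0.30, "none": 0.10})
    rt_mean: float = 0.29
    rt_sd: float = 0.18
    rt_min: float = 0.0
    rt_max: float | None = None  # None -> response_window

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            p = self.p_lick.get(cond)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"p_lick[{cond!r}] must be a probability in [0, 1]")
        if self.rt_mean <= 0 or self.rt_sd <= 0:
            raise ConfigurationError("rt_mean and rt_sd must be positive")
        if self.rt_min < 0:
            raise ConfigurationError("rt_min must be >= 0")


@dataclass
class ClassParams:
    """Generative parameters of one thalamocortical axon class.

    ``wsi_mode`` selects the shape of the true whisker-selectivity
    distribution: "bipolar" draws |WSI| uniformly from ``wsi_range`` with a
    random sign (sharp tuning when the range sits near 1, bimodal when it is
    broad), "central" draws WSI from a clipped normal around 0.
    """

    wsi_mode: str = "bipolar"
    wsi_range: tuple[float, float] = (0.8, 1.0)
    wsi_sd: float = 0.2
    latency_mean: float = 0.05
    latency_jitter: float = 0.01
    event_amplitude: float = 5.0
    lick_transient_gain: float = 0.0
    lick_gain_modulation: float = 1.0
    clustered: bool = False


def _default_class_params() -> dict[str, ClassParams]:
    # VPM-like: sharply tuned, short latency, lick-locked transients, no
    # decision gain.  POm first-order: broader bimodal tuning, later, evoked
    # response enhanced in lick trials.  POm higher-order: weakly tuned,
    # latest, enhanced in lick trials.
    return {
        "VPM_like": ClassParams(wsi_mode="bipolar", wsi_range=(0.8, 1.0),
                                latency_mean=0.05, latency_jitter=0.01,
                                lick_transient_gain=3.0,
                                lick_gain_modulation=1.0, clustered=True),
        "POmFO_like": ClassParams(wsi_mode="bipolar", wsi_range=(0.3, 0.9),
                                  latency_mean=0.15, latency_jitter=0.02,
                                  lick_transient_gain=0.0,
                                  lick_gain_modulation=1.5, clustered=False),
        "POmHO_like": ClassParams(wsi_mode="central", wsi_sd=0.2,
                                  latency_mean=0.20, latency_jitter=0.03,
                                  lick_transient_gain=0.0,
                                  lick_gain_modulation=1.5, clustered=False),
    }


@dataclass
class PopulationConfig:
    """Layout and signal parameters of the synthetic axon population."""

    n_axons: int = 50
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"VPM_like": 0.4, "POmFO_like": 0.3,
                                 "POmHO_like": 0.3})
    class_params: Mapping[str, ClassParams] = field(
        default_factory=_default_class_params)
    field_shape: tuple[int, int] = (256, 256)
    cluster_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (64.0, 64.0), (192.0, 192.0))
    cluster_sd: float = 14.0
    n_segments_range: tuple[int, int] = (1, 3)
    pixels_per_segment_range: tuple[int, int] = (5, 30)
    noise_sd: float = 1.0
    within_axon_corr: float = 0.9
    neuropil_coeff_range: tuple[float, float] = (0.6, 0.8)
    neuropil_sd_frac: float = 0.3       # neuropil fluctuation SD / noise_sd
    baseline_offset_range: tuple[float, float] = (50.0, 150.0)
    drift_amplitude_range: tuple[float, float] = (0.5, 2.0)  # in noise-SD
    trial_gain_cv: float = 0.5          # lognormal per-trial response gain
    spont_event_rate: float = 0.02      # Hz, class-independent
    kernel_tau_rise: float = 0.18
    kernel_tau_decay: float = 1.8

    def __post_init__(self) -> None:
        if self.n_axons < 1:
            raise ConfigurationError("population must contain >= 1 axon")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigurationError("class proportions must sum to 1")
        for k in self.class_proportions:
            if k not in AXON_CLASSES:
                raise ConfigurationError(f"unknown axon class {k!r}")
        if not 0.0 < self.within_axon_corr < 1.0:
            raise ConfigurationError("within_axon_corr must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _build(cls, section: Mapping) -> object:
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(section) - known
    if bad:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    return cls(**section)


def load_config(path) -> tuple[SessionConfig, BehaviorConfig, PopulationConfig]:
    """Read a YAML/JSON config file with optional ``session``, ``behavior``
    and ``population`` sections; missing sections take package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    pop_raw = dict(raw.get("population", {}))
    if "class_params" in pop_raw:
        pop_raw["class_params"] = {
            name: _build(ClassParams, params)
            for name, params in pop_raw["class_params"].items()}
    for key in ("field_shape", "n_segments_range", "pixels_per_segment_range",
                "neuropil_coeff_range", "baseline_offset_range",
                "drift_amplitude_range"):
        if key in pop_raw:
            pop_raw[key] = tuple(pop_raw[key])
    if "cluster_centers" in pop_raw:
        pop_raw["cluster_centers"] = tuple(
            tuple(c) for c in pop_raw["cluster_centers"])
    return (_build(SessionConfig, raw.get("session", {})),
            _build(BehaviorConfig, raw.get("behavior", {})),
            _build(PopulationConfig, pop_raw))


def config_snapshot(cfg: SessionConfig, beh: BehaviorConfig,
                    pop: PopulationConfig) -> dict:
    """JSON-serializable snapshot of a full configuration (provenance)."""
    def as_dict(obj):
        d = dataclasses.asdict(obj)
        return d
    return {"session": as_dict(cfg), "behavior": as_dict(beh),
            "population": as_dict(pop)}
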