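"""Shared synthetic-session fixtures.

The heavyweight sessions are session-scoped so the forward model runs once:
a passive recovery session (tuning/latency ground-truth recovery), a
zero-selectivity power session (per-condition evoked amplitude exactly
5 noise-SD), and two behavioral single-class sessions used for the
population-level class contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pytest

import axoncal as ax
from axoncal import respstats, segmerge, tracenorm
from axoncal.config import ClassParams


@dataclass
class SessionBundle:
    cfg: ax.SessionConfig
    trials: pd.DataFrame
    truth: ax.GroundTruth
    segments: list
    merged: list
    tensors: list
    responses: list
    parent: dict = field(default_factory=dict)   # segment_id -> true axon id

    def spec_of(self, merged_axon) -> ax.AxonSpec:
        """Ground-truth spec of a merged axon (via its segments' parent)."""
        parents = {self.parent[i] for i in merged_axon.segment_ids}
        assert len(parents) == 1, "merged axon mixes ground-truth axons"
        return next(a for a in self.truth.axons if a.axon_id in parents)


def _analyze(cfg, trials, truth, segments) -> SessionBundle:
    partition = segmerge.correlation_cluster(segments)
    merged = segmerge.merge_segments(segments, partition)
    normalized = [tracenorm.normalize_trace(m) for m in merged]
    tensors = [tracenorm.trial_zscore(n, trials, cfg) for n in normalized]
    responses = [respstats.analyze_axon(t) for t in tensors]
    return SessionBundle(cfg=cfg, trials=trials, truth=truth,
                         segments=segments, merged=merged, tensors=tensors,
                         responses=responses,
                         parent={s.segment_id: s.parent_axon_id
                                 for s in segments})


PASSIVE = ax.BehaviorConfig(p_lick={"C2": 0.0, "B2": 0.0, "none": 0.0})


@pytest.fixture(scope="session")
def recovery_session() -> SessionBundle:
    """200 passive axons, default 5 noise-SD events, bimodal tuning, two
    latency classes (0.05 s vs 0.15 s); ~30 trials per condition."""
    cfg = ax.SessionConfig(n_trials=75, seed=0)
    pop = ax.PopulationConfig(
        n_axons=200,
        class_proportions={"VPM_like": 0.5, "POmFO_like": 0.5},
        class_params={
            "VPM_like": ClassParams(wsi_mode="bipolar", wsi_range=(0.3, 0.9),
                                    latency_mean=0.05, latency_jitter=0.0),
            "POmFO_like": ClassParams(wsi_mode="bipolar", wsi_range=(0.3, 0.9),
                                      latency_mean=0.15, latency_jitter=0.0)})
    trials, truth, segments = ax.generate_session(cfg, PASSIVE, pop, seed=101)
    return _analyze(cfg, trials, truth, segments)


@pytest.fixture(scope="session")
def power_session() -> SessionBundle:
    """100 passive axons with true WSI 0 and event amplitude 10, so each
    condition's evoked amplitude is exactly 5 noise-SD. Spontaneous events
    are disabled so the quiet-window null really is unit noise and the
    nominal amplitude-to-noise ratio holds exactly."""
    cfg = ax.SessionConfig(n_trials=75, seed=0)
    pop = ax.PopulationConfig(
        n_axons=100, class_proportions={"POmHO_like": 1.0},
        spont_event_rate=0.0,
        class_params={"POmHO_like": ClassParams(
            wsi_mode="bipolar", wsi_range=(0.0, 0.0), event_amplitude=10.0,
            latency_mean=0.1, latency_jitter=0.0)})
    trials, truth, segments = ax.generate_session(cfg, PASSIVE, pop, seed=102)
    return _analyze(cfg, trials, truth, segments)


def _behavioral(cls_name: str, n_axons: int, seed: int) -> SessionBundle:
    cfg = ax.SessionConfig(n_trials=200, seed=0)
    # reaction times start after the early analysis window so that early
    # whisker responses are uncontaminated by lick movement
    beh = ax.BehaviorConfig(rt_min=0.29)
    pop = ax.PopulationConfig(n_axons=n_axons,
                              class_proportions={cls_name: 1.0})
    trials, truth, segments = ax.generate_session(cfg, beh, pop, seed=seed)
    return _analyze(cfg, trials, truth, segments)


@pytest.fixture(scope="session")
def vpm_session() -> SessionBundle:
    """60 VPM-like axons: sharp tuning in two spatial clusters, short
    latency, lick-locked transients, no decision gain."""
    return _behavioral("VPM_like", 60, 21)


@pytest.fixture(scope="session")
def pomfo_session() -> SessionBundle:
    """100 POm-FO-like axons: intermingled, later, lick-enhanced evoked
    responses, no lick-locked transients."""
    return _behavioral("POmFO_like", 100, 22)
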