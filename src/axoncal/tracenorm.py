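"""Baseline estimation, noise normalization and trial z-scoring.

A slow-indicator fluorescence trace rides on a drifting baseline. Because
the transients are nonnegative, the signal mode tracks the baseline and the
fluctuations *below* it reflect pure noise. The pipeline here is:

1. estimate the mode piecewise in ~3000-frame segments (half-sample mode),
   fit a low-order polynomial through the per-segment modes, subtract;
2. estimate the noise SD from the distribution of negative residuals under
   a symmetric Gaussian noise model;
3. divide by the noise SD ("noise units");
4. per trial group (condition x lick), z-score against the pooled statistics
   of the 0.5 s quiet window immediately before the response window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SessionConfig
from .segmerge import MergedAxon

__all__ = ["NormalizedTrace", "GroupTensor", "TrialTensor",
           "half_sample_mode", "estimate_baseline", "estimate_noise_sd",
           "normalize_trace", "trial_zscore"]


def half_sample_mode(values: np.ndarray) -> float:
    """Robust mode: recursively keep the half-sample with the smallest range.

    Insensitive to sparse one-sided outliers (calcium transients), which is
    why it is used for the piecewise baseline.
    """
    y = np.sort(np.asarray(values, dtype=float).ravel())
    if y.size == 0:
        raise ValueError("empty sample")
    while y.size > 3:
        m = (y.size + 1) // 2
        ranges = y[m - 1:] - y[: y.size - m + 1]
        i = int(np.argmin(ranges))
        y = y[i:i + m]
    if y.size == 3:
        d01, d12 = y[1] - y[0], y[2] - y[1]
        if d01 < d12:
            return float(0.5 * (y[0] + y[1]))
        if d12 < d01:
            return float(0.5 * (y[1] + y[2]))
        return float(y[1])
    return float(y.mean())


def estimate_baseline(trace: np.ndarray, segment_length: int = 3000,
                      poly_order: int = 5) -> np.ndarray:
    """Slow baseline: per-segment mode values fit by a polynomial.

    The trace is cut into consecutive segments of roughly *segment_length*
    frames, the half-sample mode of each segment is computed, and a
    least-squares polynomial of order *poly_order* through the
    (segment center, mode) points is evaluated at every frame. Traces
    shorter than one segment collapse to a single segment; if there are
    fewer mode points than ``poly_order + 1`` the order is reduced with a
    warning.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if n == 0:
        raise ValueError("empty trace")
    n_seg = max(1, int(round(n / segment_length)))
    bounds = np.linspace(0, n, n_seg + 1).round().astype(int)
    centers = 0.5 * (bounds[:-1] + bounds[1:] - 1)
    modes = np.array([half_sample_mode(trace[a:b])
                      for a, b in zip(bounds[:-1], bounds[1:])])
    order = poly_order
    if len(modes) < order + 1:
        order = len(modes) - 1
        warnings.warn(
            f"only {len(modes)} baseline points; polynomial order reduced "
            f"to {order}", stacklevel=2)
    poly = np.polynomial.Polynomial.fit(centers, modes, order)
    return poly(np.arange(n, dtype=float))


def estimate_noise_sd(residual: np.ndarray) -> float:
    """Noise SD from fluctuations below the baseline.

    Under a centered Gaussian noise model the negatives are a half-normal
    sample with ``E[x^2] = sigma^2``, so the SD of the mirrored set
    ``{x, -x : x < 0}`` — the RMS of the negative residuals — estimates
    sigma without any contribution from positive-going transients.
    """
    residual = np.asarray(residual, dtype=float)
    neg = residual[residual < 0]
    if neg.size == 0:
        raise ValueError("no negative residuals; baseline looks degenerate")
    if neg.size < 100:
        warnings.warn(f"only {neg.size} negative residuals; noise estimate "
                      "may be unstable", stacklevel=2)
    return float(np.sqrt(np.mean(neg ** 2)))


@dataclass
class NormalizedTrace:
    axon_id: int
    baseline_curve: np.ndarray
    noise_sd: float
    normalized: np.ndarray     # (trace - baseline) / noise_sd


def normalize_trace(merged: MergedAxon, segment_length: int = 3000,
                    poly_order: int = 5) -> NormalizedTrace:
    """Baseline-subtract and noise-normalize one merged axon trace."""
    baseline = estimate_baseline(merged.merged_trace, segment_length,
                                 poly_order)
    residual = merged.merged_trace - baseline
    noise_sd = estimate_noise_sd(residual)
    return NormalizedTrace(axon_id=merged.axon_id, baseline_curve=baseline,
                           noise_sd=noise_sd, normalized=residual / noise_sd)


@dataclass
class GroupTensor:
    """Trial-aligned z-scored window for one (condition, lick) group."""
    z: np.ndarray               # (n_trials, n_bins)
    trial_index: np.ndarray     # session trial numbers, row order of `z`
    pre_mean: float
    pre_sd: float
    valid: bool


@dataclass
class TrialTensor:
    axon_id: int
    groups: dict[tuple[str, bool], GroupTensor]
    bin_period: float
    onset_index: int            # bin index of the alignment event
    pre_frames: int

    def times(self, key: tuple[str, bool] | None = None) -> np.ndarray:
        n_bins = next(iter(self.groups.values())).z.shape[1] if key is None \
            else self.groups[key].z.shape[1]
        return (np.arange(n_bins) - self.onset_index) * self.bin_period

    def group(self, condition: str, lick: bool) -> GroupTensor | None:
        g = self.groups.get((condition, lick))
        if g is not None and g.valid:
            return g
        return None


def trial_zscore(norm: NormalizedTrace, trials: pd.DataFrame,
                 cfg: SessionConfig, pre_window: float = 0.5,
                 align: str = "stimulus", align_pre: float = 1.0,
                 align_post: float = 3.0) -> TrialTensor:
    """Cut the normalized trace into trial-aligned, z-scored windows.

    Trials are grouped by (condition, lick). Within each group the samples
    of the quiet window ``pre_window`` seconds before the response-window
    onset are pooled over trials; their mean and SD z-score every bin of
    the group. With ``align="stimulus"`` windows run from ``-pre_window``
    to the trial end, anchored on stimulus onset. With ``align="first_lick"``
    (lick trials only) windows span ``[-align_pre, align_post)`` around the
    first lick while the z-scoring statistics still come from the
    pre-stimulus quiet window.
    """
    if align not in ("stimulus", "first_lick"):
        raise ValueError("align must be 'stimulus' or 'first_lick'")
    fr = cfg.frame_rate
    pre_frames = int(round(pre_window * fr))
    if pre_frames > cfg.stim_onset_frame_in_trial:
        raise ValueError("pre-window does not fit inside the quiet window")
    x = norm.normalized
    n_frames = x.size

    groups: dict[tuple[str, bool], GroupTensor] = {}
    for (condition, lick), sub in trials.groupby(["condition", "lick"],
                                                 sort=True):
        lick = bool(lick)
        if align == "first_lick" and not lick:
            continue
        onsets = sub["stim_onset_frame"].to_numpy(dtype=int)
        if align == "stimulus":
            anchors = onsets
            lo, hi = pre_frames, cfg.frames_per_trial - cfg.stim_onset_frame_in_trial
        else:
            rt_frames = np.round(sub["reaction_time_s"].to_numpy() * fr).astype(int)
            anchors = onsets + rt_frames
            lo, hi = int(round(align_pre * fr)), int(round(align_post * fr))
        ok = (anchors - lo >= 0) & (anchors + hi <= n_frames)
        anchors, onsets = anchors[ok], onsets[ok]
        trial_idx = sub["trial"].to_numpy()[ok]
        if anchors.size == 0:
            continue
        windows = np.stack([x[a - lo:a + hi] for a in anchors])
        pre = np.concatenate([x[o - pre_frames:o] for o in onsets])
        mu, sd = float(pre.mean()), float(pre.std(ddof=1))
        if sd == 0.0:
            warnings.warn(f"axon {norm.axon_id} group ({condition}, {lick}): "
                          "zero pre-window SD; group marked invalid",
                          stacklevel=2)
            groups[(condition, lick)] = GroupTensor(
                z=windows, trial_index=trial_idx, pre_mean=mu, pre_sd=0.0,
                valid=False)
            continue
        groups[(condition, lick)] = GroupTensor(
            z=(windows - mu) / sd, trial_index=trial_idx, pre_mean=mu,
            pre_sd=sd, valid=True)
    onset_index = pre_frames if align == "stimulus" else int(round(align_pre * fr))
    return TrialTensor(axon_id=norm.axon_id, groups=groups,
                       bin_period=1.0 / fr, onset_index=onset_index,
                       pre_frames=pre_frames)
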