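"""Single-trial response latency and its correlation with lick timing.

A slow calcium indicator smears event timing, so single-trial latency is
read from the *cumulative* signal: within a 3 s window starting at the
response-window onset, the latency is the time at which the running sum of
the (rectified) z-scored signal first reaches half of the window total.
When an axon's dominant response component is locked to the lick rather
than to the whisker stimulus, this latency co-varies with the first-lick
reaction time; the Pearson coefficient over non-rewarded (B2) lick trials
quantifies that coupling, and axons with p < 0.05 are flagged as
lick-time-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracenorm import NormalizedTrace, TrialTensor

__all__ = ["LickTimingResult", "cumulative_latency", "timing_correlation",
           "session_timing_correlations", "event_triggered_average"]


def cumulative_latency(trial_trace: np.ndarray, bin_period: float,
                       rectify: bool = True) -> float | None:
    """Time of the 50th percentile of the cumulative signal.

    *trial_trace* holds the z-scored bins of the analysis window (its first
    bin is the window onset). Negative values are floored at zero by
    default so the running sum is a valid cumulative mass; the latency is
    the time of the first bin whose running sum reaches half the total,
    ties resolved toward earlier bins. Returns None when the window holds
    no mass.
    """
    x = np.asarray(trial_trace, dtype=float)
    if rectify:
        x = np.maximum(x, 0.0)
    total = x.sum()
    if total <= 0.0:
        return None
    csum = np.cumsum(x)
    idx = int(np.searchsorted(csum, 0.5 * total))
    return idx * bin_period


@dataclass
class LickTimingResult:
    axon_id: int
    n_trials: int
    pearson_r: float
    p_value: float
    flagged: bool                # p < 0.05
    latencies: np.ndarray
    reaction_times: np.ndarray


def timing_correlation(latencies: np.ndarray, reaction_times: np.ndarray,
                       axon_id: int = -1, alpha: float = 0.05
                       ) -> LickTimingResult:
    """Pearson correlation between per-trial response latency and reaction
    time, with its two-sided p-value. Requires >= 3 finite pairs and
    nonzero variance in both vectors."""
    lat = np.asarray(latencies, dtype=float)
    rt = np.asarray(reaction_times, dtype=float)
    ok = np.isfinite(lat) & np.isfinite(rt)
    lat, rt = lat[ok], rt[ok]
    if lat.size < 3:
        raise ValueError("need at least 3 paired trials")
    if np.ptp(lat) == 0.0 or np.ptp(rt) == 0.0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(lat, rt)
    return LickTimingResult(axon_id=axon_id, n_trials=int(lat.size),
                            pearson_r=float(r), p_value=float(p),
                            flagged=bool(p < alpha), latencies=lat,
                            reaction_times=rt)


def session_timing_correlations(tensors: list[TrialTensor],
                                trials: pd.DataFrame, window: float = 3.0,
                                condition: str = "B2", rectify: bool = True
                                ) -> pd.DataFrame:
    """Per-axon lick-timing correlation over lick trials of *condition*.

    Uses the stimulus-aligned tensor group (condition, lick=True): each
    trial's cumulative-signal latency over ``window`` seconds from the
    response-window onset is paired with that trial's reaction time.
    Axons with fewer than 3 usable trials or degenerate variance are
    dropped. B2 is the default because licking on the non-rewarded whisker
    carries no reward-delivery confound and its lick pattern is homogeneous
    across trials.
    """
    rt_by_trial = trials.set_index("trial")["reaction_time_s"]
    rows = []
    for tensor in tensors:
        grp = tensor.group(condition, True)
        if grp is None:
            continue
        n_bins = int(round(window / tensor.bin_period))
        start = tensor.onset_index
        lat, rts = [], []
        for z_row, trial_no in zip(grp.z, grp.trial_index):
            seg = z_row[start:start + n_bins]
            if len(seg) < n_bins:
                continue
            t = cumulative_latency(seg, tensor.bin_period, rectify=rectify)
            if t is None:
                continue
            lat.append(t)
            rts.append(rt_by_trial.loc[trial_no])
        if len(lat) < 3 or np.ptp(lat) == 0.0 or np.ptp(rts) == 0.0:
            continue
        res = timing_correlation(np.array(lat), np.array(rts),
                                 axon_id=tensor.axon_id)
        rows.append({"axon_id": res.axon_id, "n_trials": res.n_trials,
                     "pearson_r": res.pearson_r, "p_value": res.p_value,
                     "flagged": res.flagged})
    return pd.DataFrame(rows, columns=["axon_id", "n_trials", "pearson_r",
                                       "p_value", "flagged"])


def event_triggered_average(norm: NormalizedTrace, event_times: np.ndarray,
                            frame_rate: float,
                            window: tuple[float, float] = (1.0, 3.0)
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean +/- s.e.m. of the normalized trace around event times.

    *window* is (t_pre, t_post) in seconds; events whose window leaves the
    session are dropped. Returns (times, mean, sem); empty arrays when no
    event is usable.
    """
    pre = int(round(window[0] * frame_rate))
    post = int(round(window[1] * frame_rate))
    frames = np.round(np.asarray(event_times, dtype=float) * frame_rate
                      ).astype(int)
    x = norm.normalized
    snippets = [x[f - pre:f + post] for f in frames
                if f - pre >= 0 and f + post <= x.size]
    if not snippets:
        return np.empty(0), np.empty(0), np.empty(0)
    mat = np.stack(snippets)
    times = (np.arange(-pre, post)) / frame_rate
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
        else np.full(mat.shape[1], np.nan)
    return times, mean, sem
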