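"""Evoked-response statistics on trial-aligned z-score tensors.

Each time bin is tested across trials with a one-sided z-test: because the
tensor values are noise-normalized and quiet-window z-scored, the null
distribution of the trial mean ``m`` over ``n`` trials is N(0, 1/n), so the
statistic is ``m sqrt(n)`` against the standard-normal upper tail. An axon's
response to a condition is significant when ``-log10(p)`` exceeds 10 in at
least three consecutive bins of the 2 s response window — a run criterion
matched to the slow indicator kinetics that suppresses isolated spurious
bins. Latency is the time of the first bin with ``-log10(p) > 5``.

The whisker-selectivity index compares windowed response amplitudes:
``WSI = (C2 - B2) / (C2 + B2)``, with negative amplitudes floored at zero so
the index stays in [-1, 1]; axons with ``|WSI| >= 0.75`` are "tuned".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracenorm import TrialTensor

__all__ = ["BinwiseTest", "GroupResult", "AxonResponse", "binwise_ztest",
           "detect_significance", "response_latency", "response_amplitude",
           "whisker_selectivity_index", "analyze_axon",
           "early_window_comparison"]

_LN10 = math.log(10.0)


@dataclass
class BinwiseTest:
    n: int
    mean: np.ndarray
    statistic: np.ndarray        # mean * sqrt(n)
    p: np.ndarray                # one-sided upper-tail
    neg_log10_p: np.ndarray


def binwise_ztest(tensor_slice: np.ndarray) -> BinwiseTest:
    """One-sided z-test of each time bin over trials (rows).

    ``neg_log10_p`` is computed through the log survival function so it
    stays exact far beyond float underflow of ``p`` itself.
    """
    z = np.asarray(tensor_slice, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a (trials >= 2, bins) matrix")
    n = z.shape[0]
    m = z.mean(axis=0)
    statistic = m * np.sqrt(n)
    return BinwiseTest(n=n, mean=m, statistic=statistic,
                       p=stats.norm.sf(statistic),
                       neg_log10_p=-stats.norm.logsf(statistic) / _LN10)


def detect_significance(bt: BinwiseTest, threshold: float = 10.0,
                        min_consecutive: int = 3,
                        window: slice | None = None) -> bool:
    """True iff >= `min_consecutive` consecutive bins exceed `threshold`."""
    nlp = bt.neg_log10_p if window is None else bt.neg_log10_p[window]
    run = 0
    for v in nlp:
        run = run + 1 if v > threshold else 0
        if run >= min_consecutive:
            return True
    return False


def response_latency(bt: BinwiseTest, onset_index: int, bin_period: float,
                     latency_threshold: float = 5.0,
                     window: slice | None = None) -> float:
    """Time (s, from the alignment event) of the first bin whose
    ``-log10(p)`` exceeds the latency threshold. Call only on responses
    that passed the significance criterion."""
    nlp = bt.neg_log10_p if window is None else bt.neg_log10_p[window]
    start = 0 if window is None or window.start is None else window.start
    hits = np.nonzero(nlp > latency_threshold)[0]
    if hits.size == 0:
        raise RuntimeError("significant response without a latency bin; "
                           "inconsistent thresholds")
    return float((start + hits[0] - onset_index) * bin_period)


def response_amplitude(tensor_slice: np.ndarray,
                       window: slice | None = None) -> float:
    """Mean z over trials and the bins of *window*."""
    z = np.asarray(tensor_slice, dtype=float)
    if window is not None:
        z = z[:, window]
    return float(z.mean())


def whisker_selectivity_index(amp_c2: float, amp_b2: float) -> float | None:
    """(C2 - B2)/(C2 + B2) on negative-floored amplitudes; None when both
    floored amplitudes vanish (index undefined)."""
    c2, b2 = max(amp_c2, 0.0), max(amp_b2, 0.0)
    if c2 + b2 == 0.0:
        return None
    return (c2 - b2) / (c2 + b2)


@dataclass
class GroupResult:
    n_trials: int
    significant: bool
    latency: float | None        # s; None unless significant
    amplitude_full: float        # mean z over the response window
    amplitude_early: float       # mean z over [0, early_window)


@dataclass
class AxonResponse:
    axon_id: int
    groups: dict[tuple[str, bool], GroupResult] = field(default_factory=dict)
    wsi: float | None = None         # from no-lick amplitudes
    wsi_lick: float | None = None    # from lick-trial amplitudes
    tuned: bool | None = None

    def sensory_significant(self) -> bool:
        """Whisker-responsive: significant to C2 and/or B2 without licking."""
        return any(self.groups[k].significant
                   for k in (("C2", False), ("B2", False)) if k in self.groups)


def analyze_axon(tensor: TrialTensor, response_window: float = 2.0,
                 early_window: float = 0.266, sig_threshold: float = 10.0,
                 min_consecutive: int = 3, latency_threshold: float = 5.0,
                 tuned_threshold: float = 0.75) -> AxonResponse:
    """Significance, latency, windowed amplitudes and WSI for one axon.

    Statistics are computed per (condition, lick) group; the headline WSI
    uses the no-lick C2 and B2 response-window amplitudes (responses in the
    absence of licking), and ``wsi_lick`` the lick-trial ones.
    """
    res = AxonResponse(axon_id=tensor.axon_id)
    onset = tensor.onset_index
    resp_bins = int(round(response_window / tensor.bin_period))
    early_bins = int(round(early_window / tensor.bin_period))
    win = slice(onset, onset + resp_bins)
    early = slice(onset, onset + early_bins)
    for key, grp in tensor.groups.items():
        if not grp.valid or grp.z.shape[0] < 2:
            continue
        bt = binwise_ztest(grp.z)
        significant = detect_significance(bt, sig_threshold, min_consecutive,
                                          window=win)
        latency = None
        if significant:
            latency = response_latency(bt, onset, tensor.bin_period,
                                       latency_threshold, window=win)
        res.groups[key] = GroupResult(
            n_trials=grp.z.shape[0], significant=significant, latency=latency,
            amplitude_full=response_amplitude(grp.z, win),
            amplitude_early=response_amplitude(grp.z, early))

    def _wsi(lick: bool) -> float | None:
        kc, kb = ("C2", lick), ("B2", lick)
        if kc in res.groups and kb in res.groups:
            return whisker_selectivity_index(
                res.groups[kc].amplitude_full, res.groups[kb].amplitude_full)
        return None

    res.wsi = _wsi(False)
    res.wsi_lick = _wsi(True)
    if res.wsi is not None:
        res.tuned = abs(res.wsi) >= tuned_threshold
    return res


def early_window_comparison(tensors: list[TrialTensor], condition: str = "C2",
                            early_window: float = 0.266,
                            normalize_to_no_lick: bool = False
                            ) -> tuple[pd.DataFrame, float]:
    """Population lick vs no-lick comparison of early response amplitudes.

    For every axon with both groups present, the mean z over
    ``[0, early_window)`` after stimulus onset is computed for lick and
    no-lick trials of *condition*; the population is compared with a paired
    two-sided Wilcoxon signed-rank test. An early window shorter than the
    typical reaction time isolates stimulus-evoked signal from
    lick-movement contributions. Returns the per-axon table and the
    Wilcoxon p-value (1.0 when all paired differences are zero).
    """
    rows = []
    for tensor in tensors:
        g_lick = tensor.group(condition, True)
        g_nolick = tensor.group(condition, False)
        if g_lick is None or g_nolick is None:
            continue
        onset = tensor.onset_index
        early = slice(onset, onset + int(round(early_window / tensor.bin_period)))
        a_lick = response_amplitude(g_lick.z, early)
        a_nolick = response_amplitude(g_nolick.z, early)
        if normalize_to_no_lick:
            if a_nolick == 0.0:
                continue
            a_lick, a_nolick = a_lick / a_nolick, 1.0
        rows.append({"axon_id": tensor.axon_id, "amp_early_lick": a_lick,
                     "amp_early_no_lick": a_nolick,
                     "difference": a_lick - a_nolick})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, float("nan")
    diffs = table["difference"].to_numpy()
    if np.allclose(diffs, 0.0):
        return table, 1.0
    _, p = stats.wilcoxon(table["amp_early_lick"], table["amp_early_no_lick"])
    return table, float(p)
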