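"""Merging of correlated axonal ROI segments and neuropil subtraction.

Axonal stretches of one cell can appear as several disconnected ROIs in a
field of view. Segments whose raw traces correlate above a threshold
(default 0.8) are grouped by single-linkage connected components and
averaged with pixel-count weights; the neuropil background is subtracted
with the same weights and each segment's coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synthgen import RoiSegment

__all__ = ["MergePartition", "MergedAxon", "correlation_cluster",
           "merge_segments"]


@dataclass
class MergePartition:
    """Disjoint grouping of segment ids into putative single axons."""
    clusters: dict[int, set[int]]             # axon_id -> segment ids
    correlation: np.ndarray                   # pairwise Pearson, included segs
    segment_ids: list[int]                    # row/col order of `correlation`
    excluded: list[int] = field(default_factory=list)  # zero-variance segments

    def label_of(self, segment_id: int) -> int:
        for axon_id, members in self.clusters.items():
            if segment_id in members:
                return axon_id
        raise KeyError(segment_id)


@dataclass
class MergedAxon:
    axon_id: int
    segment_ids: tuple[int, ...]
    pixel_mask: np.ndarray          # (n_pixels, 2), union of member masks
    merged_trace: np.ndarray        # pixel-weighted, neuropil-corrected
    total_pixels: int


def correlation_cluster(segments: list[RoiSegment], threshold: float = 0.8
                        ) -> MergePartition:
    """Partition segments into clusters of mutually reachable high correlation.

    Builds a graph with an edge wherever the Pearson correlation of two raw
    traces exceeds *threshold*, and takes connected components (single
    linkage). Segments with zero-variance traces have undefined correlation
    and are excluded with a warning.
    """
    if not segments:
        raise ValueError("need at least one segment")
    n_frames = len(segments[0].raw_trace)
    if n_frames < 2 or any(len(s.raw_trace) != n_frames for s in segments):
        raise ValueError("traces must share a common length >= 2")

    variances = np.array([np.var(s.raw_trace) for s in segments])
    excluded = [s.segment_id for s, v in zip(segments, variances) if v == 0.0]
    if excluded:
        warnings.warn(f"excluding {len(excluded)} zero-variance segment(s): "
                      f"{excluded}", stacklevel=2)
    kept = [s for s, v in zip(segments, variances) if v > 0.0]
    ids = [s.segment_id for s in kept]
    if not kept:
        return MergePartition(clusters={}, correlation=np.empty((0, 0)),
                              segment_ids=[], excluded=excluded)

    traces = np.stack([s.raw_trace for s in kept])
    corr = np.corrcoef(traces) if len(kept) > 1 else np.ones((1, 1))
    adj = corr > threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, set[int]] = {c: set() for c in range(n_comp)}
    for seg_id, lab in zip(ids, labels):
        clusters[int(lab)].add(seg_id)
    return MergePartition(clusters=clusters, correlation=corr,
                          segment_ids=ids, excluded=excluded)


def merge_segments(segments: list[RoiSegment], partition: MergePartition
                   ) -> list[MergedAxon]:
    """Combine each cluster into one axon trace.

    With weights ``w_i = pixels_i / sum(pixels)`` the merged raw trace is
    ``sum(w_i raw_i)`` and the merged neuropil is
    ``sum(w_i c_i neuropil_i)``; the returned trace is their difference.
    """
    by_id = {s.segment_id: s for s in segments}
    merged: list[MergedAxon] = []
    for axon_id in sorted(partition.clusters):
        members = sorted(partition.clusters[axon_id])
        if not members:
            raise RuntimeError(f"cluster {axon_id} is empty")
        segs = [by_id[i] for i in members]
        pixels = np.array([s.n_pixels for s in segs], dtype=float)
        w = pixels / pixels.sum()
        raw = sum(wi * s.raw_trace for wi, s in zip(w, segs))
        npil = sum(wi * s.neuropil_coefficient * s.neuropil_trace
                   for wi, s in zip(w, segs))
        mask = np.unique(np.concatenate([s.pixel_mask for s in segs]), axis=0)
        merged.append(MergedAxon(
            axon_id=axon_id, segment_ids=tuple(members),
            pixel_mask=mask, merged_trace=raw - npil,
            total_pixels=int(pixels.sum())))
    return merged
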