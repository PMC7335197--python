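"""HDF5 / CSV persistence for sessions and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .segmerge import MergedAxon
from .synthgen import GroundTruth, RoiSegment

TRIAL_COLUMNS = ["trial", "condition", "stim_onset_frame",
                 "stim_onset_time_s", "lick", "reaction_time_s", "outcome"]


def write_session(path, trials: pd.DataFrame, segments: list[RoiSegment],
                  truth: GroundTruth | None = None,
                  config: dict | None = None, seed: int | None = None
                  ) -> None:
    """Write one session (trial table, segment traces/masks, optional ground
    truth and config snapshot) into a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "axoncal-session-1"
        if config is not None:
            f.attrs["config_json"] = json.dumps(config)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        tg = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            data = trials[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            tg.create_dataset(col, data=data)
        sg = f.create_group("segments")
        for seg in segments:
            g = sg.create_group(f"seg{seg.segment_id:05d}")
            g.attrs["segment_id"] = seg.segment_id
            g.attrs["parent_axon_id"] = seg.parent_axon_id
            g.attrs["neuropil_coefficient"] = seg.neuropil_coefficient
            g.create_dataset("pixel_mask", data=seg.pixel_mask)
            g.create_dataset("raw_trace", data=seg.raw_trace)
            g.create_dataset("neuropil_trace", data=seg.neuropil_trace)
        if truth is not None:
            f.create_dataset("ground_truth_json", data=truth.to_json())


def read_session(path) -> tuple[pd.DataFrame, list[RoiSegment],
                                GroundTruth | None]:
    with h5py.File(path, "r") as f:
        cols = {}
        for col in TRIAL_COLUMNS:
            data = f["trials"][col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        trials = pd.DataFrame(cols)
        segments = []
        for name in sorted(f["segments"]):
            g = f["segments"][name]
            segments.append(RoiSegment(
                segment_id=int(g.attrs["segment_id"]),
                parent_axon_id=int(g.attrs["parent_axon_id"]),
                pixel_mask=g["pixel_mask"][()],
                raw_trace=g["raw_trace"][()],
                neuropil_trace=g["neuropil_trace"][()],
                neuropil_coefficient=float(g.attrs["neuropil_coefficient"])))
        truth = None
        if "ground_truth_json" in f:
            raw = f["ground_truth_json"][()]
            if isinstance(raw, bytes):
                raw = raw.decode()
            truth = GroundTruth.from_json(raw)
    return trials, segments, truth


def write_merged(path, merged: list[MergedAxon]) -> None:
    """Append merged-axon traces and membership to a session container."""
    with h5py.File(path, "a") as f:
        if "merged" in f:
            del f["merged"]
        mg = f.create_group("merged")
        for axon in merged:
            g = mg.create_group(f"axon{axon.axon_id:05d}")
            g.attrs["axon_id"] = axon.axon_id
            g.attrs["segment_ids"] = list(axon.segment_ids)
            g.attrs["total_pixels"] = axon.total_pixels
            g.create_dataset("pixel_mask", data=axon.pixel_mask)
            g.create_dataset("merged_trace", data=axon.merged_trace)


def read_merged(path) -> list[MergedAxon]:
    merged = []
    with h5py.File(path, "r") as f:
        for name in sorted(f["merged"]):
            g = f["merged"][name]
            merged.append(MergedAxon(
                axon_id=int(g.attrs["axon_id"]),
                segment_ids=tuple(int(i) for i in g.attrs["segment_ids"]),
                pixel_mask=g["pixel_mask"][()],
                merged_trace=g["merged_trace"][()],
                total_pixels=int(g.attrs["total_pixels"])))
    return merged


def write_table(path, table: pd.DataFrame, provenance: dict | None = None
                ) -> None:
    """CSV with ``# key: value`` provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {json.dumps(value) if not isinstance(value, str) else value}\n")
        table.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
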