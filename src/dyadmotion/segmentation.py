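"""Threshold-based movement/pause segmentation of kinetic-energy series.

A frame counts as "moving" when its energy exceeds 20% of the actor's
spike-robust mean energy for that body part; maximal runs of moving frames
become raw movement segments. Two cleaning rules follow, in this order:
movements separated by pauses shorter than 350 ms are merged, then
movements shorter than 350 ms are discarded (350 ms being a typical
reaction time to visual stimuli — shorter events would not read as
movements to a human observer). Boundary cases are strict: a gap or
movement of exactly 350 ms survives.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .kinetics import EnergySeries

MIN_GAP_S = 0.35
MIN_DURATION_S = 0.35
THRESHOLD_FRACTION = 0.20
SPIKE_PERCENTILE = 99.0


class SegmentationError(ValueError):
    pass


@dataclasses.dataclass
class MovementSegmentList:
    """Sorted, disjoint half-open movement intervals ``[on_s, off_s)``.

    ``window`` is the half-open analysis window in seconds; all segments lie
    within it. After cleaning, every segment and every inter-segment gap is
    at least 350 ms.
    """

    role: str
    body_part: str
    window: tuple[float, float]
    segments: np.ndarray  # (n, 2) float seconds

    def __post_init__(self) -> None:
        seg = np.asarray(self.segments, dtype=float).reshape(-1, 2)
        self.segments = seg
        self.window = (float(self.window[0]), float(self.window[1]))
        if self.window[1] <= self.window[0]:
            raise SegmentationError("window must have positive length")
        if seg.size:
            if (seg[:, 1] <= seg[:, 0]).any():
                raise SegmentationError("segments must have positive duration")
            if (np.diff(seg[:, 0]) <= 0).any() or (seg[1:, 0] < seg[:-1, 1]).any():
                raise SegmentationError("segments must be sorted and disjoint")
            tol = 1e-9
            if seg[0, 0] < self.window[0] - tol or seg[-1, 1] > self.window[1] + tol:
                raise SegmentationError("segments must lie within the window")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def onsets(self) -> np.ndarray:
        return self.segments[:, 0]

    @property
    def offsets(self) -> np.ndarray:
        return self.segments[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.segments[:, 1] - self.segments[:, 0]

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())

    def replace(self, segments: np.ndarray) -> "MovementSegmentList":
        return MovementSegmentList(self.role, self.body_part, self.window, segments)

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "role": self.role,
                "body_part": self.body_part,
                "window": list(self.window),
                "segments": [[round(a, 6), round(b, 6)] for a, b in self.segments],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MovementSegmentList":
        d = json.loads(text)
        return cls(d["role"], d["body_part"], tuple(d["window"]), np.array(d["segments"]).reshape(-1, 2))

    def to_bed(self, path: str | Path, mode: str = "a") -> None:
        """Append BED-like tab-separated lines: actor, body_part, on_s, off_s."""
        with open(path, mode) as fh:
            for on, off in self.segments:
                fh.write(f"{self.role}\t{self.body_part}\t{on:.6f}\t{off:.6f}\n")


def robust_mean_energy(energy: EnergySeries | np.ndarray, spike_percentile: float = SPIKE_PERCENTILE) -> float:
    """Mean energy after removing sparse spikes from impulsive movements.

    Spikes would bias a plain mean upward; they are excluded by dropping
    samples above the ``spike_percentile``-th percentile (100 keeps all,
    recovering the plain arithmetic mean).
    """
    e = energy.energy if isinstance(energy, EnergySeries) else np.asarray(energy, dtype=float)
    if e.size == 0:
        raise SegmentationError("robust_mean_energy: empty energy series")
    if not 0 < spike_percentile <= 100:
        raise SegmentationError("spike_percentile must be in (0, 100]")
    cut = np.percentile(e, spike_percentile)
    return float(e[e <= cut].mean())


def threshold_segment(
    E: EnergySeries,
    threshold_fraction: float = THRESHOLD_FRACTION,
    spike_percentile: float = SPIKE_PERCENTILE,
) -> MovementSegmentList:
    """Raw segmentation: frames with energy strictly above the threshold.

    The threshold is ``threshold_fraction`` (default 20%) of the actor's own
    spike-robust mean energy, so scaling the energy series leaves the
    segmentation unchanged. Spikes, lying above the threshold by definition,
    stay inside movement segments. A series with zero robust mean is
    all-silent and yields an empty list.
    """
    fs = E.sampling_rate_hz
    window = (E.t0, E.t0 + E.n_frames / fs)
    mean = robust_mean_energy(E, spike_percentile)
    if mean <= 0:
        return MovementSegmentList(E.role, E.body_part, window, np.empty((0, 2)))
    moving = E.energy > threshold_fraction * mean
    padded = np.concatenate(([False], moving, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    segments = np.column_stack([E.t0 + starts / fs, E.t0 + stops / fs])
    return MovementSegmentList(E.role, E.body_part, window, segments)


def merge_short_pauses(raw: MovementSegmentList, min_gap_s: float = MIN_GAP_S) -> MovementSegmentList:
    """Merge movements separated by pauses shorter than ``min_gap_s``.

    Gaps are closed left to right, so a chain of short gaps collapses into a
    single movement; exactly-``min_gap_s`` gaps are kept (strict "shorter
    than"). Idempotent.
    """
    seg = raw.segments
    if len(seg) < 2:
        return raw.replace(seg.copy())
    merged = [seg[0].tolist()]
    for on, off in seg[1:]:
        if on - merged[-1][1] < min_gap_s:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    return raw.replace(np.array(merged))


def discard_short_movements(
    merged: MovementSegmentList, min_dur_s: float = MIN_DURATION_S
) -> MovementSegmentList:
    """Discard movements shorter than ``min_dur_s`` (strict; 350 ms kept)."""
    seg = merged.segments
    keep = (seg[:, 1] - seg[:, 0]) >= min_dur_s if seg.size else np.zeros(0, bool)
    return merged.replace(seg[keep])


def segment_movements(
    E: EnergySeries,
    threshold_fraction: float = THRESHOLD_FRACTION,
    spike_percentile: float = SPIKE_PERCENTILE,
    min_gap_s: float = MIN_GAP_S,
    min_dur_s: float = MIN_DURATION_S,
) -> MovementSegmentList:
    """Full pipeline: threshold, merge short pauses, discard short movements."""
    raw = threshold_segment(E, threshold_fraction, spike_percentile)
    return discard_short_movements(merge_short_pauses(raw, min_gap_s), min_dur_s)
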