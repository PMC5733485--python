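"""Marker-trajectory I/O and pre-processing.

Reads tab-separated marker-position exports (one row per frame, X/Y/Z
columns per marker), trims recordings to the rated interaction window,
enforces the missing-data policy with linear interpolation, and applies a
zero-phase Butterworth low-pass before differentiation.

Conventions
-----------
* Positions are stored in metres internally; files may be in millimetres
  (optical-capture default) with an explicit ``unit`` flag.
* Time is in seconds. Frame ``i`` covers the half-open interval
  ``[t0 + i/fs, t0 + (i+1)/fs)``.
* Missing samples are carried in a per-marker boolean validity mask; the
  5% missing-data rule is enforced per marker over the trimmed window.
"""

from __future__ import annotations

import dataclasses
import io
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal


class MocapIOError(ValueError):
    """Malformed marker file or invalid pre-processing request."""


class ExcessMissingDataError(MocapIOError):
    """A marker exceeds the allowed missing-data fraction; the dyad is discarded.

    Attributes
    ----------
    marker : str
        Label of the offending marker.
    missing_fraction : float
        Fraction of the window for which the marker is invalid.
    """

    def __init__(self, marker: str, missing_fraction: float, limit: float):
        self.marker = marker
        self.missing_fraction = missing_fraction
        self.limit = limit
        super().__init__(
            f"marker {marker!r} missing {missing_fraction:.1%} of the window "
            f"(limit {limit:.1%}); interaction discarded"
        )


@dataclasses.dataclass
class MarkerTimeSeries:
    """Uniformly sampled 3-D positions for one actor's marker set.

    Parameters
    ----------
    sampling_rate_hz : float
        Capture rate (the study system ran at 240 Hz).
    labels : list of str
        Marker labels; ``positions[:, j]`` belongs to ``labels[j]``.
    positions : ndarray, shape (n_frames, n_markers, 3)
        Marker coordinates in metres. Invalid entries may hold NaN.
    validity : ndarray of bool, shape (n_frames, n_markers)
        True where the marker was tracked.
    t0 : float
        Time of the first frame relative to the recording start, seconds.
    """

    sampling_rate_hz: float
    labels: list[str]
    positions: np.ndarray
    validity: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.sampling_rate_hz <= 0:
            raise MocapIOError("sampling_rate_hz must be positive")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise MocapIOError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise MocapIOError("positions second axis must match number of labels")
        if self.validity.shape != self.positions.shape[:2]:
            raise MocapIOError("validity must have shape (n_frames, n_markers)")
        if not np.isfinite(self.positions[self.validity]).all():
            raise MocapIOError("valid positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.sampling_rate_hz

    def marker_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MocapIOError(f"unknown marker label {label!r}") from None

    def marker(self, label: str) -> np.ndarray:
        """Return the (n_frames, 3) trajectory for one marker."""
        return self.positions[:, self.marker_index(label), :]

    def copy(self) -> "MarkerTimeSeries":
        return MarkerTimeSeries(
            sampling_rate_hz=self.sampling_rate_hz,
            labels=list(self.labels),
            positions=self.positions.copy(),
            validity=self.validity.copy(),
            t0=self.t0,
        )


_UNIT_SCALE = {"mm": 1e-3, "m": 1.0}
_COORD_SUFFIX = re.compile(r"^(?P<label>.+)_(?P<axis>[XYZ])$")


def read_marker_tsv(
    path: str | Path | io.TextIOBase,
    sampling_rate_hz: float,
    unit: str = "mm",
    zero_is_missing: bool = False,
) -> MarkerTimeSeries:
    """Read a tab-separated marker file into a :class:`MarkerTimeSeries`.

    Expected dialect: optional comment/metadata lines starting with ``#``,
    then a header row ``frame  time  <label>_X  <label>_Y  <label>_Z ...``,
    then one tab-separated row per frame. Empty or unparseable cells (and,
    with ``zero_is_missing``, exact 0-filled samples) are marked invalid.
    """
    if unit not in _UNIT_SCALE:
        raise MocapIOError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_SCALE)}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MocapIOError(f"malformed marker file: {exc}") from exc
    cols = list(df.columns)
    coord_cols = [c for c in cols if c not in ("frame", "time")]
    labels: list[str] = []
    for c in coord_cols:
        m = _COORD_SUFFIX.match(c)
        if m is None:
            raise MocapIOError(
                f"malformed header: column {c!r} is not of the form <label>_X/Y/Z (header line 1)"
            )
        if m.group("label") not in labels:
            labels.append(m.group("label"))
    expected = [f"{lab}_{ax}" for lab in labels for ax in "XYZ"]
    if coord_cols != expected:
        raise MocapIOError(
            "malformed header: coordinate columns must come as contiguous "
            f"<label>_X, <label>_Y, <label>_Z triples; got {coord_cols}"
        )
    values = df[expected].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    n_frames = values.shape[0]
    positions = values.reshape(n_frames, len(labels), 3) * _UNIT_SCALE[unit]
    validity = np.isfinite(positions).all(axis=2)
    if zero_is_missing:
        validity &= ~(positions == 0.0).all(axis=2)
    positions[~validity] = np.nan
    return MarkerTimeSeries(
        sampling_rate_hz=sampling_rate_hz,
        labels=labels,
        positions=positions,
        validity=validity,
        t0=0.0,
    )


def write_marker_tsv(mts: MarkerTimeSeries, path: str | Path, unit: str = "mm") -> None:
    """Write the TSV dialect read by :func:`read_marker_tsv` (invalid cells empty)."""
    if unit not in _UNIT_SCALE:
        raise MocapIOError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_SCALE)}")
    scale = 1.0 / _UNIT_SCALE[unit]
    cols: dict[str, object] = {
        "frame": np.arange(mts.n_frames),
        "time": mts.times,
    }
    for j, lab in enumerate(mts.labels):
        for k, ax in enumerate("XYZ"):
            col = mts.positions[:, j, k] * scale
            col = np.where(mts.validity[:, j], col, np.nan)
            cols[f"{lab}_{ax}"] = col
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="", float_format="%.9f")


def trim_to_window(mts: MarkerTimeSeries, start_s: float, duration_s: float) -> MarkerTimeSeries:
    """Trim to the rated window ``[start_s, start_s + duration_s)`` (frame-aligned).

    The study rated interactions from 2 min onward, for 3 min at 4 months
    and 5 min at 13 months; those windows are encoded in the run config.
    """
    if duration_s <= 0:
        raise MocapIOError("duration_s must be positive")
    fs = mts.sampling_rate_hz
    i0 = int(round((start_s - mts.t0) * fs))
    n = int(round(duration_s * fs))
    if i0 < 0 or i0 + n > mts.n_frames:
        raise MocapIOError(
            f"window [{start_s}, {start_s + duration_s}) s exceeds the recording "
            f"([{mts.t0}, {mts.t0 + mts.duration_s}) s)"
        )
    return MarkerTimeSeries(
        sampling_rate_hz=fs,
        labels=list(mts.labels),
        positions=mts.positions[i0 : i0 + n].copy(),
        validity=mts.validity[i0 : i0 + n].copy(),
        t0=mts.t0 + i0 / fs,
    )


def interpolate_missing(
    mts: MarkerTimeSeries, max_missing_fraction: float = 0.05
) -> MarkerTimeSeries:
    """Fill missing runs by per-coordinate linear interpolation.

    For every marker the total invalid time must be below
    ``max_missing_fraction`` of the window, otherwise the series is rejected
    (:class:`ExcessMissingDataError`) and the dyad is discarded — the 5% rule.
    Edge runs, which lack a flanking anchor on one side, are filled by
    holding the nearest valid sample.
    """
    if not 0 < max_missing_fraction <= 1:
        raise MocapIOError("max_missing_fraction must be in (0, 1]")
    out = mts.copy()
    n = mts.n_frames
    for j, lab in enumerate(mts.labels):
        valid = mts.validity[:, j]
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ExcessMissingDataError(lab, 1.0, max_missing_fraction)
        frac = 1.0 - n_valid / n
        if frac >= max_missing_fraction:
            raise ExcessMissingDataError(lab, frac, max_missing_fraction)
        if n_valid == n:
            continue
        idx = np.arange(n)
        vi = idx[valid]
        for k in range(3):
            # np.interp holds the nearest valid value beyond the anchors,
            # which implements the edge-run policy for free.
            out.positions[:, j, k] = np.interp(idx, vi, mts.positions[vi, j, k])
        out.validity[:, j] = True
    return out


def lowpass_filter(
    mts: MarkerTimeSeries, order: int = 4, cutoff_hz: float = 10.0
) -> MarkerTimeSeries:
    """Zero-phase Butterworth low-pass of each coordinate.

    The filter is applied forward-backward (``filtfilt``), so movement
    onsets are not delayed by phase lag; the effective magnitude response is
    the squared single-pass Butterworth response.
    """
    nyquist = mts.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise MocapIOError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    if not mts.validity.all():
        raise MocapIOError("lowpass_filter requires a fully valid series; interpolate first")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=mts.sampling_rate_hz, output="sos")
    out = mts.copy()
    flat = out.positions.reshape(out.n_frames, -1)
    out.positions = signal.sosfiltfilt(sos, flat, axis=0).reshape(out.positions.shape)
    return out


def butterworth_amplitude_ratio(freq_hz: float, order: int = 4, cutoff_hz: float = 10.0) -> float:
    """Closed-form zero-phase (squared) Butterworth magnitude at ``freq_hz``.

    Single-pass magnitude is ``1/sqrt(1 + (f/fc)^(2*order))``; the
    forward-backward filter applies it twice.
    """
    return 1.0 / (1.0 + (freq_hz / cutoff_hz) ** (2 * order))
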