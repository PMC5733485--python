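"""Synthetic dyadic motion-capture data with constructive ground truth.

Real mother-infant recordings of the kind this package analyses (240 Hz
optical capture of head/wrist/elbow/shoulder markers) are rarely shareable,
so every downstream stage is exercised against a generator that plants the
structure the pipeline is supposed to recover:

* each actor alternates movement episodes and pauses (a renewal process),
  with all planted durations and gaps >= 0.5 s so the ground truth survives
  the 350 ms merge/discard cleaning unchanged;
* during an episode all of an actor's markers translate together at a
  constant per-episode speed (piecewise-linear position). A constant-speed
  plateau keeps the kinetic energy unambiguously above the 20% threshold
  for the whole episode and confines threshold-crossing errors to a single
  sample at the true onset/offset, which is what makes exact
  segmentation-recovery checks possible;
* infant movement onsets are optionally re-timed to the mother's episodes
  to plant coactive (onset while mother moves, within the response window
  of her onset), alternating (onset while mother is still, within the
  window of her offset) or independent (explicitly violating both
  definitions) coordination labels — constructive, not inferred;
* additive Gaussian sensor noise, sparse single-sample position spikes
  during movement (impulsive movements), and contiguous missing runs
  (optical occlusion) can be layered on top.

Cohorts for end-to-end correlation recovery sweep one generative parameter
monotonically across dyads and attach a synthetic rating composite coupled
to it through a Gaussian copula, so a target population Spearman
correlation can be planted and recovered through the full pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mocap_io import MarkerTimeSeries
from .segmentation import MovementSegmentList

COUPLING_LABELS = ("coactive", "alternating", "independent")

#: Default marker layout per actor (matches the study's head/wrist/elbow/
#: shoulder set; base offsets are rough anatomical positions in metres).
DEFAULT_MARKER_BASES = {
    "head": (0.0, 0.0, 0.60),
    "wrist_l": (-0.30, 0.25, 0.10),
    "wrist_r": (0.30, 0.25, 0.10),
    "elbow_l": (-0.25, 0.10, 0.25),
    "elbow_r": (0.25, 0.10, 0.25),
    "shoulder_l": (-0.18, 0.0, 0.45),
    "shoulder_r": (0.18, 0.0, 0.45),
}

_END_MARGIN_S = 0.1  # keep planted events clear of the window edge
_MIN_GAP_S = 0.5  # planted gaps/durations stay >= 0.5 s (> 350 ms rule)
_SAFETY_S = 0.1  # slack protecting labels from 1-sample boundary errors


class SyntheticSpecError(ValueError):
    """Invalid generator specification; the message names the offending field."""


@dataclasses.dataclass
class SyntheticDyadSpec:
    """Parameters of one synthetic dyad.

    Episode durations are ``min_duration_s + Exponential(mean - min)``; each
    episode translates the markers at a constant speed drawn uniformly from
    ``[speed_min_mps, speed_max_mps]`` (per-episode displacement amplitude =
    speed x duration). Coupling probabilities ``p_co``/``p_alt`` give the
    fraction of infant movements planted as coactive/alternating, with
    latencies uniform on ``[latency_min_s, latency_max_s]`` (bounded by the
    1.5 s response window); the remainder are planted independent, i.e.
    deliberately violating both onset definitions. Explicit
    ``mother_episodes`` / ``infant_episodes`` (lists of ``(on, off)``
    seconds) override the random schedules; labels are then derived from the
    definitions.
    """

    duration_s: float = 300.0
    sampling_rate_hz: float = 240.0
    seed: int = 0
    # movement-episode model
    movement_mean_s: float = 1.5
    pause_mean_s: float = 2.0
    min_duration_s: float = 0.5
    speed_min_mps: float = 0.10
    speed_max_mps: float = 0.20
    # coupling model
    p_co: float = 0.0
    p_alt: float = 0.0
    latency_min_s: float = 0.1
    latency_max_s: float = 1.4
    # degradations
    noise_sd_m: float = 0.0003
    spike_rate_per_min: float = 0.0
    spike_amplitude_multiplier: float = 60.0
    missing_fraction: float = 0.0
    missing_run_length_s: float = 0.5
    # explicit schedules (override the renewal/coupling models)
    mother_episodes: Sequence[tuple[float, float]] | None = None
    infant_episodes: Sequence[tuple[float, float]] | None = None

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise SyntheticSpecError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise SyntheticSpecError("sampling_rate_hz must be positive")
        if self.min_duration_s < 0.5:
            raise SyntheticSpecError(
                "min_duration_s must be >= 0.5 s so ground truth survives the 350 ms cleaning"
            )
        for field in ("movement_mean_s", "pause_mean_s"):
            if getattr(self, field) < self.min_duration_s:
                raise SyntheticSpecError(f"{field} must be >= min_duration_s")
        if not 0 < self.speed_min_mps <= self.speed_max_mps:
            raise SyntheticSpecError("require 0 < speed_min_mps <= speed_max_mps")
        if self.p_co < 0 or self.p_alt < 0 or self.p_co + self.p_alt > 1 + 1e-12:
            raise SyntheticSpecError("p_co and p_alt must be >= 0 with p_co + p_alt <= 1")
        if not 0 < self.latency_min_s <= self.latency_max_s <= 1.5:
            raise SyntheticSpecError(
                "latency bounds must satisfy 0 < latency_min_s <= latency_max_s <= 1.5 (response window)"
            )
        if self.noise_sd_m < 0:
            raise SyntheticSpecError("noise_sd_m must be >= 0")
        if self.spike_rate_per_min < 0:
            raise SyntheticSpecError("spike_rate_per_min must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise SyntheticSpecError("missing_fraction must be in [0, 1)")
        if self.missing_run_length_s <= 0:
            raise SyntheticSpecError("missing_run_length_s must be positive")


@dataclasses.dataclass
class GroundTruth:
    """Planted movement intervals and infant coupling labels for one dyad.

    All of an actor's markers move together, so the true intervals are the
    same for every body part; :meth:`segment_list` exposes them per actor x
    body part in the segmentation module's container.
    """

    duration_s: float
    mother_segments: np.ndarray  # (n, 2) seconds, sorted, disjoint
    infant_segments: np.ndarray
    infant_labels: list[str]  # one of COUPLING_LABELS per infant movement
    infant_latencies: np.ndarray  # seconds; NaN for independent movements

    def segment_list(self, role: str, body_part: str = "upper_body") -> MovementSegmentList:
        seg = {"mother": self.mother_segments, "infant": self.infant_segments}[role]
        return MovementSegmentList(
            role=role, body_part=body_part, window=(0.0, self.duration_s), segments=seg.copy()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "duration_s": self.duration_s,
                "mother_segments": np.asarray(self.mother_segments).tolist(),
                "infant_segments": np.asarray(self.infant_segments).tolist(),
                "infant_labels": list(self.infant_labels),
                "infant_latencies": [
                    None if math.isnan(v) else v for v in np.asarray(self.infant_latencies)
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            duration_s=d["duration_s"],
            mother_segments=np.array(d["mother_segments"], dtype=float).reshape(-1, 2),
            infant_segments=np.array(d["infant_segments"], dtype=float).reshape(-1, 2),
            infant_labels=list(d["infant_labels"]),
            infant_latencies=np.array(
                [math.nan if v is None else v for v in d["infant_latencies"]], dtype=float
            ),
        )


@dataclasses.dataclass
class _Episode:
    onset: float
    offset: float
    speed: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def _draw_duration(spec: SyntheticDyadSpec, mean_s: float, rng: np.random.Generator) -> float:
    return spec.min_duration_s + rng.exponential(mean_s - spec.min_duration_s) \
        if mean_s > spec.min_duration_s else spec.min_duration_s


def _renewal_schedule(spec: SyntheticDyadSpec, rng: np.random.Generator) -> list[_Episode]:
    episodes: list[_Episode] = []
    t = _draw_duration(spec, spec.pause_mean_s, rng)
    horizon = spec.duration_s - _END_MARGIN_S
    while True:
        dur = _draw_duration(spec, spec.movement_mean_s, rng)
        if t + dur > horizon:
            break
        episodes.append(_Episode(t, t + dur, rng.uniform(spec.speed_min_mps, spec.speed_max_mps)))
        t = t + dur + _draw_duration(spec, spec.pause_mean_s, rng)
    return episodes


def _coupled_schedule(
    spec: SyntheticDyadSpec,
    rng: np.random.Generator,
    mother: list[_Episode],
) -> tuple[list[_Episode], list[str], list[float]]:
    """Place infant movements episode-slot by episode-slot against the mother's.

    Coactive onsets land inside a mother episode within the latency window of
    its onset; alternating onsets land in a mother pause within the window of
    the preceding offset; independent onsets are placed to violate both
    definitions (inside an episode but > 1.5 s after its onset, or in a pause
    > 1.5 s after the preceding offset, or before the mother's first
    movement). If a drawn label cannot be hosted near the current position,
    later mother episodes are tried before giving up (window exhausted).
    """
    D = spec.duration_s
    horizon = D - _END_MARGIN_S
    m_on = np.array([e.onset for e in mother])
    m_off = np.array([e.offset for e in mother])
    n_m = len(mother)

    episodes: list[_Episode] = []
    labels: list[str] = []
    latencies: list[float] = []
    prev_off = -1.0  # no previous infant movement

    def draw_label() -> str:
        u = rng.uniform()
        if u < spec.p_co:
            return "coactive"
        if u < spec.p_co + spec.p_alt:
            return "alternating"
        return "independent"

    while True:
        dur = _draw_duration(spec, spec.movement_mean_s, rng)
        label = draw_label()
        placed: float | None = None
        latency = math.nan
        min_onset = max(prev_off + _MIN_GAP_S, _SAFETY_S)

        if label == "independent" and n_m:
            # region before the mother's first movement: no preceding offset,
            # mother still -> neither coactive nor alternating.
            lo, hi = min_onset, m_on[0] - _SAFETY_S - dur
            if hi >= lo:
                placed = rng.uniform(lo, hi)

        for i in range(n_m):
            if placed is not None:
                break
            gap_end = m_on[i + 1] if i + 1 < n_m else D
            if label == "coactive":
                lo = max(spec.latency_min_s, min_onset - m_on[i])
                hi = min(
                    spec.latency_max_s,
                    mother[i].duration - _SAFETY_S,
                    horizon - dur - m_on[i],
                )
                if hi >= lo:
                    latency = rng.uniform(lo, hi)
                    placed = m_on[i] + latency
            elif label == "alternating":
                lo = max(spec.latency_min_s, min_onset - m_off[i])
                hi = min(
                    spec.latency_max_s,
                    gap_end - _SAFETY_S - m_off[i],
                    horizon - dur - m_off[i],
                )
                if hi >= lo:
                    latency = rng.uniform(lo, hi)
                    placed = m_off[i] + latency
            else:
                # inside episode i, beyond the response window of its onset
                lo = max(1.5 + _SAFETY_S, min_onset - m_on[i])
                hi = min(mother[i].duration - _SAFETY_S, horizon - dur - m_on[i])
                if hi >= lo:
                    placed = m_on[i] + rng.uniform(lo, hi)
                else:
                    # in the pause after episode i, beyond the window of its offset
                    lo = max(1.5 + _SAFETY_S, min_onset - m_off[i])
                    hi = min(gap_end - _SAFETY_S - m_off[i], horizon - dur - m_off[i])
                    if hi >= lo:
                        placed = m_off[i] + rng.uniform(lo, hi)

        if placed is None:
            break
        episodes.append(
            _Episode(placed, placed + dur, rng.uniform(spec.speed_min_mps, spec.speed_max_mps))
        )
        labels.append(label)
        latencies.append(latency)
        prev_off = placed + dur
    return episodes, labels, latencies


def classify_onsets(
    infant_segments: np.ndarray,
    mother_segments: np.ndarray,
    window_s: float = 1.5,
) -> list[str]:
    """Label each infant onset by exhaustive check of the onset definitions."""
    mother_segments = np.asarray(mother_segments, dtype=float).reshape(-1, 2)
    labels = []
    for t_on in np.asarray(infant_segments, dtype=float).reshape(-1, 2)[:, 0]:
        containing = [
            (on, off) for on, off in mother_segments if on <= t_on < off
        ]
        if containing:
            on = containing[0][0]
            labels.append("coactive" if t_on - on <= window_s else "independent")
            continue
        prior_offs = mother_segments[mother_segments[:, 1] <= t_on, 1]
        if prior_offs.size and t_on - prior_offs.max() <= window_s:
            labels.append("alternating")
        else:
            labels.append("independent")
    return labels


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_actor(
    spec: SyntheticDyadSpec,
    episodes: list[_Episode],
    rng: np.random.Generator,
    base_offset: tuple[float, float, float],
) -> MarkerTimeSeries:
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    disp = np.zeros((n, 3))
    for ep in episodes:
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        advance = np.clip(t - ep.onset, 0.0, ep.duration)
        disp += np.outer(advance, ep.speed * u)

    labels = list(DEFAULT_MARKER_BASES)
    positions = np.empty((n, len(labels), 3))
    for j, lab in enumerate(labels):
        base = np.asarray(DEFAULT_MARKER_BASES[lab]) + np.asarray(base_offset)
        positions[:, j, :] = base + disp
    if spec.noise_sd_m > 0:
        positions += rng.normal(0.0, spec.noise_sd_m, size=positions.shape)

    # sparse single-sample spikes from impulsive movements (inside episodes)
    n_spikes = rng.poisson(spec.spike_rate_per_min * spec.duration_s / 60.0)
    if n_spikes and episodes:
        jump = spec.spike_amplitude_multiplier * spec.speed_max_mps / fs
        for _ in range(n_spikes):
            ep = episodes[rng.integers(len(episodes))]
            lo = ep.onset + _SAFETY_S
            hi = ep.offset - _SAFETY_S
            if hi <= lo:
                continue
            frame = int(rng.uniform(lo, hi) * fs)
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            positions[frame] += jump * u

    mts = MarkerTimeSeries(
        sampling_rate_hz=fs,
        labels=labels,
        positions=positions,
        validity=np.ones((n, len(labels)), dtype=bool),
        t0=0.0,
    )
    if spec.missing_fraction > 0:
        mts = inject_missing(
            mts,
            spec.missing_fraction,
            spec.missing_run_length_s,
            seed=int(rng.integers(2**31)),
        )
    return mts


def _snap_to_grid(episodes: list[_Episode], fs: float) -> list[_Episode]:
    """Align episode boundaries with the sample grid.

    Ground-truth event times are stated on the capture frame grid, so that
    discrete differentiation sees the speed change exactly at a sample
    instant and threshold crossings land within one sample of the truth.
    Snapping moves each boundary by at most half a sample (~2 ms at 240 Hz),
    well inside the coupling-label safety margins.
    """
    return [
        _Episode(round(e.onset * fs) / fs, round(e.offset * fs) / fs, e.speed)
        for e in episodes
    ]


def generate_dyad(
    spec: SyntheticDyadSpec,
) -> tuple[MarkerTimeSeries, MarkerTimeSeries, GroundTruth]:
    """Generate one dyad's marker trajectories and ground truth.

    Deterministic given ``spec.seed``. Markers are stationary (plus noise)
    outside the true movement intervals and translate inside them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.mother_episodes is not None:
        speed = 0.5 * (spec.speed_min_mps + spec.speed_max_mps)
        mother_eps = [_Episode(on, off, speed) for on, off in spec.mother_episodes]
    else:
        mother_eps = _renewal_schedule(spec, rng)

    if spec.infant_episodes is not None:
        speed = 0.5 * (spec.speed_min_mps + spec.speed_max_mps)
        infant_eps = [_Episode(on, off, speed) for on, off in spec.infant_episodes]
        m_seg = np.array([[e.onset, e.offset] for e in mother_eps]).reshape(-1, 2)
        i_seg = np.array([[e.onset, e.offset] for e in infant_eps]).reshape(-1, 2)
        labels = classify_onsets(i_seg, m_seg)
        latencies = [math.nan] * len(infant_eps)
    else:
        infant_eps, labels, latencies = _coupled_schedule(spec, rng, mother_eps)

    mother_eps = _snap_to_grid(mother_eps, spec.sampling_rate_hz)
    infant_eps = _snap_to_grid(infant_eps, spec.sampling_rate_hz)

    mother_mts = _render_actor(spec, mother_eps, rng, base_offset=(0.0, 0.0, 0.0))
    infant_mts = _render_actor(spec, infant_eps, rng, base_offset=(0.0, 0.6, -0.3))
    gt = GroundTruth(
        duration_s=spec.duration_s,
        mother_segments=np.array([[e.onset, e.offset] for e in mother_eps]).reshape(-1, 2),
        infant_segments=np.array([[e.onset, e.offset] for e in infant_eps]).reshape(-1, 2),
        infant_labels=labels,
        infant_latencies=np.asarray(latencies, dtype=float),
    )
    return mother_mts, infant_mts, gt


def inject_missing(
    mts: MarkerTimeSeries,
    missing_fraction: float,
    run_length_s: float,
    seed: int,
) -> MarkerTimeSeries:
    """Invalidate contiguous runs of samples per marker (occlusion model).

    Total invalidated time per marker approximates ``missing_fraction x
    duration`` and never exceeds it by more than one run length. Positions
    of invalidated samples are replaced by NaN; valid samples are untouched.
    """
    if not 0 <= missing_fraction < 1:
        raise SyntheticSpecError("missing_fraction must be in [0, 1)")
    if run_length_s <= 0:
        raise SyntheticSpecError("run_length_s must be positive")
    out = mts.copy()
    if missing_fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    n = mts.n_frames
    run = max(1, int(round(run_length_s * mts.sampling_rate_hz)))
    n_runs = int(missing_fraction * n / run)  # floor: never overshoot by > 1 run
    for j in range(mts.n_markers):
        invalid = np.zeros(n, dtype=bool)
        placed = 0
        attempts = 0
        while placed < n_runs and attempts < 100 * max(n_runs, 1):
            attempts += 1
            start = int(rng.integers(0, max(1, n - run)))
            if invalid[start : start + run].any():
                continue
            invalid[start : start + run] = True
            placed += 1
        out.validity[invalid, j] = False
        out.positions[invalid, j, :] = np.nan
    return out


# ---------------------------------------------------------------------------
# Cohorts with planted correlation structure
# ---------------------------------------------------------------------------

#: Targets supported by :func:`generate_cohort`: the generative parameter is
#: an episode duration swept linearly across dyads, which makes the extracted
#: feature strictly monotone in it. ``direction`` is the sign of the
#: feature's dependence on the parameter.
COHORT_TARGETS = {
    "silence_ratio": {"direction": -1},
    "infant_activity_ratio": {"direction": +1},
    "maternal_activity_ratio": {"direction": +1},
    "overlap_ratio": {"direction": +1},
}


@dataclasses.dataclass
class CohortDyad:
    """One cohort member; trajectories are rendered on demand."""

    dyad_id: str
    spec: SyntheticDyadSpec
    ground_truth: GroundTruth = None  # filled by realize()

    def realize(self) -> tuple[MarkerTimeSeries, MarkerTimeSeries]:
        mother, infant, gt = generate_dyad(self.spec)
        self.ground_truth = gt
        return mother, infant


def _cohort_schedules(
    target: str, param: float, duration_s: float
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Deterministic episode schedules in which ``target`` is strictly
    monotone in ``param`` (an episode duration in seconds)."""
    cycle = 12.0
    n_cycles = int((duration_s - 2.0) // cycle)
    ks = range(n_cycles)
    if target == "overlap_ratio":
        mother = [(2.0 + k * cycle, 7.0 + k * cycle) for k in ks]  # dur 5
        infant = [(2.2 + k * cycle, 2.2 + k * cycle + param) for k in ks]
    elif target == "maternal_activity_ratio":
        mother = [(2.0 + k * cycle, 2.0 + k * cycle + param) for k in ks]
        infant = [(7.0 + k * cycle, 9.0 + k * cycle) for k in ks]  # dur 2
    else:  # silence_ratio, infant_activity_ratio
        mother = [(2.0 + k * cycle, 4.0 + k * cycle) for k in ks]  # dur 2
        infant = [(7.0 + k * cycle, 7.0 + k * cycle + param) for k in ks]
    return mother, infant


def generate_cohort(
    n_dyads: int,
    feature_target: str,
    planted_rho: float,
    seed: int,
    duration_s: float = 60.0,
    param_range: tuple[float, float] = (0.8, 4.0),
    noise_sd_m: float = 0.0,
) -> tuple[list[CohortDyad], pd.DataFrame]:
    """Cohort of dyads with a planted Spearman correlation.

    The generative parameter (an infant or mother episode duration) is swept
    linearly across dyads; a synthetic composite on the 1-5 rating scale is
    generated through a Gaussian copula so that the population Spearman
    correlation between the extracted ``feature_target`` and the composite
    is approximately ``planted_rho`` (exactly 1 when ``planted_rho`` is 1,
    since both sides are then strictly monotone in the parameter).

    Returns the dyad list and a ratings table indexed by dyad id with one
    ``synthetic_composite`` column.
    """
    if feature_target not in COHORT_TARGETS:
        raise SyntheticSpecError(
            f"unknown feature_target {feature_target!r}; valid names: "
            f"{sorted(COHORT_TARGETS)}"
        )
    if abs(planted_rho) > 1:
        raise SyntheticSpecError("planted_rho must satisfy |rho| <= 1")
    if n_dyads < 3:
        raise SyntheticSpecError("n_dyads must be >= 3")
    rng = np.random.default_rng(seed)
    direction = COHORT_TARGETS[feature_target]["direction"]
    params = np.linspace(param_range[0], param_range[1], n_dyads)

    dyads = []
    for i, p in enumerate(params):
        mother_eps, infant_eps = _cohort_schedules(feature_target, float(p), duration_s)
        spec = SyntheticDyadSpec(
            duration_s=duration_s,
            seed=int(rng.integers(2**31)),
            noise_sd_m=noise_sd_m,
            spike_rate_per_min=0.0,
            mother_episodes=mother_eps,
            infant_episodes=infant_eps,
        )
        dyads.append(CohortDyad(dyad_id=f"dyad{i:04d}", spec=spec))

    # Gaussian copula: rank-correlate the composite with the feature's
    # expected ordering at Pearson r = 2 sin(pi * rho_s / 6).
    z_feature = direction * stats.norm.ppf((np.arange(n_dyads) + 0.5) / n_dyads)
    r = 2.0 * math.sin(math.pi * planted_rho / 6.0)
    z = r * z_feature + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_dyads)
    composite = 1.0 + 4.0 * stats.norm.cdf(z)
    ratings = pd.DataFrame(
        {"synthetic_composite": composite},
        index=pd.Index([d.dyad_id for d in dyads], name="dyad_id"),
    )
    return dyads, ratings


# ---------------------------------------------------------------------------
# File output (same dialects the I/O layer reads)
# ---------------------------------------------------------------------------

def write_dyad(
    out_dir: str | Path,
    dyad_id: str,
    mother: MarkerTimeSeries,
    infant: MarkerTimeSeries,
    ground_truth: GroundTruth,
    unit: str = "mm",
) -> None:
    """Write marker TSVs plus a ground-truth sidecar JSON for one dyad."""
    from .mocap_io import write_marker_tsv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_marker_tsv(mother, out_dir / f"{dyad_id}_mother.tsv", unit=unit)
    write_marker_tsv(infant, out_dir / f"{dyad_id}_infant.tsv", unit=unit)
    (out_dir / f"{dyad_id}_truth.json").write_text(ground_truth.to_json())
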