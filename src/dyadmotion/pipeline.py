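"""End-to-end orchestration: read -> trim -> interpolate -> filter ->
energy -> segment -> features, plus the feature-rating correlation stage.

The extraction run mirrors the study protocol: recordings are trimmed to
the rated window (from 2 min onward; 3 min at 4 months, 5 min at 13
months), dyads whose markers miss more than 5% of the window are rejected
with a logged reason (quality-control accounting), and the surviving
trajectories flow through the kinetic-energy and segmentation stages into
the eight dyadic motion features per body part.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import features as feat
from . import kinetics, mocap_io, rating_stats, segmentation

logger = logging.getLogger(__name__)

AGE_WINDOWS = {"4m": (120.0, 180.0), "13m": (120.0, 300.0)}


class PipelineError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Tunable parameters of one extraction run (study values as defaults)."""

    age_group: str = "13m"
    window_start_s: float | None = None  # None: age-group default
    window_duration_s: float | None = None
    sampling_rate_hz: float = 240.0
    unit: str = "mm"
    max_missing_fraction: float = 0.05
    filter_order: int = 4
    filter_cutoff_hz: float = 10.0
    apply_filter: bool = True
    threshold_fraction: float = segmentation.THRESHOLD_FRACTION
    spike_percentile: float = segmentation.SPIKE_PERCENTILE
    min_gap_s: float = segmentation.MIN_GAP_S
    min_duration_s: float = segmentation.MIN_DURATION_S
    response_window_s: float = feat.RESPONSE_WINDOW_S
    mother_mass_kg: float = 65.0
    infant_mass_kg: float = 8.0
    body_parts: tuple = kinetics.BODY_PARTS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_missing_fraction",
            "filter_cutoff_hz",
            "threshold_fraction",
            "min_gap_s",
            "min_duration_s",
            "response_window_s",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        if self.age_group not in AGE_WINDOWS and (
            self.window_start_s is None or self.window_duration_s is None
        ):
            raise PipelineError(
                f"unknown age group {self.age_group!r} and no explicit window given"
            )

    @property
    def window(self) -> tuple[float, float]:
        start, dur = AGE_WINDOWS.get(self.age_group, (None, None))
        if self.window_start_s is not None:
            start = self.window_start_s
        if self.window_duration_s is not None:
            dur = self.window_duration_s
        return float(start), float(dur)

    def segment_model(self, role: str) -> kinetics.SegmentModel:
        if role == "mother":
            return kinetics.SegmentModel.default("mother", self.mother_mass_kg)
        return kinetics.SegmentModel.default(
            "infant", self.infant_mass_kg, with_shoulders=self.age_group != "4m"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "body_parts" in raw:
            raw["body_parts"] = tuple(raw["body_parts"])
        return cls(**raw)


def preprocess(
    mts: mocap_io.MarkerTimeSeries, config: RunConfig, trim: bool = True
) -> mocap_io.MarkerTimeSeries:
    """Trim, interpolate missing runs (or reject), and low-pass filter."""
    if trim:
        start, dur = config.window
        mts = mocap_io.trim_to_window(mts, start, dur)
    mts = mocap_io.interpolate_missing(mts, config.max_missing_fraction)
    if config.apply_filter:
        mts = mocap_io.lowpass_filter(mts, config.filter_order, config.filter_cutoff_hz)
    return mts


def segment_dyad(
    mother: mocap_io.MarkerTimeSeries,
    infant: mocap_io.MarkerTimeSeries,
    config: RunConfig,
    trim: bool = False,
) -> dict[str, tuple[segmentation.MovementSegmentList, segmentation.MovementSegmentList]]:
    """Cleaned (infant, mother) segment lists per body part for one dyad."""
    out = {}
    series = {
        "mother": kinetics.energy_series(
            preprocess(mother, config, trim), config.segment_model("mother"), config.body_parts
        ),
        "infant": kinetics.energy_series(
            preprocess(infant, config, trim), config.segment_model("infant"), config.body_parts
        ),
    }
    for bp in config.body_parts:
        segs = {
            role: segmentation.segment_movements(
                series[role][bp],
                threshold_fraction=config.threshold_fraction,
                spike_percentile=config.spike_percentile,
                min_gap_s=config.min_gap_s,
                min_dur_s=config.min_duration_s,
            )
            for role in ("infant", "mother")
        }
        out[bp] = (segs["infant"], segs["mother"])
    return out


def run_extract(
    config: RunConfig,
    dyad_inputs: Iterable[tuple[str, object, object]],
    trim: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the feature table for many dyads, with a QC report.

    ``dyad_inputs`` yields ``(dyad_id, mother, infant)`` where each actor is
    either a :class:`~dyadmotion.mocap_io.MarkerTimeSeries` or a path to a
    marker TSV. Dyads violating the missing-data policy (or unreadable) are
    excluded and recorded in the QC report rather than aborting the run.

    Returns ``(feature_table, qc_report)``; the QC report has one row per
    dyad with its status and, for rejections, the reason.
    """
    rows, qc = [], []
    for dyad_id, mother, infant in dyad_inputs:
        try:
            mother = _as_mts(mother, config)
            infant = _as_mts(infant, config)
            parts = segment_dyad(mother, infant, config, trim=trim)
        except mocap_io.ExcessMissingDataError as exc:
            logger.warning("dyad %s rejected: %s", dyad_id, exc)
            qc.append(
                {
                    "dyad_id": dyad_id,
                    "status": "rejected",
                    "reason": f"missing>{exc.limit:.0%}",
                    "detail": str(exc),
                }
            )
            continue
        except (OSError, mocap_io.MocapIOError) as exc:
            logger.warning("dyad %s failed: %s", dyad_id, exc)
            qc.append(
                {"dyad_id": dyad_id, "status": "failed", "reason": "unreadable", "detail": str(exc)}
            )
            continue
        table = feat.extract_feature_table(
            [(dyad_id, parts)], config.body_parts, config.response_window_s
        )
        rows.append(table)
        qc.append({"dyad_id": dyad_id, "status": "ok", "reason": "", "detail": ""})
    columns = ["dyad_id", "body_part", *feat.FEATURE_NAMES]
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=columns)
    return table, pd.DataFrame(qc, columns=["dyad_id", "status", "reason", "detail"])


def _as_mts(obj: object, config: RunConfig) -> mocap_io.MarkerTimeSeries:
    if isinstance(obj, mocap_io.MarkerTimeSeries):
        return obj
    return mocap_io.read_marker_tsv(obj, config.sampling_rate_hz, config.unit)


def run_correlate(
    feature_table: pd.DataFrame,
    ratings: pd.DataFrame,
    composite_map: Mapping | None = None,
    age_group: str = "13m",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Correlate extracted features with rating composites.

    ``ratings`` is indexed by dyad id. If a ``composite_map`` is given, the
    columns are treated as raw CIB scale ratings and averaged into the age
    group's composites first; otherwise they are used as composites
    directly. Raises when no dyad ids match.
    """
    if ratings.empty:
        raise PipelineError("ratings table is empty")
    if composite_map is not None:
        comps = rating_stats.parse_composite_map(composite_map)[age_group]
        composites = rating_stats.composite_scores(ratings, comps)
    else:
        composites = ratings
    matched = feature_table["dyad_id"].isin(composites.index)
    if not matched.any():
        unmatched = sorted(set(feature_table["dyad_id"]))[:10]
        raise PipelineError(f"no dyad ids match the ratings; feature ids start with {unmatched}")
    return rating_stats.correlation_table(feature_table, composites, bh_correction=bh_correction)
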