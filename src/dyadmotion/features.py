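"""Coarse- and fine-grained dyadic motion features.

Coarse (global) features describe how much each partner moves over the
rated window and how their movement co-occurs:

* *activity ratio* — fraction of the window one actor spends moving;
* *overlap ratio* — fraction where both move simultaneously;
* *silence ratio* — fraction where neither moves.

Fine-grained features describe movement coordination at onsets, with a
1.5 s response window (a generous visual reaction/response time):

* *coactive onset ratio* — fraction of the target actor's movements that
  start (a) while the partner is moving and (b) at most 1.5 s after the
  containing partner movement's onset (simultaneous-activity coordination);
* *alternating onset ratio* — fraction starting (a) while the partner is
  still and (b) at most 1.5 s after the partner's most recent movement
  offset (turn-taking-like coordination).

Conditions (a) partition time, so no onset is both coactive and
alternating. Ratios for an actor with no movements in the window are
undefined and reported as missing (NaN), never as zero.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .segmentation import MovementSegmentList

logger = logging.getLogger(__name__)

RESPONSE_WINDOW_S = 1.5

FEATURE_NAMES = (
    "infant_activity_ratio",
    "maternal_activity_ratio",
    "overlap_ratio",
    "silence_ratio",
    "infant_coactive_onset_ratio",
    "maternal_coactive_onset_ratio",
    "infant_alternating_onset_ratio",
    "maternal_alternating_onset_ratio",
)


class FeatureError(ValueError):
    pass


@dataclasses.dataclass
class MotionFeatureSet:
    """The eight motion features for one dyad x body part (fractions in [0, 1])."""

    dyad_id: str
    body_part: str
    infant_activity_ratio: float
    maternal_activity_ratio: float
    overlap_ratio: float
    silence_ratio: float
    infant_coactive_onset_ratio: float
    maternal_coactive_onset_ratio: float
    infant_alternating_onset_ratio: float
    maternal_alternating_onset_ratio: float
    response_window_s: float = RESPONSE_WINDOW_S

    def as_dict(self) -> dict[str, float]:
        d = {"dyad_id": self.dyad_id, "body_part": self.body_part}
        d.update({name: getattr(self, name) for name in FEATURE_NAMES})
        return d


def _check_window(window: tuple[float, float]) -> float:
    length = window[1] - window[0]
    if length <= 0:
        raise FeatureError("window must have positive length")
    return length


def _check_same_window(a: MovementSegmentList, b: MovementSegmentList) -> tuple[float, float]:
    if not math.isclose(a.window[0], b.window[0], abs_tol=1e-9) or not math.isclose(
        a.window[1], b.window[1], abs_tol=1e-9
    ):
        raise FeatureError(f"mismatched windows: {a.window} vs {b.window}")
    return a.window


def _intersection_length(a: np.ndarray, b: np.ndarray) -> float:
    """Total length of the pairwise intersection of two sorted interval sets."""
    total, i, j = 0.0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return total


def activity_ratio(segs: MovementSegmentList, window: tuple[float, float] | None = None) -> float:
    """Fraction of the window during which the actor was moving."""
    window = segs.window if window is None else window
    return segs.total_time / _check_window(window)


def overlap_ratio(infant: MovementSegmentList, mother: MovementSegmentList) -> float:
    """Fraction of the window during which both partners moved simultaneously."""
    window = _check_same_window(infant, mother)
    return _intersection_length(infant.segments, mother.segments) / _check_window(window)


def silence_ratio(infant: MovementSegmentList, mother: MovementSegmentList) -> float:
    """Fraction of the window during which neither partner moved."""
    window = _check_same_window(infant, mother)
    length = _check_window(window)
    union = infant.total_time + mother.total_time - _intersection_length(
        infant.segments, mother.segments
    )
    return (length - union) / length


def _partner_state_at(partner: MovementSegmentList, t: float) -> tuple[bool, float, float]:
    """(moving, containing-segment onset, most recent offset <= t) at time ``t``."""
    seg = partner.segments
    k = int(np.searchsorted(seg[:, 0], t, side="right")) - 1 if len(seg) else -1
    if k >= 0 and t < seg[k, 1]:
        return True, seg[k, 0], np.nan
    last_off = seg[k, 1] if k >= 0 else np.nan
    return False, np.nan, last_off


def coactive_onset_ratio(
    target: MovementSegmentList,
    partner: MovementSegmentList,
    window_s: float = RESPONSE_WINDOW_S,
    include_simultaneous: bool = True,
) -> float:
    """Fraction of target movements starting while the partner moves, soon after its onset.

    A target onset ``t_on`` counts when some partner segment ``[p_on, p_off)``
    contains it and ``t_on - p_on <= window_s``; the containing segment's own
    onset is the reference. With ``include_simultaneous=False``, onsets
    coinciding exactly with the partner onset are excluded.
    """
    _check_same_window(target, partner)
    if len(target) == 0:
        logger.info(
            "coactive_onset_ratio undefined: %s/%s has no movements in the window",
            target.role,
            target.body_part,
        )
        return math.nan
    count = 0
    for t_on in target.onsets:
        moving, p_on, _ = _partner_state_at(partner, t_on)
        if moving and t_on - p_on <= window_s:
            if include_simultaneous or t_on > p_on:
                count += 1
    return count / len(target)


def alternating_onset_ratio(
    target: MovementSegmentList,
    partner: MovementSegmentList,
    window_s: float = RESPONSE_WINDOW_S,
) -> float:
    """Fraction of target movements starting while the partner is still, soon after its offset.

    A target onset counts when no partner segment contains it and the most
    recent partner offset ``p_off <= t_on`` satisfies ``t_on - p_off <=
    window_s``. Onsets before any partner movement have no preceding offset
    and never count.
    """
    _check_same_window(target, partner)
    if len(target) == 0:
        logger.info(
            "alternating_onset_ratio undefined: %s/%s has no movements in the window",
            target.role,
            target.body_part,
        )
        return math.nan
    count = 0
    for t_on in target.onsets:
        moving, _, last_off = _partner_state_at(partner, t_on)
        if not moving and not math.isnan(last_off) and t_on - last_off <= window_s:
            count += 1
    return count / len(target)


def compute_feature_set(
    dyad_id: str,
    body_part: str,
    infant: MovementSegmentList,
    mother: MovementSegmentList,
    response_window_s: float = RESPONSE_WINDOW_S,
) -> MotionFeatureSet:
    """All eight features for one dyad and body part."""
    return MotionFeatureSet(
        dyad_id=dyad_id,
        body_part=body_part,
        infant_activity_ratio=activity_ratio(infant),
        maternal_activity_ratio=activity_ratio(mother),
        overlap_ratio=overlap_ratio(infant, mother),
        silence_ratio=silence_ratio(infant, mother),
        infant_coactive_onset_ratio=coactive_onset_ratio(infant, mother, response_window_s),
        maternal_coactive_onset_ratio=coactive_onset_ratio(mother, infant, response_window_s),
        infant_alternating_onset_ratio=alternating_onset_ratio(infant, mother, response_window_s),
        maternal_alternating_onset_ratio=alternating_onset_ratio(mother, infant, response_window_s),
        response_window_s=response_window_s,
    )


def extract_feature_table(
    dyads: Iterable[tuple[str, Mapping[str, tuple[MovementSegmentList, MovementSegmentList]]]],
    body_parts: Iterable[str] = ("head", "arms", "upper_body"),
    response_window_s: float = RESPONSE_WINDOW_S,
) -> pd.DataFrame:
    """One row per dyad x body part with all eight features.

    ``dyads`` yields ``(dyad_id, {body_part: (infant_segs, mother_segs)})``.
    Missing body parts or undefined ratios propagate as missing cells (NaN),
    never as silent zeros.
    """
    body_parts = list(body_parts)
    rows = []
    for dyad_id, parts in dyads:
        for bp in body_parts:
            if bp not in parts:
                logger.warning("dyad %s lacks body part %s; emitting missing row", dyad_id, bp)
                rows.append({"dyad_id": dyad_id, "body_part": bp})
                continue
            infant, mother = parts[bp]
            rows.append(
                compute_feature_set(dyad_id, bp, infant, mother, response_window_s).as_dict()
            )
    return pd.DataFrame(rows, columns=["dyad_id", "body_part", *FEATURE_NAMES])
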