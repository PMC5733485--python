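"""Translational kinetic energy of head, arms, and upper body.

Each actor's upper body is modelled as a small set of mass-carrying
segments — head, forearm+hand and upper arm per side, and the shoulders —
whose masses are expressed as fractions of total body mass (anthropometric
tables in the Winter tradition). Per-frame segment centre-of-mass speeds
are obtained by central finite differences of the filtered marker
trajectories, and the per-body-part energies are

    K_head       = 1/2 m_h v_h^2
    K_arms       = sum_sides 1/2 m_fa v_fa^2 (+ sum_sides 1/2 m_ua v_ua^2)
    K_upper_body = K_head + forearm terms (+ upper-arm and shoulder terms)

with the parenthesised terms included only when the corresponding segments
are tracked (infants at 4 months lack usable shoulder markers, so their
shoulder and upper-arm terms are dropped).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

from .mocap_io import MarkerTimeSeries

BODY_PARTS = ("head", "arms", "upper_body")

#: Segment names; *_l/*_r are independent mass-carrying terms.
ALL_SEGMENTS = (
    "head",
    "forearm_l",
    "forearm_r",
    "upper_arm_l",
    "upper_arm_r",
    "shoulder_l",
    "shoulder_r",
)

#: Terms entering each body part's energy (used if present in the model).
_BODY_PART_TERMS = {
    "head": ("head",),
    "arms": ("forearm_l", "forearm_r", "upper_arm_l", "upper_arm_r"),
    "upper_body": ALL_SEGMENTS,
}

#: Default mass fractions of total body mass, per segment instance.
#: Head and bilateral forearm+hand / upper-arm values follow the Winter
#: anthropometric tables; a discrete "shoulder" segment has no table entry,
#: so its default is a documented configuration placeholder.
DEFAULT_MASS_FRACTIONS = {
    "head": 0.081,
    "forearm": 0.022,
    "upper_arm": 0.028,
    "shoulder": 0.050,
}

DEFAULT_MARKER_MAP = {
    "head": ["head"],
    "wrist_l": "wrist_l",
    "wrist_r": "wrist_r",
    "elbow_l": "elbow_l",
    "elbow_r": "elbow_r",
    "shoulder_l": "shoulder_l",
    "shoulder_r": "shoulder_r",
}


class KineticsError(ValueError):
    pass


def _fraction_key(segment: str) -> str:
    for base in ("forearm", "upper_arm", "shoulder"):
        if segment.startswith(base) and segment != "head":
            return base
    return "head"


@dataclasses.dataclass
class SegmentModel:
    """Anthropometric model mapping markers to mass-carrying segments.

    Parameters
    ----------
    role : str
        ``"mother"`` or ``"infant"``.
    total_mass_kg : float
        Total body mass; segment masses are ``fraction * total_mass_kg``.
    mass_fractions : mapping
        Keys ``head``, ``forearm``, ``upper_arm``, ``shoulder`` — fraction of
        total body mass per segment *instance* (i.e. per side for bilateral
        segments).
    marker_map : mapping
        ``head`` maps to a list of head-marker labels (centroid is used);
        wrist/elbow/shoulder entries map to single labels.
    segments_present : iterable of str
        Subset of :data:`ALL_SEGMENTS` available for this actor.
    com_fraction_forearm, com_fraction_upper_arm : float
        Position of the segment centre of mass along wrist→elbow and
        elbow→shoulder respectively (0 = distal marker, 1 = proximal).
    """

    role: str
    total_mass_kg: float
    mass_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MASS_FRACTIONS)
    )
    marker_map: Mapping[str, object] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MARKER_MAP)
    )
    segments_present: frozenset = frozenset(ALL_SEGMENTS)
    com_fraction_forearm: float = 0.5
    com_fraction_upper_arm: float = 0.5

    def __post_init__(self) -> None:
        if self.total_mass_kg <= 0:
            raise KineticsError("total_mass_kg must be positive")
        self.segments_present = frozenset(self.segments_present)
        unknown = self.segments_present - set(ALL_SEGMENTS)
        if unknown:
            raise KineticsError(f"unknown segments: {sorted(unknown)}")
        used = sum(self.mass_fractions[_fraction_key(s)] for s in self.segments_present)
        for key, f in self.mass_fractions.items():
            if not 0 < f < 1:
                raise KineticsError(f"mass fraction {key!r}={f} must be in (0, 1)")
        if used >= 1:
            raise KineticsError(f"sum of used mass fractions ({used:.3f}) must be < 1")

    def segment_mass(self, segment: str) -> float:
        return self.mass_fractions[_fraction_key(segment)] * self.total_mass_kg

    @classmethod
    def default(cls, role: str, total_mass_kg: float, with_shoulders: bool = True) -> "SegmentModel":
        """Convenience constructor for the study's two marker layouts.

        ``with_shoulders=False`` reproduces the 4-month infant layout, where
        shoulder (and hence upper-arm) terms are excluded.
        """
        present = set(ALL_SEGMENTS)
        if not with_shoulders:
            present -= {"shoulder_l", "shoulder_r", "upper_arm_l", "upper_arm_r"}
        return cls(role=role, total_mass_kg=total_mass_kg, segments_present=frozenset(present))


@dataclasses.dataclass
class SpeedSeries:
    """Per-frame centre-of-mass speed (m/s) for each present segment."""

    role: str
    sampling_rate_hz: float
    speeds: dict[str, np.ndarray]
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.speeds.items():
            v = np.asarray(v, dtype=float)
            if (v < 0).any() or not np.isfinite(v).all():
                raise KineticsError(f"speeds for {name!r} must be finite and >= 0")
            self.speeds[name] = v

    @property
    def n_frames(self) -> int:
        return next(iter(self.speeds.values())).shape[0]


@dataclasses.dataclass
class EnergySeries:
    """Per-frame translational kinetic energy (J) for one actor x body part."""

    body_part: str
    energy: np.ndarray
    sampling_rate_hz: float
    role: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        if (self.energy < 0).any() or not np.isfinite(self.energy).all():
            raise KineticsError("energies must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return self.energy.shape[0]


def _com_trajectory(mts: MarkerTimeSeries, model: SegmentModel, segment: str) -> np.ndarray:
    from .mocap_io import MocapIOError

    mm = model.marker_map

    def one(label_key: str) -> np.ndarray:
        label = mm.get(label_key)
        if label is None:
            raise KineticsError(f"segment {segment!r}: marker {label_key!r} absent from marker map")
        try:
            return mts.marker(label)
        except MocapIOError as exc:
            raise KineticsError(f"segment {segment!r}: {exc}") from None

    if segment == "head":
        labels = mm.get("head")
        if not labels:
            raise KineticsError("segment 'head': no head markers in marker map")
        try:
            return np.mean([mts.marker(lab) for lab in labels], axis=0)
        except MocapIOError as exc:
            raise KineticsError(f"segment 'head': {exc}") from None
    side = segment[-1]
    if segment.startswith("forearm"):
        w, e = one(f"wrist_{side}"), one(f"elbow_{side}")
        return w + model.com_fraction_forearm * (e - w)
    if segment.startswith("upper_arm"):
        e, s = one(f"elbow_{side}"), one(f"shoulder_{side}")
        return e + model.com_fraction_upper_arm * (s - e)
    if segment.startswith("shoulder"):
        return one(f"shoulder_{side}")
    raise KineticsError(f"unknown segment {segment!r}")


def segment_com_speed(mts: MarkerTimeSeries, model: SegmentModel) -> SpeedSeries:
    """Centre-of-mass speed per present segment.

    Velocity is computed by central finite differences at the sampling rate
    (one-sided at the ends); speed is the Euclidean norm. The series is
    expected to be low-pass filtered already, which suppresses
    differentiation noise.
    """
    if not mts.validity.all():
        raise KineticsError("segment_com_speed requires a fully valid series")
    speeds: dict[str, np.ndarray] = {}
    dt = 1.0 / mts.sampling_rate_hz
    for segment in sorted(model.segments_present):
        com = _com_trajectory(mts, model, segment)
        vel = np.gradient(com, dt, axis=0)
        speeds[segment] = np.linalg.norm(vel, axis=1)
    return SpeedSeries(
        role=model.role, sampling_rate_hz=mts.sampling_rate_hz, speeds=speeds, t0=mts.t0
    )


def kinetic_energy(
    speeds: SpeedSeries, model: SegmentModel, body_part: str, strict: bool = False
) -> EnergySeries:
    """Sum ``1/2 m v^2`` over the segments entering one body part.

    Segments absent from ``model.segments_present`` contribute nothing;
    with ``strict=True`` a requested-but-absent term raises instead.
    """
    if body_part not in _BODY_PART_TERMS:
        raise KineticsError(f"unknown body part {body_part!r}; expected one of {BODY_PARTS}")
    total = np.zeros(speeds.n_frames)
    for segment in _BODY_PART_TERMS[body_part]:
        if segment not in model.segments_present:
            if strict:
                raise KineticsError(
                    f"body part {body_part!r} requires segment {segment!r}, "
                    "absent from this model"
                )
            continue
        v = speeds.speeds[segment]
        total = total + 0.5 * model.segment_mass(segment) * v**2
    return EnergySeries(
        body_part=body_part,
        energy=total,
        sampling_rate_hz=speeds.sampling_rate_hz,
        role=speeds.role,
        t0=speeds.t0,
    )


def energy_series(
    mts: MarkerTimeSeries,
    model: SegmentModel,
    body_parts: Iterable[str] = BODY_PARTS,
) -> dict[str, EnergySeries]:
    """Convenience: CoM speeds then kinetic energy for several body parts."""
    speeds = segment_com_speed(mts, model)
    return {bp: kinetic_energy(speeds, model, bp) for bp in body_parts}
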