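"""Body-segment and movement-axis catalogue.

Seven upper-body segments are tracked with one wearable IMU each: neck (N),
lower back (LB), right/left shoulder (RS/LS), right/left elbow (RE/LE) and
upper back (UB).  Every anatomical degree of freedom of a segment is modelled
as one *signed channel* in degrees: the two opposing movement directions
(flexion vs. extension, right vs. left, external vs. internal) are the two
signs of the same channel.  A :class:`MovementAxis` names one direction of one
channel -- it is the unit at which posture standards state their thresholds
and at which time-in-zone exposure is reported.

Mirrored direction pairs that exposure reports pool into a single "stressed
body part" (e.g. lower-back rotation right/left as ``LB5/6``) are listed in
:data:`STRESSED_PARTS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Segment(str, Enum):
    """Instrumented upper-body segments."""

    NECK = "N"
    LOWER_BACK = "LB"
    RIGHT_SHOULDER = "RS"
    LEFT_SHOULDER = "LS"
    RIGHT_ELBOW = "RE"
    LEFT_ELBOW = "LE"
    UPPER_BACK = "UB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Signed anatomical channels per segment.  Positive direction is flexion /
#: right / external; negative is extension / left / internal.  Shoulder
#: channels follow the wearable-system convention: ``vertical_rotation`` is
#: arm elevation (flexion/abduction plane, extension negative),
#: ``horizontal_rotation`` is horizontal arm swing (external positive).
SEGMENT_CHANNELS: dict[Segment, tuple[str, ...]] = {
    Segment.NECK: ("flexion_extension", "lateral_flexion", "rotation"),
    Segment.LOWER_BACK: ("flexion_extension", "lateral_flexion", "rotation"),
    Segment.RIGHT_SHOULDER: (
        "rotation_int_ext",
        "vertical_rotation",
        "horizontal_rotation",
    ),
    Segment.LEFT_SHOULDER: (
        "rotation_int_ext",
        "vertical_rotation",
        "horizontal_rotation",
    ),
    Segment.RIGHT_ELBOW: ("flexion_extension", "rotation_int_ext"),
    Segment.LEFT_ELBOW: ("flexion_extension", "rotation_int_ext"),
    Segment.UPPER_BACK: ("flexion_extension",),
}


@dataclass(frozen=True)
class MovementAxis:
    """One labelled movement direction of a signed segment channel."""

    label: str
    segment: Segment
    channel: str
    direction_sign: int
    movement: str

    def __post_init__(self) -> None:
        if self.direction_sign not in (-1, 1):
            raise ValueError(f"direction_sign must be +/-1, got {self.direction_sign}")
        if self.channel not in SEGMENT_CHANNELS[self.segment]:
            raise ValueError(
                f"channel {self.channel!r} not defined for segment {self.segment.value}"
            )


def _axes() -> dict[str, MovementAxis]:
    spec: list[tuple[str, Segment, str, int, str]] = []
    for seg, prefix in ((Segment.NECK, "N"), (Segment.LOWER_BACK, "LB")):
        spec += [
            (f"{prefix}1", seg, "flexion_extension", +1, "forward flexion"),
            (f"{prefix}2", seg, "flexion_extension", -1, "extension"),
            (f"{prefix}3", seg, "lateral_flexion", +1, "lateral flexion right"),
            (f"{prefix}4", seg, "lateral_flexion", -1, "lateral flexion left"),
            (f"{prefix}5", seg, "rotation", +1, "rotation right"),
            (f"{prefix}6", seg, "rotation", -1, "rotation left"),
        ]
    for seg, prefix in ((Segment.RIGHT_SHOULDER, "RS"), (Segment.LEFT_SHOULDER, "LS")):
        spec += [
            (f"{prefix}1", seg, "rotation_int_ext", +1, "rotation external"),
            (f"{prefix}2", seg, "rotation_int_ext", -1, "rotation internal"),
            (f"{prefix}3", seg, "vertical_rotation", +1, "vertical rotation"),
            (f"{prefix}4", seg, "horizontal_rotation", +1, "horizontal rotation external"),
            (f"{prefix}5", seg, "horizontal_rotation", -1, "horizontal rotation internal"),
        ]
    for seg, prefix in ((Segment.RIGHT_ELBOW, "RE"), (Segment.LEFT_ELBOW, "LE")):
        spec += [
            (f"{prefix}1", seg, "flexion_extension", +1, "flexion"),
            (f"{prefix}2", seg, "flexion_extension", -1, "extension"),
            (f"{prefix}3", seg, "rotation_int_ext", +1, "rotation external"),
            (f"{prefix}4", seg, "rotation_int_ext", -1, "rotation internal"),
        ]
    return {
        label: MovementAxis(label, seg, chan, sign, movement)
        for label, seg, chan, sign, movement in spec
    }


#: Label -> axis for every catalogued movement direction (N1..N6, LB1..LB6,
#: RS1..RS5, LS1..LS5, RE1..RE4, LE1..LE4).  The upper-back sensor only
#: supports neck tracking and carries no labelled axes of its own.
AXES: dict[str, MovementAxis] = _axes()

#: Stressed-body-part pooling used in exposure reports: mirrored direction
#: pairs are pooled (worst zone of the two directions); one-direction labels
#: pass through unchanged.
STRESSED_PARTS: dict[str, tuple[str, ...]] = {
    "N1": ("N1",),
    "N2": ("N2",),
    "N3/4": ("N3", "N4"),
    "N5/6": ("N5", "N6"),
    "LB1": ("LB1",),
    "LB2": ("LB2",),
    "LB3/4": ("LB3", "LB4"),
    "LB5/6": ("LB5", "LB6"),
    "RS1/2": ("RS1", "RS2"),
    "RS3": ("RS3",),
    "RS4/5": ("RS4", "RS5"),
    "LS1/2": ("LS1", "LS2"),
    "LS3": ("LS3",),
    "LS4/5": ("LS4", "LS5"),
    "RE1": ("RE1",),
    "RE2": ("RE2",),
    "RE3/4": ("RE3", "RE4"),
    "LE1": ("LE1",),
    "LE2": ("LE2",),
    "LE3/4": ("LE3", "LE4"),
}


def axes_for_segment(segment: Segment) -> list[MovementAxis]:
    """All catalogued movement axes belonging to *segment*."""
    return [ax for ax in AXES.values() if ax.segment == segment]


def parts_for_segment(segment: Segment) -> list[str]:
    """Stressed-part labels whose member axes belong to *segment*."""
    return [
        part
        for part, members in STRESSED_PARTS.items()
        if AXES[members[0]].segment == segment
    ]
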