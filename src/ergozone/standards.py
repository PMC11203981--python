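"""Declarative posture-threshold standards and the per-sample zone classifier.

A posture standard is a set of :class:`ThresholdRule` objects, each stating:
for one movement axis, under a given work type (static/dynamic) and support
condition, an angle region and optionally a movement-frequency condition that
place the posture in the unacceptable (RED) or conditionally acceptable
(ORANGE) zone.  A sample for which no rule fires is acceptable (GREEN) --
standards enumerate hazards, not safety.

Three encodings are bundled with the package (see ``ergozone/rulesets``):

``legislation_542_2007``
    Slovak Decree 542/2007 Coll. on protection against physical load at work
    (standard id ``L``).
``stn_en_1005_4``
    STN EN 1005-4+A1, machinery-safety assessment of working postures
    (standard id ``S``).
``captiv_inrs``
    The French/INRS thresholds built into the Captiv wearable system
    (standard id ``C``).  These carry no static-work variants.

Angle predicates are expressed on the *signed* channel of the axis (see
:mod:`ergozone.catalog`): a one-sided lower bound catches positive-direction
excursions (e.g. flexion beyond 25 deg), a one-sided upper bound catches
negative-direction excursions (e.g. any extension: angle < 0), a band catches
an intermediate range, and an outside-band fires left of ``lo`` or right of
``hi`` (used for paired limits written like "-90/30").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .catalog import AXES, SEGMENT_CHANNELS, MovementAxis, Segment

__all__ = [
    "Zone",
    "AnglePredicate",
    "FrequencyPredicate",
    "ThresholdRule",
    "StandardRuleSet",
    "RulesetError",
    "Diagnostic",
    "load_ruleset",
    "dump_ruleset",
    "validate_ruleset",
    "classify_axis_sample",
    "combine_axis_zones",
    "BUNDLED_RULESETS",
]

ANGLE_FORMS = ("one_sided", "inside_band", "outside_band")
FREQ_FORMS = ("none", "ge", "lt", "eq")
WORK_TYPES = ("static", "dynamic", "any")
SUPPORT_MODES = ("requires_support", "requires_no_support", "any")


class RulesetError(ValueError):
    """Raised when a ruleset document fails schema or catalogue validation."""


class Zone(IntEnum):
    """Posture risk zone.

    Severity is totally ordered GREEN < ORANGE < RED.  NOT_ASSESSED marks
    segments a standard does not define and never enters severity
    comparisons.
    """

    NOT_ASSESSED = -1
    GREEN = 0
    ORANGE = 1
    RED = 2

    @property
    def severity(self) -> int:
        if self is Zone.NOT_ASSESSED:
            raise ValueError("NOT_ASSESSED has no severity")
        return int(self)


def combine_axis_zones(zones: Sequence[Zone]) -> Zone:
    """Worst (maximum-severity) zone among assessed entries.

    NOT_ASSESSED entries are ignored unless *all* entries are NOT_ASSESSED,
    in which case NOT_ASSESSED is returned.  Used to pool mirrored movement
    directions into one stressed body part.
    """
    zones = list(zones)
    if not zones:
        raise ValueError("combine_axis_zones requires a non-empty list")
    assessed = [z for z in zones if z is not Zone.NOT_ASSESSED]
    if not assessed:
        return Zone.NOT_ASSESSED
    return max(assessed, key=lambda z: z.severity)


def _cmp(value, bound, strict, side):
    """Vectorised bound comparison; side is 'ge' or 'le'."""
    if side == "ge":
        return value > bound if strict else value >= bound
    return value < bound if strict else value <= bound


@dataclass(frozen=True)
class AnglePredicate:
    """Angle region of a rule on a signed channel, in degrees.

    form ``one_sided``: exactly one bound.  ``lo`` fires at/above the bound,
    ``hi`` fires at/below it.  form ``inside_band``: fires between ``lo`` and
    ``hi``.  form ``outside_band``: fires at/left-of ``lo`` or at/right-of
    ``hi``.  ``lo_strict``/``hi_strict`` exclude the bound itself.
    """

    form: str
    lo: float | None = None
    hi: float | None = None
    lo_strict: bool = False
    hi_strict: bool = False

    def __post_init__(self) -> None:
        if self.form not in ANGLE_FORMS:
            raise RulesetError(f"unknown angle predicate form {self.form!r}")
        for bound in (self.lo, self.hi):
            if bound is not None and not -180.0 <= bound <= 180.0:
                raise RulesetError(f"angle bound {bound} outside [-180, 180]")
        if self.form == "one_sided":
            if (self.lo is None) == (self.hi is None):
                raise RulesetError("one_sided predicate needs exactly one bound")
        else:
            if self.lo is None or self.hi is None:
                raise RulesetError(f"{self.form} predicate needs both bounds")
            if not self.lo < self.hi:
                raise RulesetError(f"need lo < hi, got lo={self.lo}, hi={self.hi}")

    def matches(self, angle):
        """Boolean (scalar or ndarray) mask of angles inside the region."""
        if self.form == "one_sided":
            if self.lo is not None:
                return _cmp(angle, self.lo, self.lo_strict, "ge")
            return _cmp(angle, self.hi, self.hi_strict, "le")
        if self.form == "inside_band":
            return _cmp(angle, self.lo, self.lo_strict, "ge") & _cmp(
                angle, self.hi, self.hi_strict, "le"
            )
        return _cmp(angle, self.lo, self.lo_strict, "le") | _cmp(
            angle, self.hi, self.hi_strict, "ge"
        )

    def crossing_spec(self) -> tuple[int, float]:
        """(direction_sign, threshold) whose upward crossings count as one
        movement repetition into this predicate's region.

        Regions on the negative half-axis count crossings of the mirrored
        signal.  For outside-band regions the positive-side bound is used;
        bundled rules never pair outside-band with a frequency condition.
        """
        if self.form == "one_sided":
            if self.lo is not None:
                return (+1, self.lo)
            return (-1, -self.hi)
        if self.form == "inside_band":
            if self.hi <= 0:
                return (-1, -self.hi)
            return (+1, self.lo)
        return (+1, self.hi)


@dataclass(frozen=True)
class FrequencyPredicate:
    """Movement-frequency condition in repetitions per minute.

    ``eq`` is interpreted as the half-open interval ``[threshold,
    threshold + quantum)`` where the quantum is one countable event per
    observation window (exact equality is untestable on real-valued rates).
    """

    form: str = "none"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.form not in FREQ_FORMS:
            raise RulesetError(f"unknown frequency predicate form {self.form!r}")
        if self.form == "none":
            if self.threshold is not None:
                raise RulesetError("frequency form 'none' takes no threshold")
        elif self.threshold is None or self.threshold <= 0:
            raise RulesetError("frequency threshold must be > 0")

    def matches(self, freq, quantum: float = 1.0):
        if self.form == "none":
            return np.broadcast_to(True, np.shape(freq)) if np.ndim(freq) else True
        if self.form == "ge":
            return freq >= self.threshold
        if self.form == "lt":
            return freq < self.threshold
        return (freq >= self.threshold) & (freq < self.threshold + quantum)


@dataclass(frozen=True)
class ThresholdRule:
    """One threshold cell of a posture standard."""

    standard: str
    axis: MovementAxis
    zone: Zone
    angle: AnglePredicate
    frequency: FrequencyPredicate = FrequencyPredicate()
    work_type: str = "any"
    support: str = "any"
    note: str = ""

    def __post_init__(self) -> None:
        if self.zone not in (Zone.RED, Zone.ORANGE):
            raise RulesetError("rules only assign RED or ORANGE (GREEN = no rule fires)")
        if self.work_type not in WORK_TYPES:
            raise RulesetError(f"unknown work_type {self.work_type!r}")
        if self.support not in SUPPORT_MODES:
            raise RulesetError(f"unknown support mode {self.support!r}")

    def context_matches(self, work_type, supported):
        """Mask of samples whose work type and support state admit this rule.

        *work_type* may be a scalar or a per-sample array; *supported* is a
        scalar or array broadcastable against it.
        """
        vector = np.ndim(work_type) > 0 or np.ndim(supported) > 0
        if self.work_type == "any":
            ok = np.ones(np.shape(work_type), dtype=bool) if vector else True
        else:
            ok = np.asarray(work_type) == self.work_type
            ok = ok if vector else bool(ok)
        sup = np.asarray(supported, dtype=bool)
        if self.support == "requires_support":
            ok = ok & sup if vector else (ok and bool(sup))
        elif self.support == "requires_no_support":
            ok = ok & ~sup if vector else (ok and not bool(sup))
        return ok

    def matches(self, angle, freq, work_type, supported, quantum: float = 1.0):
        if np.ndim(angle) or np.ndim(freq) or np.ndim(work_type):
            return (
                np.asarray(self.angle.matches(angle))
                & np.asarray(self.frequency.matches(freq, quantum))
                & np.asarray(self.context_matches(work_type, supported))
            )
        return (
            bool(self.angle.matches(angle))
            and bool(self.frequency.matches(freq, quantum))
            and bool(self.context_matches(work_type, supported))
        )


@dataclass
class StandardRuleSet:
    """A validated set of threshold rules for one standard."""

    standard_id: str
    name: str = ""
    rules: list[ThresholdRule] = field(default_factory=list)
    unassessed_segments: set[Segment] = field(default_factory=set)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.standard_id not in ("L", "S", "C"):
            raise RulesetError(f"standard_id must be L, S or C, got {self.standard_id!r}")
        for rule in self.rules:
            if rule.axis.label not in AXES:
                raise RulesetError(f"unknown axis label {rule.axis.label!r}")
            if rule.axis.segment in self.unassessed_segments:
                raise RulesetError(
                    f"rule on axis {rule.axis.label} targets unassessed segment "
                    f"{rule.axis.segment.value}"
                )

    def rules_for_axis(self, label: str) -> list[ThresholdRule]:
        return [r for r in self.rules if r.axis.label == label]

    def assessed_segments(self) -> list[Segment]:
        return [s for s in Segment if s not in self.unassessed_segments]

    def to_dict(self) -> dict:
        return {
            "standard_id": self.standard_id,
            "name": self.name,
            "notes": self.notes,
            "unassessed_segments": sorted(s.value for s in self.unassessed_segments),
            "rules": [_rule_to_dict(r) for r in self.rules],
        }


def _rule_to_dict(rule: ThresholdRule) -> dict:
    angle: dict = {"form": rule.angle.form}
    for key in ("lo", "hi"):
        if getattr(rule.angle, key) is not None:
            angle[key] = float(getattr(rule.angle, key))
    if rule.angle.lo_strict:
        angle["lo_strict"] = True
    if rule.angle.hi_strict:
        angle["hi_strict"] = True
    out = {
        "axis": rule.axis.label,
        "zone": rule.zone.name.lower(),
        "work_type": rule.work_type,
        "support": rule.support,
        "angle": angle,
    }
    if rule.frequency.form != "none":
        out["frequency"] = {
            "form": rule.frequency.form,
            "threshold": float(rule.frequency.threshold),
        }
    if rule.note:
        out["note"] = rule.note
    return out


def _rule_from_dict(doc: Mapping, standard_id: str, index: int) -> ThresholdRule:
    where = f"rule #{index} ({doc.get('axis', '?')})"
    try:
        label = doc["axis"]
    except KeyError as exc:
        raise RulesetError(f"{where}: missing 'axis'") from exc
    if label not in AXES:
        raise RulesetError(f"{where}: axis label {label!r} not in catalogue")
    try:
        zone = Zone[doc["zone"].upper()]
        angle = AnglePredicate(**doc["angle"])
        freq = FrequencyPredicate(**doc.get("frequency", {"form": "none"}))
        return ThresholdRule(
            standard=standard_id,
            axis=AXES[label],
            zone=zone,
            angle=angle,
            frequency=freq,
            work_type=doc.get("work_type", "any"),
            support=doc.get("support", "any"),
            note=doc.get("note", ""),
        )
    except (KeyError, TypeError, RulesetError) as exc:
        raise RulesetError(f"{where}: {exc}") from exc


#: Bundled document name -> standard id.
BUNDLED_RULESETS: dict[str, str] = {
    "legislation_542_2007": "L",
    "stn_en_1005_4": "S",
    "captiv_inrs": "C",
}
_BY_ID = {v: k for k, v in BUNDLED_RULESETS.items()}


def load_ruleset(source: str | Path | Mapping) -> StandardRuleSet:
    """Load and validate a ruleset from a bundled name or id, a YAML/JSON
    file path, or an already-parsed mapping.

    ``load_ruleset("S")`` and ``load_ruleset("stn_en_1005_4")`` both resolve
    to the bundled STN EN encoding.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        name = str(source)
        if name in _BY_ID:
            name = _BY_ID[name]
        if name in BUNDLED_RULESETS:
            text = (
                resources.files("ergozone.rulesets").joinpath(f"{name}.yaml").read_text()
            )
        else:
            path = Path(source)
            if not path.exists():
                raise RulesetError(f"no bundled ruleset or file named {source!r}")
            text = path.read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise RulesetError("ruleset document must be a mapping")
    standard_id = doc.get("standard_id")
    if standard_id not in ("L", "S", "C"):
        raise RulesetError(f"standard_id must be L, S or C, got {standard_id!r}")
    try:
        unassessed = {Segment(s) for s in doc.get("unassessed_segments", [])}
    except ValueError as exc:
        raise RulesetError(f"unknown segment in unassessed_segments: {exc}") from exc
    rules = [
        _rule_from_dict(r, standard_id, i) for i, r in enumerate(doc.get("rules", []))
    ]
    return StandardRuleSet(
        standard_id=standard_id,
        name=doc.get("name", ""),
        rules=rules,
        unassessed_segments=unassessed,
        notes=doc.get("notes", ""),
    )


def dump_ruleset(rs: StandardRuleSet, path: str | Path | None = None) -> str:
    """Serialise a ruleset back to YAML; round-trips with :func:`load_ruleset`."""
    text = yaml.safe_dump(rs.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def classify_axis_sample(
    angle: float,
    freq: float,
    work_type: str,
    supported: bool,
    rules: Iterable[ThresholdRule],
    quantum: float = 1.0,
) -> Zone:
    """Classify one sample of one movement axis.

    RED rules are evaluated first, then ORANGE; the zone of the first tier
    with any satisfied rule is returned, else GREEN.  A rule is satisfied iff
    its work-type, support, angle and frequency conditions all hold.
    """
    if not np.isfinite(angle):
        raise ValueError(f"non-finite angle {angle!r}")
    if freq < 0:
        raise ValueError("frequency must be >= 0")
    rules = list(rules)
    for tier in (Zone.RED, Zone.ORANGE):
        for rule in rules:
            if rule.zone is tier and rule.matches(angle, freq, work_type, supported, quantum):
                return tier
    return Zone.GREEN


@dataclass(frozen=True)
class Diagnostic:
    """A non-fatal finding of :func:`validate_ruleset`."""

    kind: str  # 'overlap' | 'monotonicity' | 'uncovered_axes'
    message: str


def _one_sided_threshold(rule: ThresholdRule) -> float | None:
    """Magnitude of a one-sided bound in the rule's direction, if one-sided."""
    pred = rule.angle
    if pred.form != "one_sided":
        return None
    return abs(pred.lo if pred.lo is not None else pred.hi)


def validate_ruleset(rs: StandardRuleSet) -> list[Diagnostic]:
    """Report structural findings: RED/ORANGE overlap in identical context
    (legitimate; resolved by RED precedence), non-nested one-sided thresholds
    where an ORANGE bound exceeds the RED bound on the same axis and context
    (a monotonicity break), and assessed axes carrying no rules at all.
    """
    out: list[Diagnostic] = []
    probe = np.arange(-180.0, 180.5, 0.5)
    by_key: dict[tuple, dict[Zone, list[ThresholdRule]]] = {}
    for rule in rs.rules:
        key = (rule.axis.label, rule.work_type, rule.support, rule.frequency)
        by_key.setdefault(key, {}).setdefault(rule.zone, []).append(rule)
    for (label, wt, sup, _freq), tiers in by_key.items():
        for red in tiers.get(Zone.RED, []):
            for orange in tiers.get(Zone.ORANGE, []):
                if np.any(red.angle.matches(probe) & orange.angle.matches(probe)):
                    out.append(
                        Diagnostic(
                            "overlap",
                            f"{label} ({wt}, {sup}): ORANGE and RED angle regions "
                            "overlap; resolved by RED precedence",
                        )
                    )
                t_red = _one_sided_threshold(red)
                t_orange = _one_sided_threshold(orange)
                same_side = (red.angle.lo is None) == (orange.angle.lo is None)
                if (
                    t_red is not None
                    and t_orange is not None
                    and same_side
                    and t_orange > t_red
                ):
                    out.append(
                        Diagnostic(
                            "monotonicity",
                            f"{label} ({wt}, {sup}): ORANGE threshold {t_orange} deg "
                            f"exceeds RED threshold {t_red} deg",
                        )
                    )
    covered = {r.axis.label for r in rs.rules}
    uncovered = [
        label
        for label, axis in AXES.items()
        if axis.segment not in rs.unassessed_segments and label not in covered
    ]
    if uncovered:
        out.append(Diagnostic("uncovered_axes", "axes with no rules: " + ", ".join(uncovered)))
    return out
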