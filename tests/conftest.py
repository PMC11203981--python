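import pytest

from ergozone import load_ruleset


@pytest.fixture(scope="session")
def rulesets():
    """The three bundled standard encodings, keyed by id."""
    return {sid: load_ruleset(sid) for sid in ("L", "S", "C")}


def brute_force_zone(angle, freq, work_type, supported, rules, quantum=1.0):
    """Independent oracle: evaluate every rule on its own with plain Python
    comparisons and return the worst zone among satisfied rules.

    Interprets the rule fields directly instead of going through the
    package's predicate/classifier code paths.
    """
    from ergozone import Zone

    fired = []
    for rule in rules:
        if rule.work_type not in ("any", work_type):
            continue
        if rule.support == "requires_support" and not supported:
            continue
        if rule.support == "requires_no_support" and supported:
            continue
        a = rule.angle
        checks = []
        if a.lo is not None:
            checks.append(angle > a.lo if a.lo_strict else angle >= a.lo)
        if a.hi is not None:
            checks.append(angle < a.hi if a.hi_strict else angle <= a.hi)
        if a.form == "outside_band":
            lo_ok = angle < a.lo if a.lo_strict else angle <= a.lo
            hi_ok = angle > a.hi if a.hi_strict else angle >= a.hi
            angle_ok = lo_ok or hi_ok
        else:
            angle_ok = all(checks)
        if not angle_ok:
            continue
        f = rule.frequency
        if f.form == "ge" and not freq >= f.threshold:
            continue
        if f.form == "lt" and not freq < f.threshold:
            continue
        if f.form == "eq" and not (f.threshold <= freq < f.threshold + quantum):
            continue
        fired.append(rule.zone)
    if not fired:
        return Zone.GREEN
    return max(fired, key=lambda z: z.severity)
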