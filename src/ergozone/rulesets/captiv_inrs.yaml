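# Captiv / INRS default thresholds (standard id C).
#
# See legislation_542_2007.yaml for the shared encoding conventions.
# Standard-specific notes:
#   * This standard states dynamic-work thresholds only (static cells are
#     marked "/" in the source comparison); all rules are work_type dynamic.
#   * Thresholds are written ">= x" and transcribed inclusive.
#   * Paired limits written "-a/b" bracket the acceptable band between a
#     negative and a positive bound (an outside-band region).  They are
#     encoded here as two one-sided rules, one per movement direction, so
#     each labelled direction keeps its own zone attribution; the pooled
#     stressed part (e.g. RS4/5) reproduces the outside-band semantics.
#       - shoulder horizontal rotation "-90/30" red,  "-70/10" orange
#       - shoulder rotation internal/external "-60/45" red, "-40/20" orange
#   * No frequency conditions: the system applies its angle thresholds
#     directly to the streamed posture.
standard_id: C
name: "Captiv built-in thresholds (INRS, France)"
unassessed_segments: [UB, RE, LE]
notes: >
  Nested one-sided thresholds on every axis (ORANGE bound below RED bound);
  no static-work variants and no frequency gating.
rules:
  # ---- head and neck -------------------------------------------------
  - axis: N1
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 30}
    note: forward flexion >= 30 deg
  - axis: N2
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -20}
    note: extension >= 20 deg
  - axis: N3
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 20}
    note: lateral flexion >= 20 deg
  - axis: N4
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -20}
    note: lateral flexion >= 20 deg (left)
  - axis: N5
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 30}
    note: rotation >= 30 deg
  - axis: N6
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -30}
    note: rotation >= 30 deg (left)
  - axis: N1
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 15}
    note: forward flexion >= 15 deg
  - axis: N2
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -10}
    note: extension >= 10 deg
  - axis: N3
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 10}
    note: lateral flexion >= 10 deg
  - axis: N4
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -10}
    note: lateral flexion >= 10 deg (left)
  - axis: N5
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 15}
    note: rotation >= 15 deg
  - axis: N6
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -15}
    note: rotation >= 15 deg (left)
  # ---- back ----------------------------------------------------------
  - axis: LB1
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 45}
    note: forward flexion >= 45 deg
  - axis: LB2
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -20}
    note: extension >= 20 deg
  - axis: LB3
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 20}
    note: lateral flexion >= 20 deg
  - axis: LB4
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -20}
    note: lateral flexion >= 20 deg (left)
  - axis: LB5
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 30}
    note: rotation >= 30 deg
  - axis: LB6
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -30}
    note: rotation >= 30 deg (left)
  - axis: LB1
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 30}
    note: forward flexion >= 30 deg
  - axis: LB2
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -10}
    note: extension >= 10 deg
  - axis: LB3
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 10}
    note: lateral flexion >= 10 deg
  - axis: LB4
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -10}
    note: lateral flexion >= 10 deg (left)
  - axis: LB5
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 15}
    note: rotation >= 15 deg
  - axis: LB6
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -15}
    note: rotation >= 15 deg (left)
  # ---- upper limb (shoulder) -----------------------------------------
  - axis: RS3
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 90}
    note: vertical rotation >= 90 deg
  - axis: LS3
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 90}
    note: vertical rotation >= 90 deg
  - axis: RS4
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 30}
    note: horizontal rotation -90/30 deg, external side
  - axis: LS4
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 30}
    note: horizontal rotation -90/30 deg, external side
  - axis: RS5
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -90}
    note: horizontal rotation -90/30 deg, internal side
  - axis: LS5
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -90}
    note: horizontal rotation -90/30 deg, internal side
  - axis: RS1
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 45}
    note: rotation internal/external -60/45 deg, external side
  - axis: LS1
    zone: red
    work_type: dynamic
    angle: {form: one_sided, lo: 45}
    note: rotation internal/external -60/45 deg, external side
  - axis: RS2
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -60}
    note: rotation internal/external -60/45 deg, internal side
  - axis: LS2
    zone: red
    work_type: dynamic
    angle: {form: one_sided, hi: -60}
    note: rotation internal/external -60/45 deg, internal side
  - axis: RS3
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 60}
    note: vertical rotation >= 60 deg
  - axis: LS3
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 60}
    note: vertical rotation >= 60 deg
  - axis: RS4
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 10}
    note: horizontal rotation -70/10 deg, external side
  - axis: LS4
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 10}
    note: horizontal rotation -70/10 deg, external side
  - axis: RS5
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -70}
    note: horizontal rotation -70/10 deg, internal side
  - axis: LS5
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -70}
    note: horizontal rotation -70/10 deg, internal side
  - axis: RS1
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 20}
    note: rotation internal/external -40/20 deg, external side
  - axis: LS1
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, lo: 20}
    note: rotation internal/external -40/20 deg, external side
  - axis: RS2
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -40}
    note: rotation internal/external -40/20 deg, internal side
  - axis: LS2
    zone: orange
    work_type: dynamic
    angle: {form: one_sided, hi: -40}
    note: rotation internal/external -40/20 deg, internal side
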