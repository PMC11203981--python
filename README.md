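# ergozone

Time-in-zone ergonomic posture risk assessment under multiple codified
standards.

`ergozone` is for occupational-biomechanics practitioners and researchers who
record joint-angle time series with wearable IMUs and need to answer: *how
much of the shift does each body segment spend in an acceptable,
conditionally acceptable or unacceptable posture — and does the answer depend
on which standard you apply?*  The package ships declarative encodings of
three posture standards whose thresholds famously disagree:

* **L** — Slovak Decree 542/2007 Coll. (protection against physical load at
  work),
* **S** — STN EN 1005-4+A1 (machinery safety: assessment of working postures
  and movements),
* **C** — the French/INRS thresholds built into the Captiv wearable system,

and a full pipeline from raw angle CSVs (or a synthetic worker-motion
generator) to between-standard difference tables and paired significance
tests.

## The model

Each anatomical degree of freedom is a signed channel in degrees (flexion /
right / external positive).  A standard is a set of threshold rules; each
rule assigns the **red** (unacceptable) or **orange** (conditionally
acceptable) zone to an angle region of one movement axis, optionally gated by
work type (static/dynamic), support, and a movement-frequency condition
`f` in repetitions per minute (e.g. *trunk flexion > 20° at f ≥ 2/min is
unacceptable*).  A sample with no firing rule is **green**.  Red rules take
precedence over orange.

For worker *r*, standard *m* and stressed body part *k*, the exposure is

    Z_{m,k,r} = 100 x (samples in zone) / (samples assessed)   [%]

with `Z_G + Z_O + Z_R = 100`.  Between-standard differences per zone and
part are

    d1 = Z_C - Z_L,   d2 = Z_C - Z_S,   d3 = Z_S - Z_L,

so `d1 = d2 + d3` holds cell by cell.  Equality of method means is tested per
worker, zone and method pair with a two-sided paired *t*-test across stressed
parts (Shapiro–Wilk normality screening first, α = 0.05): 5 workers × 3 zones
× 3 pairs = 45 tests.

Movement frequency is estimated per rule threshold by counting
hysteresis-filtered upward crossings inside a sliding 60 s window.

## Worked example

One synthetic worker (three trials of a standing pick-inspect-place task)
assessed under all three standards:

```python
from dataclasses import replace
import ergozone as ez
from ergozone.assessment import (
    assess_recording, average_summaries, worker_overall_summary, difference_table,
)

profile = ez.default_task_profile()
rulesets = {sid: ez.load_ruleset(sid) for sid in ("L", "S", "C")}
trials = [
    assess_recording(
        ez.generate_recording(replace(profile, seed=t), duration=300.0, trial=t),
        rulesets,
    )
    for t in (1, 2, 3)
]
summaries = {m: average_summaries([tr[m] for tr in trials]) for m in rulesets}
print(worker_overall_summary(summaries, "W1").table.round(2))
print(difference_table(summaries, "W1").table.loc[("LB1",)].round(2))
```

prints

```
   green  orange    red
L  94.16    0.33   5.51
S  85.21    1.80  12.99
C  86.76   10.42   2.82

           d1     d2     d3
zone
green  -23.55   1.87 -25.42
orange  23.43  23.43   0.00
red      0.12 -25.30  25.42
```

The first table is the worker's overall share of work time per risk zone
under each standard (unweighted mean over stressed parts): the same motion
is 94% acceptable under the Slovak decree but only 85% under STN EN.  The
second table shows why, for trunk forward flexion (part `LB1`): the ~40°
pick excursions at 2/min are green under L (limit 60°), red under S (limit
20° at f ≥ 2/min, `d3 = +25.42` points of red) and orange under C (limit
30°).  Note `d1 = d2 + d3` in every row.

The same pipeline is available from the shell:

```
ergozone simulate --out-dir sim --seed 1
ergozone assess   --in-dir sim --out-dir out
ergozone compare  --in-dir out --out-dir out
ergozone report   --in-dir out --out report.md
```

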