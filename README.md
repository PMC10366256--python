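# majorload

Covering same-origin 3D joint-load vectors with spherical sectors, to derive
a small set of enveloping **major loads** for static finite-element load
cases — built for hip-implant (acetabular cage) strength checks, usable for
any load collection sharing one application point.

## The problem

The hip contact force passes through the centre of the femoral head, so the
thousands of force vectors recorded over daily activities (walking at three
speeds, stairs up/down, chair rise/sit, standing, knee bends) share one
initial point and differ only in direction and magnitude. FE practice
usually keeps just the peak loads of walking and stair climbing — but an
implant that survives a large load from one direction may still fail under a
smaller load from a different one, and high-magnitude loads occur well away
from the walking directions.

A **major load** summarises a group of recorded loads: it is the axis **c**
of a spherical sector with half-apex angle ϑ, scaled to the maximum
magnitude among the vectors the sector covers. A vector **u** is covered
when

    (u·c)² − (c·c)(u·u) cos²ϑ ≥ 0   and   u·c > 0,

i.e. **u** lies within ϑ of the axis (the positive-dot guard excludes the
antipodal sheet of the quadratic). Finding the fewest sectors that cover
every direction is a spherical set-cover problem (NP-hard), so the package
implements a deterministic two-phase heuristic:

1. **Directions.** Normalise the uncovered vectors; take their mean
   direction; pick the *edge vector* (the direction farthest from the
   mean); weight each direction within 2ϑ of the edge by the penalty
   v = v_min + (1 − v_min)(1 − d_norm)^p, where d_norm is the chord
   distance to the edge normalised by the largest local distance; sweep a
   candidate axis over a (tilt × azimuth) grid around the edge (tilt ≤ ϑ,
   so the edge always stays covered) and keep the axis with the largest
   penalty sum over its covered set; remove what it covers; repeat.
2. **Magnitudes.** Give each cone the maximum resultant magnitude among
   all samples it covers, so every recorded load is enveloped in both
   direction and magnitude.

Defaults ϑ = 10°, p = 6, 1° grid increment, v_min = 0.1.

## Worked example

```python
from majorload import CoverConfig, cover, coverage_report, generate_daily_activity_dataset

dataset = generate_daily_activity_dataset(seed=1)        # 9 x 201 = 1809 vectors, BW%
loads = cover(dataset, CoverConfig(half_apex_deg=10, penalty_exponent=6))
print(len(loads))                                        # 11
report = coverage_report([ml.cone for ml in loads], dataset)
print(report.fraction)                                   # 1.0
print(round(loads[0].magnitude, 1))                      # 156.0  (BW%)
```

Eleven 10° sectors envelop all 1809 synthetic daily-activity vectors: every
recorded load lies within 10° of some major-load axis and does not exceed
its magnitude. By contrast, the five walking/stairs activity peaks used as
10° load cases cover only 61.7 % of the same collection and miss loads up to
260 BW% (`examples/03_coverage_comparison.py`). The `examples/` scripts walk
through each capability; the same pipelines run from the shell:

```
majorload synth --preset activities --seed 1 --out loads.csv
majorload cover --in loads.csv --units bw --mass-kg 80 --theta 10 \
    --penalty-exponent 6 --out major.csv
majorload report --in loads.csv --axes major.csv --theta 10 --out report.json
```

## Using a recorded collection (converter recipe)

The public instrumented-prosthesis collection of daily-activity hip loads
("HIP98", orthoload.com) distributes per-activity time series — 201 samples
per activity, X/Y/Z force components in BW%, pelvic coordinate system — via
its own viewer program. To use it here, export each activity's table and
stack them into one CSV with columns
`activity,sample_index,fx,fy,fz` (comma separator, '.' decimal, one header
row), then place it at `data/hip98_pelvic.csv`:

```python
dataset = read_load_table("data/hip98_pelvic.csv", units="bw")   # 1809 rows
```

With that file present the test suite additionally verifies the published
per-activity peaks at 80 kg (e.g. normal walking → (228, −207, 1803) N) and
that ϑ = 10°, p = 6 covers the collection with at most ten major loads;
without it, `tests/test_acceptance.py::test_daily_activity_collection_reproduction`
fails with a message pointing back to this recipe.

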