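# Methods

## Model

All loads are force vectors with a common application point (the hip joint
centre), expressed in a fixed anatomical frame (pelvic, by convention of
the instrumented-prosthesis collections) in percent of body weight (BW%)
or newtons. A *spherical sector* (cone) with unit axis c and half-apex
angle ϑ covers a vector u when

    (u·c)² − (c·c)(u·u) cos²ϑ ≥ 0   and   u·c > 0.

The quadratic alone is sign-symmetric and admits both sheets of the double
cone; the positive-dot guard keeps only the sheet around the axis, because
a load opposite the axis is a physically distinct load case. With this
guard the condition is exactly "angle(u, c) ≤ ϑ", boundary inclusive, and
is invariant to positive scaling of u. On the reference collections every
direction lies in one half-space, so the guard never fires there; it
matters only for datasets with opposing load directions.

A *major load* is a covering cone together with the maximum resultant
magnitude among the samples it covers; its force vector (axis × magnitude)
is one static FE load case. The exact minimum number of cones is a
spherical set-cover problem, NP-hard in general; the package provides a
heuristic, not an optimality proof.

## The heuristic

Phase one (directions) loops until every nonzero direction is covered:

1. normalise the remaining vectors; zero-magnitude samples are retained in
   the dataset but excluded here (a warning is logged at read time);
2. mean direction: arithmetic component mean, renormalised. A mean norm
   below `mean_degeneracy_tol` (default 1e-9) is degenerate (antipodally
   balanced input); the edge fallback is then the direction of the
   largest-magnitude remaining sample. Degeneracy cannot occur for
   half-space data but must not crash;
3. edge vector: the remaining direction with the largest Euclidean chord
   distance to the mean (chord distance is order-equivalent to angle and
   cheapest; ties go to the lowest dataset index);
4. local set: directions within 2ϑ of the edge. This is the tightest
   radius that provably loses nothing — any cone whose axis stays within
   ϑ of the edge reaches at most 2ϑ from it;
5. penalty weights over the local set: v = v_min + (1 − v_min)(1 − d_norm)^p
   with d_norm the chord distance to the edge divided by the largest local
   distance (all zero when the largest is zero). v ∈ [v_min, 1], equal to 1
   at the edge and non-increasing in distance for p > 0;
6. axis search: candidates on a grid of tilts {0, Δ, …, ϑ} away from the
   edge (ϑ always included, so a cone can just reach 2ϑ-distant vectors)
   and azimuths {0, Δ, …, 360°−Δ}, Δ = `increment_deg`. Azimuth zero lies
   in the plane spanned by the edge and the current mean, making the grid
   data-anchored and hence the whole procedure equivariant under rotation
   of the input; when the mean is parallel to the edge the frame falls
   back to the coordinate axis least aligned with it (that fallback is the
   one rotation-anchored exception, reachable only in degenerate inputs).
   Tilt 0 contributes a single candidate. Each candidate is scored by the
   penalty sum over the local directions it covers; the first maximum in
   (tilt, azimuth) order wins, implementing the smaller-tilt, then
   smaller-azimuth tie-break;
7. everything the winning cone covers is removed. Each round removes at
   least the edge vector, so the loop terminates within n iterations.

Phase two (magnitudes) attributes every sample to *every* cone that covers
it and assigns each cone the maximum covered magnitude. The procedure of
starting all representatives at the global maximum and shrinking them
stepwise until each meets its largest covered sample has exactly this
fixed point, so the fixed point is computed directly — identical result,
simpler, exactly testable. Multiple attribution makes the envelope
property unconditional: no sample exceeds the magnitude of any cone that
covers it, and the largest major load equals the global maximum.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `half_apex_deg` (ϑ) | 10 | deg | sector angular radius; smaller → more, finer load cases |
| `penalty_exponent` (p) | 6 | — | sharpness of the edge-centred weighting; larger p concentrates coverage near the edge and empirically lowers the cone count |
| `v_min` | 0.1 | — | penalty floor; keeps far local vectors from being ignored entirely. The reference description names this floor without printing its value; 0.1 is this package's choice and is exposed everywhere |
| `increment_deg` (Δ) | 1 | deg | search grid step; finer steps cost time roughly ∝ Δ⁻² with little effect on the count |
| `mean_degeneracy_tol` | 1e-9 | — | norm threshold declaring the mean direction degenerate |

## Numerical choices

- Dot products are clamped to [−1, 1] before arccos.
- The coverage quadratic carries a relative slack of 1e-12 (≈ 2·10⁻¹⁰
  degrees beyond the boundary): a full-tilt candidate axis holds the edge
  vector exactly on its boundary, and an exact comparison would let 1-ulp
  noise decide membership per candidate, breaking determinism under
  rescaling or rotation of the input. The same slack is used in the axis
  scoring, so phase one and phase two agree on every membership decision.
- Angles are degrees at every interface; radians appear only inside
  trigonometric calls.
- All ties (edge selection, axis scoring, peak extraction) break to the
  lowest index / smallest grid coordinate, making runs bit-reproducible.
- CSV round trips use 17-significant-digit output and round-trip float
  parsing; integer-newton rounding exists only in the presentation layer.

## Synthetic data

`generate_daily_activity_dataset` emulates the structure of an
instrumented-hip daily-activity collection: 9 activities × 201 samples,
BW% units. Per activity the direction follows a reflected random walk in
the azimuthal-equidistant chart of a spherical cap (smooth trajectory,
hard spread bound) and the magnitude a sinusoidal cycle profile inside the
activity's range. The layout places walking (spreads 9–12°, tilts 4–16°
from a global superior-medial direction), stairs and quiet standing near
that global direction, and chair rise/sit and knee bending 28–34° away
with lower magnitudes (40–190 BW% vs 80–260 BW%), echoing published
per-activity peak magnitudes. Because the chair/knee clusters sit more
than 2ϑ from every walking/stairs peak direction, walking-only load cases
structurally cannot cover them — the partial-coverage demonstration does
not depend on the random seed.

What the generator does **not** emulate: measured noise and artefacts,
inter-patient variability, correlation between direction and magnitude
within a cycle, and the exact per-sample components of any recorded
collection. Tests passing on synthetic data therefore establish the
geometric and algorithmic guarantees (completeness, envelope, determinism,
equivariance, oracle agreement), not numeric agreement with any published
per-activity table; the latter requires a user-supplied export (see the
README recipe). On the synthetic collection the reference settings yield
11 major loads; on the recorded collection the reference count is ten, and
the package treats that as a bound to verify against real data, not a
property of the heuristic.

`generate_separated_clusters` builds instances whose minimal cover is
known *by construction*: clusters of angular radius (jitter) < ϑ, centres
separated by more than 2ϑ + 2·jitter, so each cluster fits in one cone and
no cone touches two. The exhaustive oracle `exact_min_cover` searches
subsets of a candidate axis family (the input directions plus all pairwise
bisectors) by branch-and-bound; it is exact relative to that family, and
the fixtures keep 2·jitter ≤ ϑ so a cluster member's own cone covers its
whole cluster and the restriction is provably harmless. The oracle refuses
instances above 15 vectors.

## Limitations

- One application point: multi-origin loads (muscle forces) are out of
  scope by construction.
- The heuristic is greedy and grid-based; it is deterministic and never
  below the exact minimum, but carries no approximation guarantee. Running
  several (ϑ, p) settings via `parameter_sweep` is the intended practice.
- The cone count is not claimed monotone in ϑ or p; the sweep reports data.
- `v_min` is a package choice (see table) and the count on recorded data
  may depend on it.
- The magnitude prefilter removes samples at exactly the threshold
  (strict >); `remove_precovered` offers both purely directional and
  magnitude-aware removal, since a committed load case may or may not
  carry a magnitude bound.
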