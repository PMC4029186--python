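# Methods

This note documents the models, geometric conventions, numerical choices and
known limitations behind `kneespect`. It is the package's own account of its
design; every number quoted here is computed by the test suite or the
acceptance script, not asserted.

## Zone scheme and label grammar

The localization scheme names 30 geometric zones: the femur contributes 8
condylar quadrant zones (`{medial, lateral} × {superior, inferior} ×
{anterior, posterior}`) plus the shaft reference zone `R` (9 total); the
patella 8 quadrant zones; the tibia 12 quadrant zones over three columns
(medial, intercondylar, lateral) plus the distal plate area `T4` (13 total).
Reports aggregate the patellar anterior/posterior sub-zones by maximum into
4 rows (`P1s`, `P2s`, `P1i`, `P2i`), giving 25 reportable rows; `R` is
reported separately as the normalization denominator. Report order runs
femur, patella, tibia, with tibial columns ordered medial, intercondylar,
lateral inside each quadrant block and `T4` last.

The patellar depth aggregation is a design decision: the scheme's 8 patellar
geometric zones are quadrants in all three directions, while the reportable
granularity for the patella is vertical × column only. Taking the maximum
over depth is consistent with the max-statistic used for every
volume-of-interest and cannot hide a lesion.

The native and postoperative scheme variants share the identical label set by
construction; they differ only in partition geometry (below). This keeps
pre/post reports row-compatible.

## Knee frame and partition geometry

All partitioning happens in an orthonormal anatomical frame built from the
alignment landmarks: longitudinal axis from talar centre to femoral head
centre; mediolateral axis = epicondylar direction orthogonalized against the
longitudinal axis (medial → lateral); anteroposterior axis completing a
right-handed frame. Depth tests use the *side-resolved* anterior direction
(`+ap` for right knees, `−ap` for left), so anterior/posterior labels are
anatomically correct for both sides and the whole partition is mirror
symmetric: mirroring landmarks and volume across the mid-sagittal plane with
the side flipped swaps medial/lateral labels at fixed spatial locations and
leaves everything else unchanged.

Each bone's region of interest is either a supplied binary mask or an
axis-aligned box in knee-frame (mediolateral, anterior, longitudinal)
coordinates (`bone_extents`). Within the ROI, membership is decided at the
voxel centre in physical millimetres by three planes:

* sagittal through the bone centre (femur: epicondyle midpoint; patella:
  patella centre; tibia: plateau centre, with two parasagittal planes at
  ±1/6 of the plateau width delimiting the intercondylar middle third —
  equal thirds being the simplest symmetric choice absent a published
  width);
* transverse at the epicondylar level (femur), at a configurable offset
  below the joint line (tibia, default 15 mm), or at the patella centre;
* coronal through the same bone centre.

Carve-outs happen first: the femoral reference cylinder `R` (axis along the
femoral mechanical axis through `femoral_shaft_point`, default radius 10 mm,
height 20 mm — the reference region has no published dimensions, so these
are explicit configurable defaults) and the tibial `T4` (postoperative: the
axis-aligned knee-frame box spanned by the plate landmarks padded by 10 mm;
native: the distal 25 mm slab of the tibial ROI). The postoperative variant
additionally shifts the tibial superior/inferior plane 10 mm inferiorly to
clear the osteotomy gap. Ties on a plane go to the
lateral/inferior/posterior side; the intercondylar column includes its
boundaries. Assignment is exhaustive and exclusive per bone by construction
and is tested by voxel-count conservation and by rigid-motion/mirror
properties.

`tibial_tuberosity` is accepted in landmark files for completeness but no
partition rule consumes it: every depth split runs through a bone centre.

## Uptake quantification

The volume-of-interest statistic is the zone **maximum**; the reference
statistic is the **mean** over `R` (configurable to median or max — which
statistic the reference uses is a modelling choice, and max/mean is the
conventional one for this normalization). Ratios are dimensionless and
invariant under global rescaling of the volume, which the tests verify to
machine precision. Zones with no voxels in the field of view yield `NaN`
with an explicit `missing` flag, never zero, so downstream statistics can
exclude them deliberately.

## Mechanical alignment

Femoral mechanical axis: femoral head centre → tibial plateau centre; tibial
mechanical axis: plateau centre → talar centre (the plateau centre serves as
the knee centre for both axes — the smallest-assumption reading of the
landmark list). Both axes are projected onto the coronal plane spanned by
the longitudinal and mediolateral frame axes; the epicondyles therefore only
orient the projection plane (removing flexion/rotation components), they are
not axis endpoints. The HKA deviation is the atan2 angle between the
projected axes; varus = medial deviation of the distal tibial axis relative
to the prolonged femoral axis, signed positive. Angles below 1e-7° are
reported as neutral. Human-readable output rounds to 0.1° and always prints
the direction word; machine output keeps full precision. The implementation
agrees with an independent closed-form vector oracle to < 1e-9° and is
invariant under rigid motion and mirror symmetry (tested).

## Reliability analysis

The agreement index is ICC(2,1): two-way random effects, absolute agreement,
single measure, computed from ANOVA mean squares. The variant is a design
choice — it is the standard model when observers are interchangeable — and
the implementation is cross-checked against an independent statistical
package in the tests. Numerical details: a matrix whose rater columns agree
exactly short-circuits to ICC = 1 (the mathematical value) to avoid
mean-square cancellation residue; estimates are clipped at 1 from above for
the same reason; negative estimates are reported raw with no truncation at
zero; zero total variance raises an explicit undefined-ICC error.

`reliability_report` mirrors the canonical two-observer × two-session
design: intra-observer ICCs pair each observer's sessions, the
inter-observer ICC pairs the observers' session-1 readings by default
(`session_pairing="mean"` averages sessions first; which pairing a study
used is often unstated, so both are implemented). The `Total` row pools all
(subject, target) pairs as rows of one matrix — the simplest reproduction of
a single overall ICC. Unbalanced targets are excluded with an explicit
warning, never silently.

`difference_table` reports median and (min–max) of absolute paired
differences — observers paired within sessions (inter) and sessions within
observers (intra) — with a human-readable integer-rounded column in the
`"1 (0–2)"` style.

## Phantom generator

The phantom emulates a knee SPECT/CT study with controllable geometry:
bones are axis-aligned boxes in the knee frame, scaled to the grid's
physical half-extents (default 48×48×100 voxels at 2×2×3 mm ≈ a 94×94×297 mm
field of view; validation requires at least 40/40/120 mm half-extents so all
landmarks fit). Default uptake levels are 50 counts for both baseline bone
and the reference region, a scale at which Poisson noise is visibly rough
but zones remain distinguishable; uniform baseline equal to the reference
gives the all-ones ratio table used as the end-to-end identity check.

Hot spots are spheres of constant amplitude whose centre defaults to the
most interior voxel of the declared zone (Euclidean distance transform).
Generation *fails* if a sphere spills outside its declared zone or touches
the reference region — this guarantees the ground-truth table
(`(baseline + amplitude) / reference_level` for hot zones,
`baseline / reference_level` elsewhere) is exact, so the noise-free
end-to-end test can assert bit-exact equality. With Poisson noise enabled,
ratios converge to truth as counts increase (tested at two count levels);
the maximum statistic is upward-biased at low counts, which is a property of
the method, not the phantom.

`simulate_raters` reproduces the two-observer × two-session design: each
recording is truth + per-observer bias + an independent error draw, either
Gaussian (tracer-ratio readings) or discrete −1/0/+1 (integer-degree
alignment readings, defaults p = 0.15/0.70/0.15 chosen so inter-observer
differences concentrate on the 0–2° scale). All randomness flows through one
explicit seed per artifact.

What the phantom does **not** emulate: anatomical bone shapes, SPECT
projection/reconstruction physics, partial-volume effects, scatter,
registration error between timepoints, or observer disagreement about
*landmark placement* (observer noise is applied to readings, not
landmarks). Passing tests therefore demonstrate the correctness of the
geometry, quantification and statistics, not clinical image fidelity.

## Simulation sizes

The packaged study designs use 23 subjects for the tracer-style reliability
simulation and 200 knees for the alignment-style simulation; estimator
recovery is checked as the mean of 50 replicate studies of 200 subjects,
which bounds the Monte-Carlo error of the mean estimate well below the 0.02
assertion width.

## Known limitations

* Zone boundary placements (plane levels, column widths, reference-cylinder
  dimensions, T4 extent) are declared, configurable defaults; clinical
  software may use different proprietary geometry.
* No automatic landmark detection or bone segmentation: landmarks and
  optional masks are inputs.
* No SUV-style dose/weight normalization and no inter-timepoint image
  registration; pre/post comparability relies on the reference-region
  normalization.
* The side-consistency check for landmark files assumes patient-oriented RAS
  coordinates; volumes in arbitrary rotated frames should disable it.
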