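# Methods

## Problem and model

Three triaxial accelerometers ride in the seam of a trouser leg at the
waist, thigh and ankle, sampled synchronously at 50 Hz. Because the garment
is loose, each sensor's orientation relative to the limb — and to the world —
is unknown and changes from day to day. The analysis recovers posture from
two observations that survive this uncertainty:

* the *direction* of the time-averaged acceleration is gravity, so after a
  per-day alignment the angle θ_z between a sensor's z-axis and vertical
  measures the inclination of its limb segment;
* the *variability* of acceleration over a short window separates held
  postures (sensor noise only) from locomotion.

A sample is first labelled static/dynamic by a weighted KNN on moving-std
features, then static samples are assigned one of four postures by a second
weighted KNN on the three inclination angles.

## Pipeline details and numerical choices

**Units.** All accelerations are in g with |g| = 1. This makes the
0.005 g / 0.1 g variability regimes directly interpretable and makes the
arccos estimator invariant to the unit question entirely.

**Gravity alignment.** The calibration segment is the first annotated
standing interval of the day (overridable). The rotation mapping the
calibration mean m onto ẑ is built with Rodrigues' formula from
axis = m × ẑ and angle = ∠(m, ẑ). Degeneracies: m ∥ ẑ gives the identity;
m anti-parallel to ẑ is rotated by π about x̂ (any perpendicular axis is
valid; x̂ is fixed for reproducibility). Orthonormality and det = +1 are
enforced to 1e-9. Alignment is an isometry and commutes with the (linear)
filter. Note that alignment references angles to the wearer's *realised*
standing pose: a thigh standing at 5° and sitting at 85° yields an aligned
sitting angle near 80°. Classification is unaffected — clusters shift
rigidly — but archetype tables should be read as angles relative to
standing.

**Filtering.** 2nd-order Butterworth, 3 Hz cutoff, applied forwards and
backwards (`sosfiltfilt`, odd-reflection padding). The effective magnitude
response is the squared single-pass response; near the cutoff it follows
the analog closed form 1/(1+(f/f_c)⁴) to well under 1%, while towards
Nyquist the bilinear design follows the tan-prewarped version of that
curve (both are asserted in tests). Segments shorter than 1 s are rejected
rather than filtered on reflection padding alone.

**Inclination.** θ_z = arccos(s_z/|g|) on the 1 s centred moving mean of
the vertical component, in degrees in [0, 180]. The ratio is clamped to
[−1, 1] because noise can push |s_z| past the calibration magnitude. |g| is
estimated per sensor as the mean norm of the moving-mean acceleration over
the standing interval, smoothed *within* the extracted interval so
neighbouring activities cannot leak into the calibration windows. The
signed atan2 estimator is implemented (undefined (0,0) samples become NaN)
but feeds nothing downstream.

**Windows.** All moving windows are centred with edges truncated to the
available samples and a stride of one sample, so feature series stay
aligned with per-sample annotations. Moving std uses the sample (n−1)
divisor. Candidate windows are 0.5, 1, 1.5, 2 and 3 s.

**Weighted KNN.** Euclidean metric, k = 10, vote weight 1/d². Two
conventions are fixed: if any neighbour is at distance zero the vote is a
plain majority among the zero-distance neighbours, and weight ties break
towards the lexicographically smallest label. Neighbour search uses a
KD-tree; the voting rules are validated against an exhaustive
all-pairs-distance oracle in the tests. Cross-validation is stratified
5-fold (shuffled with a fixed seed) or leave-one-subject-out with
participant ids as groups; confusion matrices aggregate test predictions
over folds.

**Training vs deployment features.** Training sets are built per extracted
activity segment: each annotated interval is sliced out, filtered and
windowed on its own, the analogue of cutting clean ~90 s strips from the
middle of longer bouts so transitions never contaminate a training window.
Deployment-style prediction (the cascade, the sit-to-stand analysis)
filters and windows the continuous stream instead. Features are computed
after alignment; the magnitude features are rotation-invariant, the
thigh-z feature is what alignment makes comparable across days.

**Bilateral rule.** With both legs instrumented, a sample is dynamic only
if both legs' static/dynamic classifiers say dynamic; otherwise the posture
comes from the right-leg posture classifier (the right leg is the primary
analysis side throughout).

**Reporting.** Daily summaries are per-category percentages of wear time
over the five categories (sum to 100). Segment extraction keeps a centred
`target_s` (default 90 s) sub-interval of longer bouts — centring is the
least-biased automatic stand-in for manual transition avoidance — and keeps
shorter intervals whole, flagged. Posture archetypes are per-posture median
angles per sensor, the data behind stick-figure renderings.

## The synthetic benchmark

No public recordings exist for this kind of study, so the generator is a
first-class, tested component that emulates the statistical structure the
classifiers rely on — not the biomechanics of gait.

* **Postures.** Each posture fixes a mean inclination per sensor (degrees,
  waist/thigh/ankle): standing 5/5/5, sitting 10/85/20, lying 85/88/88,
  legs outstretched 40/85/80, with between-repetition jitter sd 5°. The
  numbers are stand-ins chosen to give four separated clusters and a
  sitting-vs-outstretched contrast carried mainly by the ankle; they are
  configurable, not measured truths.
* **Dynamics.** Walking (0.3 g sinusoid at 2 Hz, 40° inclination sweep)
  and stairs (0.3 g at 1.5 Hz, 60° sweep) around the standing pose.
* **Mount model.** One uniformly random rotation per sensor per day, plus a
  small per-segment re-seating wobble (sd 0.5°), constant within a segment.
  Inclination is realised as rotation about the sensor x-axis; only θ_z is
  consumed downstream, so one rotation plane suffices.
* **Noise.** White Gaussian, sd 0.002 g per axis — static 3 s moving std
  then stays near 0.001 g (< 0.005 g) while dynamic segments stay above
  0.17 g (> 0.1 g).
* **Benchmark.** 15 participant-days (5 simulated participants × 3 days),
  six 90 s activities per day: 405,000 labelled samples, 67,500 per static
  posture, and per left-out participant 54,000 static + 27,000 dynamic
  test samples. Everything is deterministic given one seed
  (`numpy.SeedSequence` spawned per day).
* **Sit-to-stand stress protocol.** Four cycles of 1.2 s holds separated by
  1.5 s transition bursts (0.5 g, 2 Hz, 70° sweep) after a 60 s standing
  lead-in. The geometry guarantees a 3 s window always overlaps a
  transition while 0.5 s windows fit inside holds, which is exactly the
  window-size trade-off the static/dynamic classifier exhibits.

**What passing tests do and do not show.** The generator reproduces cluster
geometry, variability regimes, unknown mounts and protocol arithmetic; it
does not model soft-tissue or clothing slippage dynamics, realistic gait
harmonics, gravity-direction drift within a posture, or ambiguous
in-between postures (e.g. legs crossed). 100% benchmark accuracy therefore
demonstrates that the implementation realises the intended feature
geometry, not that the method would be error-free on naturalistic
recordings. One consequence: on transition-free extracted segments even
0.5 s windows classify perfectly, so the short-window degradation seen on
real data appears here only in the continuous sit-to-stand analysis.

## Problem sizes

Tests and the acceptance script run the full 15-day benchmark (405,000
samples); unit tests use 3-day, 20 s-segment miniatures of the same
generator. The permutation-null check uses a 40,000-sample subsample, whose
chance level for four balanced classes is 25%.

## Known limitations

* The arccos estimator folds angles into [0, 180]° and cannot separate
  forward from backward lean; the rotation-matrix (MARG) route that would
  lift this is out of scope.
* The optional second rotation into the sagittal plane is not implemented;
  it is unnecessary for θ_z-based classification.
* Angles are relative to the realised standing calibration pose (see
  above), so absolute posture-angle tables from different days are
  comparable only up to each day's standing posture.
* Gyroscope/magnetometer channels, upper-body sensors and video/diary
  synchronisation are out of scope; diary comparison is supported only as
  a generic agreement matrix between two interval tracks.
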