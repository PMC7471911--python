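# Methods

`reamsim` models the force–displacement behavior of the human acetabulum
under surgical reaming and renders it in a volumetric haptic simulation.
This note records the models, the numerical choices and the reasons behind
them.

## The measurement model

A reaming test presses a hemispherical reamer into the acetabulum at a
constant feed rate while a biaxial test machine samples tool displacement,
axial force and axial torque at 100 Hz (0.01 s).  Tests are *static* (reamer
off: pure compression, no friction torque) or *dynamic* (reamer cutting:
force plus friction-induced torque).  Every test starts from a 20 N contact
force and stops at 800 N or 20 mm of displacement.  All internal units are
s / mm / N / Nm; `ReamingRecord` enforces a uniform, strictly increasing
time base and an identically zero torque channel for static tests.

Three exclusion rules mirror the failure modes seen in such experiments and
are applied verbatim by `validate_recording` (report-only, never mutating):

* **feed-rate variation** — the displacement/time slope over any 1 s window
  deviates from the nominal feed rate by more than ±20%.  The tolerance is
  generous against measurement jitter yet catches a feed-rate step change.
* **force breakout** — after building past 50 N, the force collapses below
  5% of its maximum for the final 2 s: the signature of a specimen breaking
  out of its embedding.
* **early termination** — the run ends before 10 mm of displacement, i.e.
  the cartilage was fully reamed too early for the record to be comparable.

## Signal conditioning

Dynamic records carry band-limited oscillations from the rotating tool on
top of the slow material response.  Each dataset gets its own cutoff from a
Fourier analysis of the linearly de-trended force channel:

1. Bins whose smoothed energy (5-bin moving average) reaches the mean bin
   energy are *active*.
2. The *base band* is the contiguous run of active bins from the bottom of
   the spectrum; holes up to 10 bins are tolerated.
3. If active content exists above the base band (a distinct oscillation
   band), the cutoff is placed mid-gap between the two bands; otherwise at
   2× the base-band edge.  The result is clipped to [1 Hz, 0.95 × Nyquist]
   and logged in the `SpectrumReport`.

The mean-bin-energy criterion makes the rule independent of record length:
both the base-band bins and the significance level scale with the bin count.
A plain cumulative-energy fraction was rejected because no single fraction
separates a smooth base from a distinct oscillation band across the curve
family (with two equal-energy components, every fraction below 50% pulls the
cutoff above the upper band).

Filtering is a zero-phase 4th-order Butterworth low-pass (forward–backward),
applied to force and torque only — displacement and time are passed through
bit-exactly, and zero phase matters because a displacement–force lag would
distort the material model.  Boundary handling extends both ends with a
cubic fitted to the adjacent 1 s of data before filtering: the stock
odd-reflection padding leaves edge transients of the order of the boundary
curvature (~0.2 N on a typical record), whereas the C²-continuous extension
passes a smooth in-band signal unchanged to below 10⁻⁶ N.  Static records
bypass filtering entirely (the reamer is off; there is nothing to remove).

Filtered channels are normalized with reference to the maximum vertical
displacement of each test (the value axis keeps physical units), duplicate
displacement samples are collapsed by averaging, and per-test-set envelopes
(pointwise max / mean / min across samples, linearly resampled to a common
512-point grid on [0, 1]) summarize the spectrum of occurring forces and
torques.

## The spline material model

The material model is an interpolating piecewise cubic
`s_i(d) = a_i (d−d_i)³ + b_i (d−d_i)² + c_i (d−d_i) + const_i` on knot
intervals of the normalized displacement axis, in two variants:

* **Natural cubic spline (C²)** — interpolation plus value/first/second-
  derivative continuity at interior knots leaves two degrees of freedom;
  natural closure (zero end curvature) is the least-assumptive standard
  choice.  The knot second derivatives come from the classical tridiagonal
  system (solved with a banded LAPACK call); two knots degenerate cleanly to
  the straight segment.
* **Cubic Hermite spline (C¹)** — values and first derivatives matched at
  both ends of each segment, no coupling across segments.  Slopes default to
  Fritsch–Butland monotonicity-preserving weighted harmonic means with
  one-sided three-point ends, which makes the interpolant overshoot-free on
  non-smooth data.  This realizes the claimed advantage of the Hermite
  variant: an interpolant that rings between knots is felt immediately as a
  force wobble in a haptic loop.

The error statistic is the max-norm relative error
`e_a = max |(v − v_approx)/v| × 100`.  Samples below 1% of the curve's
maximum are excluded: measured curves start at 0 N, where relative error is
undefined, and just above zero it is unstable.

**Adaptive knot selection** lowers a threshold on a knot-priority field
recursively (2% of the field maximum per step), takes the endpoints plus all
points above threshold as knots, fits, and stops when `e_a` meets the budget
— or when every point is a knot, where `e_a = 0`, so termination is
guaranteed, and knot sets are nested along the recursion, so tightening the
budget never yields fewer knots.  Two numerical choices differ from the
naive reading of "threshold the second derivative":

* the second derivative is estimated on a uniform stencil of at most 512
  points (resample → differentiate → interpolate back).  On records with
  10⁵+ samples, per-sample central differences measure sample-scale wiggle
  and boundary artifacts rather than curve shape, and the threshold rule
  degenerates (all knots collapse into a few boundary samples);
* the priority field is |f''| / max(|f|, floor) rather than |f''| alone.
  The error statistic is *relative*, so a fixed knot budget must resolve the
  curve wherever curvature is large compared to the local value; with an
  absolute field, any 12-knot model of a 0–800 N curve carries relative
  errors of hundreds of percent in the low-force region, and comparisons
  between interpolants there are decided by noise.

The same priority field, plus a spacing guard of half the average knot
spacing, drives the fixed-count selection used by `compare_models` when a
knot count (e.g. 12) is requested directly.

Evaluation clamps out-of-domain arguments to the nearest knot value — cubic
extrapolation explodes, and a haptic device must never receive an unbounded
force — and costs one binary search plus one cubic per sample (O(log N)); a
1,000-sample batch on a 12-knot model takes ~30 µs here, comfortably inside
a 1 ms haptic tick.  `scale_hardness` multiplies node values, slopes and
coefficients by a factor in [0.1, 10]: the interpolant is linear in its
coefficients, so all continuity invariants survive and the surgeon-facing
"machining hardness" becomes a free parameter.

## The volumetric stage

**Sphere packing.** The bone mesh is filled with non-overlapping spheres,
greedy largest-first: candidates are a regular grid of pitch `min_radius`
(aligned on the bounding-box center so symmetric optima are representable)
plus a jittered copy; each candidate's admissible radius is the minimum of
the radius cap, its exact distance to the mesh surface and its clearance
from placed spheres; the largest admissible sphere is placed until nothing
of at least `min_radius` fits.  The surface distance enters lazily — a
KD-tree against dense surface samples provides an upper bound for ranking,
and the exact point-to-triangle distance is computed only when a candidate
wins — so every placed sphere provably stays inside the mesh.  Non-overlap
matters beyond speed: the aggregate surface normal is only meaningful when
no geometric feature is counted twice.

Mesh queries (inside test, surface distance) are numba-compiled kernels over
the raw triangle array: a generalized-winding-number inside test (sum of
signed solid angles; |w| > ½ means inside, robust for watertight meshes) and
exact point–triangle distances with barycentric clamping.

**Contacts and force feedback.** The reamer is a hemispherical cutting
surface of radius R advanced along its axis; geometrically the tool is
treated as the full ball (the shank-side half never meets material in a cup
geometry, and one region keeps contact and removal mutually consistent).
For each sphere the tool ball intersects, the contact surface is the
spherical-cap area cut from that sphere (computed from the sphere–sphere
intersection; fully engulfed spheres count their whole area).  The contact
density is the cap-area-weighted mean of sphere densities — invariant under
uniform rescaling of the areas — and the surface normal is the normalized
area-weighted mean of tool-center-to-sphere directions.  The feedback force
is the spline model evaluated at `advance / depth_scale` (default 20 mm, the
protocol's total reaming depth), multiplied by the ratio of contact density
to the reference density, directed against the surface normal.
Multiplicative density modulation is the simplest form that leaves the
calibrated curve intact at uniform density.

**Material removal** deletes spheres fully inside the tool, splits partially
cut spheres larger than 2 × `min_radius` into eight octant children (radius
r/3, centers offset r/3 along the octant diagonals — fully inside the
parent, so children never collide with outside spheres; densities
inherited), and displaces smaller ones outward along the cut normal (at most
half a radius) before shrinking them to clear both the tool and their
neighbors; repaired spheres below 0.05 mm are dropped.  Total sphere volume
never increases, and per-step cost is bounded by the KD-tree neighborhood of
the tool, independent of the total sphere count — the complexity contract
standing in for a hardware-bound 1 kHz update rate.

**Density calibration.** Removal is purely geometric (densities modulate
force, not cutting), so the contact geometry along a fixed trajectory is
replayed once and cached as per-step, per-shell cap-area sums; the simulated
force is then *linear* in the densities and each swarm evaluation is a few
matrix products.  Densities are parameterized per radial shell around the
packing centroid (default 16 shells — the direction in which tissue
properties vary as the reamer digs from cartilage into subchondral bone); a
per-sphere mode would only add unidentifiable parameters at this sphere
count.  The optimizer is a plain global-best particle swarm (30 particles,
200 iterations, inertia 0.72, cognitive/social 1.49, densities bounded to
[0.1, 10] × reference) with two implementation choices that matter:

* the swarm flies in log₁₀-density space.  Densities are multiplicative and
  the bounds span two orders of magnitude; in linear space the shell
  sensitivities differ by ~10⁴ and the swarm stagnates at several percent
  mean force error, while the log parameterization reaches well below 1%;
* one initial particle sits exactly at the uniform reference density — the
  optimization starts from the uniform distribution and can only improve on
  it.  Velocities are clamped to 20% of the search range.

The objective is the mean absolute error [N] between simulated and target
force magnitudes over the trajectory steps with nonzero contact.

**The virtual experiment** packs a toy acetabular cup (outer radius 26 mm,
wall 12 mm, tool radius 20 mm), calibrates the densities against the Hermite
material model, then advances the reamer along −z in 0.25 mm steps to 10 mm,
alternating force feedback and removal, and reports the simulated trace, the
target trace and their mean relative error (skipping targets below 1% of the
maximum, the same floor as `e_a`), plus cumulative removed volume.

## The synthetic-data generator

Cadaveric recordings are not numerically published, so `synthdata` emulates
their structure.  Each planted curve is

* a monotone power-law rise (`stiffness · (d/20 mm)^2.2`, default 650 N at
  full depth) — forces that stay near zero early and grow nonlinearly;
* one localized force peak (Gaussian, 120 N, width 1.5 mm, at 35% of the
  depth range) — the characteristic local peak of reaming curves;
* a displacement-locked piecewise-linear material texture (6% relative,
  0.8 mm correlation length, deterministic per profile seed).  Real curves
  are non-uniform at the millimeter scale (cartilage thickness varies, the
  joint is not a perfect sphere); this texture is material structure, not
  noise — it survives, and must survive, the low-pass filter.  Without it
  the filtered curve is infinitely smooth and the cubic-vs-Hermite
  comparison loses its subject (the Hermite advantage exists only on
  non-smooth data);
* the 20 N contact preload: static tests keep it (nothing removes the
  contact), most dynamic tests start near 0 N because the running reamer
  clears the contact, and a 30% minority retain a preload decaying over
  2 mm;
* band-limited Gaussian jitter (10 N RMS in 5–30 Hz) on dynamic tests, plus
  a torque channel `0.3 · F · (reamer radius / 2)` with its own small jitter.

Runs truncate at 800 N or 20 mm, whichever comes first.  Cohorts mirror the
experimental design — one static plus two dynamic tests per specimen, the
second dynamic trial with a 2 mm larger reamer, per-specimen stiffness and
peak variability — and can plant the three exclusion defects at a requested
rate, recorded in a manifest so tests have ground truth.

What the generator does *not* emulate: anatomical geometry (the cup is an
idealized hemispherical shell), reamer rotation dynamics and vibration
physics, inter-channel noise correlation, pose-dependent effects (one
reaming angle only), and any biological covariates (age, sex, bone quality).
Passing tests therefore show that the pipeline recovers what it assumes —
smooth-plus-textured monotone curves with band-limited jitter — not that the
model is validated against cadaver tissue.

## Problem sizes and determinism

Unit tests run on short records (3–6 mm depth at fast feed) and small cups
(10 mm outer radius, ~300 spheres); the end-to-end checks use the default
protocol record (200,001 samples), a 24-specimen cohort, and cup packings of
~1,000–2,500 spheres — sizes chosen so the method's asymptotics are visible
while a full run of suite plus acceptance script stays under a few minutes.
All randomness flows through explicit integer seeds (`numpy.random.default_rng`);
packing, removal, calibration and the virtual experiment are bit-reproducible
for a given seed.

## Known limitations

* The cutoff heuristic assumes the oscillation band is spectrally separated
  from the material response; a tool whose vibration overlaps the base band
  would require the manual `--cutoff` override.
* `e_a` is extremely sensitive near its floor; reported max errors often sit
  just above the 1%-of-maximum exclusion boundary, and small changes in the
  floor move the reported number (not the fitted model).
* The Hermite-vs-cubic comparison at a fixed small knot count depends on the
  curve: across random generator seeds the Hermite model wins on roughly two
  thirds of default curves (and on the default profile itself), with both
  errors of the same order — consistent with a qualitative, not universal,
  superiority on non-smooth data.
* Splitting spheres into octant children loses ~70% of the parent volume by
  construction; removed-volume bookkeeping is therefore an upper bound on
  the "machined" volume, not a mass balance.
* Sphere density does not influence removal speed; the hook exists in the
  removal routine but the mapping from density to cutting rate is left
  undefined.
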