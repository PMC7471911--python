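# reamsim

A real-time material model of acetabulum reaming for haptic surgical
simulators.

Total hip arthroplasty begins by reaming the acetabulum — removing cartilage
and subchondral bone with a rotating hemispherical cutter — and the forces a
surgeon feels there are far beyond what commodity haptic devices render.
Training simulators with realistic force feedback need two things: an
analytical force/torque-vs-displacement model fast enough for a 1 kHz haptic
loop, and a volumetric representation of the bone that supports contact
queries and material removal at that rate.  `reamsim` implements both, plus
the signal pipeline that turns raw reaming-test recordings into material
curves and a synthetic-data generator that emulates the statistical
structure of cadaveric reaming tests so the whole pipeline is testable
without cadaver data.

## The model

Filtered, displacement-normalized force curves `f(d)`, `d ∈ [0, 1]`, are
interpolated by piecewise cubics on adaptively chosen knots `d_i`:

    s_i(d) = a_i (d − d_i)³ + b_i (d − d_i)² + c_i (d − d_i) + const_i

either as a **natural cubic spline** (C², knot curvatures from the classical
tridiagonal system) or as a **cubic Hermite spline** (C¹, Fritsch–Butland
monotone slopes, overshoot-free on non-smooth data).  Model quality is the
max-norm relative error

    e_a = max |(v − v_approx) / v| × 100 ,

and knots are inserted where |f″| / |f| is largest, recursively, until `e_a`
meets a requested budget.  Evaluation is a binary-search segment lookup plus
one cubic — microseconds per batch, well inside a 1 ms haptic tick.

For rendering, the bone mesh is filled with non-overlapping spheres; the
feedback force is the spline magnitude modulated by the cap-area-weighted
density of the contacted spheres, directed against their aggregate surface
normal.  The density field is calibrated by global-best particle swarm
optimization so that a virtual reaming pass reproduces the measured force
curve, and material removal deletes, splits or shrinks spheres under the
advancing tool.

## A worked example

`examples/03_compare_interpolants.py` fits both interpolants on 12 shared
knots of the default synthetic reaming curve (filtered and normalized):

```
12 shared knots at normalized displacements:
  [0.    0.063 0.127 0.182 0.399 0.56  0.659 0.739 0.781 0.859 0.939 1.   ]
natural cubic spline : e_a = 58.5% at 9.6 mm
cubic Hermite spline : e_a = 46.2% at 9.6 mm
```

The reaming curve is not smooth — tissue response varies at the millimeter
scale — and between knots the C² spline rings where the monotone Hermite
segments do not, so at equal knot budget the Hermite model approximates the
measured curve better.  That gap is why the material model uses Hermite
segments.

`examples/04_pack_calibrate_ream.py` runs the volumetric stage end to end on
a small cup:

```
cup mesh: 1024 faces, volume 3821 mm^3
packing: 263 non-overlapping spheres
PSO calibration: final objective 0.000 N mean absolute force error
virtual reaming: 16 steps to 4.0 mm, removed 1411 mm^3 of material
simulated vs target force trace: 0.00% mean relative error
force at final depth: simulated 34.1 N, target 34.1 N
```

The calibrated sphere densities make the simulated contact force track the
spline target along the whole advance while the tool removes material.

The other examples cover signal conditioning (`01`) and adaptive knot
selection with hardness scaling (`02`).  A thin CLI wraps the same stages:

```sh
reamsim synth --seed 1 --out data/
reamsim filter data/synthetic.csv --out data/filtered.csv
reamsim fit data/synthetic.csv --kind hermite --out data/model.json
reamsim simulate data/cup.stl data/model.json --out data/report.json
```

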