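"""Fit the spline material model with adaptive knot selection.

The filtered, displacement-normalized force curve is approximated by a cubic
Hermite spline whose knots are chosen recursively: a threshold on the curve's
second derivative is lowered until the max-norm relative error e_a drops
below the requested budget.  Fewer knots mean cheaper evaluation in the
haptic loop; the error budget controls the trade.
"""

import reamsim as rs

recording = rs.generate_recording(rs.CurveProfile(test_kind="dynamic2",
                                                  feed_rate=0.03, seed=7))
filtered, _ = rs.filter_recording(recording)
raw_curve = rs.normalize_curve(filtered, "force")

# resample to the standard 512-point analysis grid (the raw record has 66k
# samples; fitting against them reproduces sample-scale texture knot by knot)
env = rs.compute_envelopes([raw_curve], grid_size=512)
curve = rs.MaterialCurve(env.grid, env.average, "force", raw_curve.source_id)

for budget in (20.0, 10.0, 5.0):
    selection = rs.select_nodes(curve, desired_max_error=budget, kind="hermite")
    print(f"error budget {budget:5.1f}% -> {len(selection.node_indices):5d} knots, "
          f"achieved e_a {selection.achieved_max_error_percent:5.2f}% "
          f"at normalized displacement {selection.error_location:.3f}")

selection = rs.select_nodes(curve, desired_max_error=10.0, kind="hermite")
knots = curve.normalized_displacement[selection.node_indices]
values = curve.value[selection.node_indices]
model = rs.fit_hermite_spline(knots, values)
print(f"\nmodel: {model.n_segments} cubic segments; "
      f"force at half depth = {model(0.5):.1f} N")

harder = rs.scale_hardness(model, 1.5)
print(f"with hardness x1.5 (a stiffer acetabulum): {harder(0.5):.1f} N")
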