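"""The volumetric stage: sphere packing, density calibration, virtual reaming.

A toy acetabular cup is filled with non-overlapping spheres, the sphere
density field is calibrated by particle swarm optimization so the simulated
contact force matches the spline material model, and a virtual reamer then
advances into the cup, alternating force feedback and material removal.
A small cup keeps this demonstration around a minute; the method is the same
at full scale.
"""

import numpy as np

import reamsim as rs

# material model from the default protocol recording
recording = rs.generate_recording(rs.CurveProfile())
filtered, _ = rs.filter_recording(recording)
curve = rs.normalize_curve(filtered, "force")
model = rs.compare_models(curve, 12)["hermite"]["model"]

mesh = rs.generate_cup_mesh(outer_radius=13.0, cartilage_thickness=6.0,
                            resolution=32)
print(f"cup mesh: {len(mesh.faces)} faces, volume {mesh.volume:.0f} mm^3")

config = rs.VirtualExperimentConfig(
    tool_radius=10.0, max_depth=4.0, depth_step=0.25,
    min_sphere_radius=0.6, max_sphere_radius=1.5,
    pso=rs.PSOConfig(n_shells=8, seed=0))
report = rs.run_virtual_experiment(mesh, model, config, seed=1)

print(f"packing: {report.sphere_count} non-overlapping spheres")
print(f"PSO calibration: final objective "
      f"{report.convergence.best_objective:.3f} N mean absolute force error")
print(f"virtual reaming: {len(report.depths)} steps to {report.depths[-1]:.1f} mm, "
      f"removed {report.removed_volume[-1]:.0f} mm^3 of material")
print(f"simulated vs target force trace: "
      f"{report.mean_relative_error_percent:.2f}% mean relative error")
print("force at final depth: "
      f"simulated {report.simulated_force[-1]:.1f} N, "
      f"target {report.target_force[-1]:.1f} N")
assert np.all(np.diff(report.removed_volume) >= -1e-9)
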