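"""Synthetic reaming recordings and toy acetabulum meshes.

Cadaveric force/torque recordings of acetabulum reaming are not publicly
available as numbers, so this module emulates their statistical structure for
testing every stage of the pipeline:

* 100 Hz sampling (0.01 s), constant feed rate (0.07 mm/s static,
  0.01 / 0.03 mm/s dynamic), stop at 800 N force or 20 mm displacement,
  whichever comes first;
* a smooth, monotone nonlinear force rise from ~0 N with one characteristic
  local peak superimposed (a scaled power law plus a Gaussian bump);
* band-limited high-frequency jitter (5–30 Hz) on dynamic tests, none on
  static tests (reamer switched off);
* a torque channel generated from the force via a friction factor acting at
  an effective radius on the reamer surface, identically zero for static
  tests.

``generate_cohort`` mirrors the experimental design — one static plus two
dynamic tests per specimen — with per-specimen variability and, optionally,
planted invalid runs (feed-rate alteration, resin breakout, early
completion) so that the exclusion validator has true positives.
``generate_cup_mesh`` builds a watertight hemispherical cup solid standing in
for the acetabular cartilage/bone shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh
from scipy import signal as sps

from .errors import ParameterError
from .records import FEED_RATES, SAMPLE_DT, ReamingRecord


@dataclass
class CurveProfile:
    """Ground-truth shape parameters of one synthetic reaming test.

    The smooth base curve is ``stiffness * (d / max_depth)^exponent`` plus a
    Gaussian bump of the given amplitude/width at ``peak_location_fraction``
    of the depth range, modulated by a displacement-locked material texture.
    ``contact_preload`` is the 20 N contact force applied before each test:
    a static test (reamer off, nothing removed) keeps it as a baseline, while
    most dynamic tests start near 0 N because the running reamer clears the
    contact immediately — unless ``preload_retained`` is set, in which case
    the preload decays over ``preload_fade`` mm of cutting instead.
    """

    test_kind: str = "dynamic1"
    feed_rate: float = 0.01  # mm/s (0.01 | 0.03 dynamic, 0.07 static)
    max_depth: float = 20.0  # mm
    force_cap: float = 800.0  # N
    contact_preload: float = 20.0  # N
    stiffness: float = 650.0  # N reached by the power-law rise at max_depth
    rise_exponent: float = 2.2
    peak_location_fraction: float = 0.35
    peak_amplitude: float = 120.0  # N
    peak_width: float = 1.5  # mm
    jitter_amplitude: float = 10.0  # N RMS, dynamic tests only
    jitter_band: tuple = (5.0, 30.0)  # Hz
    texture_amplitude: float = 0.06  # relative, material inhomogeneity
    texture_scale: float = 0.8  # mm correlation length of the texture
    preload_retained: bool = False  # dynamic test keeps the contact preload
    preload_fade: float = 2.0  # mm over which a retained preload decays
    torque_jitter_amplitude: float = 0.05  # Nm RMS
    friction_coefficient: float = 0.3
    reamer_diameter: float = 52.0  # mm
    sample_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feed_rate not in FEED_RATES:
            raise ParameterError(f"feed_rate must be one of {FEED_RATES}")
        if not (0.0 < self.peak_location_fraction < 1.0):
            raise ParameterError("peak location fraction must lie in (0, 1)")
        nyquist = 0.5 / SAMPLE_DT
        if not (0.0 < self.jitter_band[0] < self.jitter_band[1] < nyquist):
            raise ParameterError("jitter band must lie below the Nyquist frequency")
        if self.max_depth <= 0 or self.force_cap <= 0:
            raise ParameterError("max_depth and force_cap must be positive")

    @property
    def is_static(self) -> bool:
        return self.test_kind == "static"


def static_profile(**kwargs) -> CurveProfile:
    """Convenience constructor for the static (reamer off) protocol."""
    kwargs.setdefault("test_kind", "static")
    kwargs.setdefault("feed_rate", 0.07)
    return CurveProfile(**kwargs)


def _material_texture(profile: CurveProfile, d: np.ndarray) -> np.ndarray:
    """Displacement-locked relative roughness of the tissue response.

    Real reaming curves are non-uniform at the millimeter scale (cartilage
    thickness varies, the joint is not a perfect sphere), so the planted
    curve carries a piecewise-linear random texture with correlation length
    ``texture_scale`` — a deterministic function of displacement for a given
    profile seed, hence identical no matter how the curve is sampled.  This
    texture is material structure, not noise: it survives (and must survive)
    the low-pass filter.
    """
    if profile.texture_amplitude <= 0.0:
        return np.zeros_like(d)
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 0x7e97]))
    half = profile.texture_scale / 2.0
    knots = np.arange(0.0, profile.max_depth + profile.texture_scale, half)
    control = rng.standard_normal(len(knots))
    return profile.texture_amplitude * np.interp(d, knots, control)


def base_curve(profile: CurveProfile, displacement: np.ndarray) -> np.ndarray:
    """The jitter-free force curve planted in a synthetic test [N].

    A monotone power-law rise to ``stiffness`` at full depth, one localized
    Gaussian force peak, and the profile's deterministic material texture.
    This is what the low-pass stage is expected to recover from a jittery
    dynamic recording.
    """
    d = np.asarray(displacement, dtype=float)
    rise = profile.stiffness * (d / profile.max_depth) ** profile.rise_exponent
    d_peak = profile.peak_location_fraction * profile.max_depth
    bump = profile.peak_amplitude * np.exp(-0.5 * ((d - d_peak) / profile.peak_width) ** 2)
    curve = (rise + bump) * (1.0 + _material_texture(profile, d))
    if profile.is_static:
        curve = curve + profile.contact_preload  # nothing removes the contact
    elif profile.preload_retained:
        curve = curve + profile.contact_preload * np.exp(-d / profile.preload_fade)
    return curve


def _band_limited_noise(n: int, rms: float, band: tuple, fs: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-passed to ``band`` and rescaled to the target RMS."""
    if rms <= 0.0 or n < 64:
        return np.zeros(n)
    pad = int(10.0 * fs)  # discard filter edge transients
    white = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(3, np.array(band) / (fs / 2.0), btype="bandpass", output="sos")
    shaped = sps.sosfiltfilt(sos, white)[pad:pad + n]
    scale = shaped.std()
    return shaped * (rms / scale) if scale > 0 else np.zeros(n)


def generate_recording(profile: CurveProfile,
                       rng: Optional[np.random.Generator] = None) -> ReamingRecord:
    """Synthesize one reaming test from its ground-truth profile.

    Displacement is feed_rate x time at 0.01 s steps; the run truncates at
    the force cap or the maximum depth, whichever is hit first.  Forces are
    clipped at 0 N (the machine cannot register tension in this protocol).
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    n = int(np.floor(profile.max_depth / (profile.feed_rate * SAMPLE_DT))) + 1
    time = np.arange(n) * SAMPLE_DT
    displacement = profile.feed_rate * time
    base = base_curve(profile, displacement)

    if profile.is_static:
        force = base.copy()
        torque = np.zeros(n)
    else:
        fs = 1.0 / SAMPLE_DT
        force = base + _band_limited_noise(n, profile.jitter_amplitude,
                                           profile.jitter_band, fs, rng)
        effective_radius_m = 0.5 * (profile.reamer_diameter / 2.0) / 1000.0
        torque = (profile.friction_coefficient * force * effective_radius_m
                  + _band_limited_noise(n, profile.torque_jitter_amplitude,
                                        profile.jitter_band, fs, rng))
    force = np.clip(force, 0.0, None)

    over = np.flatnonzero(force >= profile.force_cap)
    if over.size:
        stop = max(int(over[0]) + 1, 2)
        time, displacement = time[:stop], displacement[:stop]
        force, torque = force[:stop], torque[:stop]

    return ReamingRecord(sample_id=profile.sample_id, test_kind=profile.test_kind,
                         feed_rate=profile.feed_rate, reamer_diameter=profile.reamer_diameter,
                         time=time, displacement=displacement, force=force, torque=torque)


# ---------------------------------------------------------------------------
# cohort generation with planted defects
# ---------------------------------------------------------------------------

#: the three exclusion mechanisms the validator must recognize
DEFECT_KINDS = ("feed_alteration", "breakout", "early_completion")


@dataclass
class CohortManifest:
    """Planted ground truth of a synthetic cohort, for tests."""

    profiles: list = field(default_factory=list)  # CurveProfile per recording
    defects: list = field(default_factory=list)  # None or a DEFECT_KINDS entry


def _plant_defect(rec: ReamingRecord, kind: str,
                  rng: np.random.Generator) -> ReamingRecord:
    n = len(rec)
    if kind == "feed_alteration":
        # feed rate doubles mid-test: same time base, displacement slope break
        half = n // 2
        disp = rec.displacement.copy()
        disp[half:] = disp[half] + 2.0 * (rec.displacement[half:] - rec.displacement[half])
        return replace(rec, displacement=disp)
    if kind == "breakout":
        # specimen breaks out of the resin: force collapses to ~0 for the rest
        start = int(n * rng.uniform(0.5, 0.7))
        force = rec.force.copy()
        torque = rec.torque.copy()
        force[start:] = np.abs(rng.normal(0.0, 1.0, n - start))
        torque[start:] = 0.0 if rec.test_kind == "static" else torque[start:] * 0.01
        return rec.with_channels(force, torque)
    if kind == "early_completion":
        # cartilage fully reamed before 10 mm: truncate the run at 8 mm
        stop = int(np.searchsorted(rec.displacement, 8.0)) + 1
        stop = min(max(stop, 2), n)
        return replace(rec, time=rec.time[:stop], displacement=rec.displacement[:stop],
                       force=rec.force[:stop], torque=rec.torque[:stop])
    raise ParameterError(f"unknown defect kind {kind!r}")


def generate_cohort(n_specimens: int, invalid_fraction: float = 0.0,
                    seed: int = 0, max_depth: float = 20.0,
                    stiffness_range: tuple = (0.7, 1.3),
                    peak_amplitude_range: tuple = (0.6, 1.4)):
    """Synthesize a cohort: one static plus two dynamic tests per specimen.

    Per-specimen stiffness and peak size are drawn uniformly from the given
    multiplicative ranges; the two dynamic trials use the two dynamic feed
    rates and reamer diameters 2 mm apart.  ``invalid_fraction`` of all
    recordings receive one planted defect (cycled through the three exclusion
    mechanisms); the manifest records which.  Returns
    ``(records, CohortManifest)``.
    """
    if n_specimens < 1:
        raise ParameterError("need at least one specimen")
    if not (0.0 <= invalid_fraction < 1.0):
        raise ParameterError("invalid_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records, manifest = [], CohortManifest()

    for s in range(n_specimens):
        stiff = 650.0 * rng.uniform(*stiffness_range)
        peak_amp = 120.0 * rng.uniform(*peak_amplitude_range)
        peak_loc = rng.uniform(0.25, 0.5)
        diameter = float(rng.choice([48.0, 50.0, 52.0, 54.0]))
        dyn_feed = float(rng.choice([0.01, 0.03]))
        for k, kind in enumerate(("static", "dynamic1", "dynamic2")):
            profile = CurveProfile(
                test_kind=kind,
                feed_rate=0.07 if kind == "static" else dyn_feed,
                max_depth=max_depth,
                stiffness=stiff * (1.0 if kind != "dynamic2" else 1.1),
                peak_amplitude=peak_amp,
                peak_location_fraction=peak_loc,
                reamer_diameter=diameter + (2.0 if kind == "dynamic2" else 0.0),
                # a minority of dynamic tests keep the 20 N contact preload
                # (the reamer does not always clear the contact instantly)
                preload_retained=kind != "static" and rng.random() < 0.3,
                sample_id=f"S{s + 1:02d}-{kind}",
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            records.append(generate_recording(profile))
            manifest.profiles.append(profile)
            manifest.defects.append(None)

    n_invalid = int(round(invalid_fraction * len(records)))
    if n_invalid:
        picks = rng.choice(len(records), size=n_invalid, replace=False)
        for j, idx in enumerate(sorted(int(i) for i in picks)):
            kind = DEFECT_KINDS[j % len(DEFECT_KINDS)]
            records[idx] = _plant_defect(records[idx], kind, rng)
            manifest.defects[idx] = kind
    return records, manifest


# ---------------------------------------------------------------------------
# toy acetabulum geometry
# ---------------------------------------------------------------------------

def generate_cup_mesh(outer_radius: float = 26.0, cartilage_thickness: float = 5.0,
                      resolution: int = 48) -> trimesh.Trimesh:
    """Watertight hemispherical-cup solid standing in for the acetabulum.

    The solid is the lower-half shell between two concentric hemispheres
    (outer radius ``outer_radius``, inner radius ``outer_radius -
    cartilage_thickness``), closed by a flat annular rim in the z = 0 plane.
    The cavity opens toward +z; ``resolution`` is the azimuthal vertex count.
    """
    if not (0.0 < cartilage_thickness < outer_radius):
        raise ParameterError("need 0 < thickness < outer_radius")
    if resolution < 8:
        raise ParameterError("resolution must be at least 8")
    n_phi = int(resolution)
    n_theta = max(4, n_phi // 4)
    r_in = outer_radius - cartilage_thickness

    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    # polar angle measured downward from the equator: 0 (rim) .. pi/2 (pole)
    theta = np.linspace(0.0, np.pi / 2.0, n_theta + 1)[:-1]

    def hemisphere_vertices(radius):
        rings = []
        for t in theta:
            rho = radius * np.cos(t)
            z = -radius * np.sin(t)
            rings.append(np.column_stack([rho * np.cos(phi), rho * np.sin(phi),
                                          np.full(n_phi, z)]))
        return np.vstack(rings), np.array([0.0, 0.0, -radius])

    outer_v, outer_pole = hemisphere_vertices(outer_radius)
    inner_v, inner_pole = hemisphere_vertices(r_in)

    vertices = [outer_v, outer_pole[None, :], inner_v, inner_pole[None, :]]
    n_out = len(outer_v)
    off_in = n_out + 1
    idx_outer_pole = n_out
    idx_inner_pole = off_in + len(inner_v)
    vertices = np.vstack(vertices)

    faces = []

    def hemisphere_faces(offset, pole_index, outward):
        # outward=True: normals away from the origin (outer shell boundary)
        for i in range(n_theta - 1):
            for j in range(n_phi):
                a = offset + i * n_phi + j
                b = offset + i * n_phi + (j + 1) % n_phi
                c = offset + (i + 1) * n_phi + j
                d = offset + (i + 1) * n_phi + (j + 1) % n_phi
                if outward:
                    faces.extend([[a, c, b], [b, c, d]])
                else:
                    faces.extend([[a, b, c], [b, d, c]])
        last = offset + (n_theta - 1) * n_phi
        for j in range(n_phi):
            a = last + j
            b = last + (j + 1) % n_phi
            faces.append([a, pole_index, b] if outward else [a, b, pole_index])

    hemisphere_faces(0, idx_outer_pole, outward=True)
    hemisphere_faces(off_in, idx_inner_pole, outward=False)

    # annular rim in the z=0 plane joining the two equator rings, normal +z
    for j in range(n_phi):
        a_out, b_out = j, (j + 1) % n_phi
        a_in, b_in = off_in + j, off_in + (j + 1) % n_phi
        faces.extend([[a_out, b_out, a_in], [b_out, b_in, a_in]])

    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise ParameterError("cup construction produced a non-watertight mesh")
    return mesh
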