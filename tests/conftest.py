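"""Shared fixtures: synthetic recordings, curves, meshes and packings."""

import numpy as np
import pytest
from hypothesis import settings

import reamsim as rs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_dynamic_profile():
    """A fast-feed dynamic profile (short record) for unit tests."""
    return rs.CurveProfile(test_kind="dynamic2", feed_rate=0.03, max_depth=5.0,
                           stiffness=650.0, seed=42)


@pytest.fixture(scope="session")
def short_dynamic_recording(short_dynamic_profile):
    return rs.generate_recording(short_dynamic_profile)


@pytest.fixture(scope="session")
def default_dynamic_recording():
    """The default (20 mm, 0.01 mm/s) dynamic recording of the study protocol."""
    return rs.generate_recording(rs.CurveProfile())


@pytest.fixture(scope="session")
def filtered_short_curve(short_dynamic_recording):
    filtered, _ = rs.filter_recording(short_dynamic_recording)
    return rs.normalize_curve(filtered, "force")


@pytest.fixture(scope="session")
def small_cup_mesh():
    """A small toy cup so packing-based tests stay fast."""
    return rs.generate_cup_mesh(outer_radius=10.0, cartilage_thickness=4.0,
                                resolution=24)


@pytest.fixture(scope="session")
def small_packing(small_cup_mesh):
    return rs.pack_mesh(small_cup_mesh, 0.6, 1.5, seed=3)


@pytest.fixture()
def sine_recording():
    """100 Hz record whose force is a 2 Hz unit tone on a 100 N baseline."""
    t = np.arange(2000) * rs.SAMPLE_DT
    force = 100.0 + np.sin(2 * np.pi * 2.0 * t)
    return rs.ReamingRecord("tone", "dynamic1", 0.03, 52.0,
                            t, 0.03 * t, force, np.zeros_like(t))
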