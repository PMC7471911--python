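"""Core record types for reaming test data.

A reaming test presses a (possibly rotating) hemispherical reamer into the
acetabulum at a constant feed rate while a biaxial test machine logs tool
displacement, axial force and axial torque at 100 Hz.  ``ReamingRecord``
holds one such test; ``RunConfig`` collects every tunable of the analysis
pipeline.  All internal units are fixed to s / mm / N / Nm; any conversion
happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ParameterError, ValidationError

#: protocol sampling interval [s]
SAMPLE_DT = 0.01

#: the three test kinds: static (reamer off), and two dynamic trials with
#: successively larger reamers
TEST_KINDS = ("static", "dynamic1", "dynamic2")

#: nominal feed rates used in the test protocol [mm/s]
FEED_RATES = (0.01, 0.03, 0.07)


@dataclass
class ReamingRecord:
    """One reaming test: uniformly sampled time / displacement / force / torque.

    Invariants enforced on construction: equal-length vectors (>= 2), a
    strictly increasing time base with constant step, and an identically zero
    torque channel for static tests (with the reamer switched off no friction
    torque can arise).
    """

    sample_id: str
    test_kind: str
    feed_rate: float  # mm/s
    reamer_diameter: float  # mm
    time: np.ndarray  # s
    displacement: np.ndarray  # mm
    force: np.ndarray  # N
    torque: np.ndarray  # Nm

    #: relative tolerance on time-step uniformity
    _DT_RTOL = 1e-4

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)

        if self.test_kind not in TEST_KINDS:
            raise ValidationError(f"unknown test_kind {self.test_kind!r}")
        if self.feed_rate <= 0:
            raise ValidationError("feed_rate must be positive")

        n = len(self.time)
        if n < 2:
            raise ValidationError("recording needs at least 2 samples")
        for name in ("displacement", "force", "torque"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"channel {name!r} length != time length")

        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time must be strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > self._DT_RTOL * step:
            raise ValidationError("time step is not uniform")

        if self.test_kind == "static" and np.any(np.abs(self.torque) > 1e-9):
            raise ValidationError("static tests must have an all-zero torque channel")

    @property
    def dt(self) -> float:
        """Sampling interval [s]."""
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        """Sampling rate [Hz]."""
        return 1.0 / self.dt

    def __len__(self) -> int:
        return len(self.time)

    def with_channels(self, force: np.ndarray, torque: np.ndarray) -> "ReamingRecord":
        """Copy of the record with replaced force/torque channels."""
        return replace(self, force=np.asarray(force, float), torque=np.asarray(torque, float))


@dataclass
class PSOConfig:
    """Settings for the global-best particle swarm density calibration."""

    particles: int = 30
    iterations: int = 200
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    density_bounds: tuple = (0.1, 10.0)  # multiples of the reference density
    n_shells: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particles < 2 or self.iterations < 1 or self.n_shells < 1:
            raise ParameterError("PSO sizes must be positive")
        lo, hi = self.density_bounds
        if not (0 < lo < hi):
            raise ParameterError("density bounds must satisfy 0 < lo < hi")


#: admissible range for the machining-hardness multiplier
HARDNESS_RANGE = (0.1, 10.0)


@dataclass
class RunConfig:
    """All tunables of the pipeline, with the defaults used throughout.

    ``cutoff_override`` bypasses the spectral cutoff heuristic; errors are in
    percent of the measured value (max-norm relative error e_a);
    ``derivative_threshold_step`` is the per-recursion decrement of the
    second-derivative threshold, as a fraction of its maximum.
    """

    cutoff_override: Optional[float] = None  # Hz
    desired_max_error: float = 15.0  # percent
    derivative_threshold_step: float = 0.02
    normalization_grid_size: int = 512
    pso: PSOConfig = field(default_factory=PSOConfig)
    split_threshold_factor: float = 2.0  # x min_radius
    min_keep_radius: float = 0.05  # mm
    hardness_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff_override is not None and self.cutoff_override <= 0:
            raise ParameterError("cutoff_override must be positive")
        for name in ("desired_max_error", "derivative_threshold_step",
                     "normalization_grid_size", "split_threshold_factor",
                     "min_keep_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        lo, hi = HARDNESS_RANGE
        if not (lo <= self.hardness_scale <= hi):
            raise ParameterError(f"hardness_scale must lie in [{lo}, {hi}]")
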