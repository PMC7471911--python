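"""Signal conditioning: spectra, low-pass filtering, normalization, envelopes.

Dynamic reaming recordings carry high-frequency oscillations from the rotating
tool on top of the slow force build-up.  Each dataset gets a customized
low-pass filter: a Fourier analysis of the de-trended channel picks the
cutoff, and a zero-phase Butterworth filter removes the oscillations without
introducing a displacement-force lag that would distort the material model.
Static recordings bypass filtering (the reamer is switched off).

Filtered channels are then normalized with reference to the maximum vertical
displacement of each test, so that different samples can be compared on a
common dimensionless grid, and per-test-set envelopes (pointwise maximum /
average / minimum across samples) summarize the spectrum of occurring forces
and torques.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, ValidationError
from .records import ReamingRecord

#: default filter order of the zero-phase Butterworth low-pass
FILTER_ORDER = 4

#: moving-average width [bins] applied to the energy spectrum before the
#: active-band search
SMOOTH_BINS = 5

#: a bin is "active" when its smoothed energy reaches the mean bin energy
ACTIVE_BIN_FACTOR = 1.0

#: holes up to this many bins do not terminate the base band
GAP_BINS = 10

#: cutoff = margin x base-band edge when no separate oscillation band exists
CUTOFF_MARGIN = 2.0

#: fallback cutoff [Hz] for signals with no spectral content (constant force)
CUTOFF_FLOOR = 1.0


@dataclass
class SpectrumReport:
    """Magnitude spectrum of a de-trended channel and the chosen cutoff."""

    frequencies: np.ndarray  # Hz
    amplitudes: np.ndarray  # channel units
    chosen_cutoff: float  # Hz, strictly inside (0, Nyquist)
    channel: str = "force"


@dataclass
class MaterialCurve:
    """A force or torque curve on a normalized, strictly increasing grid.

    ``normalized_displacement`` spans [0, 1] with the last point exactly 1
    (displacement divided by the test's maximum vertical displacement).
    """

    normalized_displacement: np.ndarray
    value: np.ndarray  # N (force) or Nm (torque)
    channel: str  # "force" | "torque"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.normalized_displacement = np.asarray(self.normalized_displacement, float)
        self.value = np.asarray(self.value, float)
        if self.normalized_displacement.shape != self.value.shape:
            raise ValidationError("grid and value vectors must have equal length")
        if np.any(np.diff(self.normalized_displacement) <= 0):
            raise ValidationError("normalized displacement must be strictly increasing")
        if self.channel not in ("force", "torque"):
            raise ValidationError(f"unknown channel {self.channel!r}")


@dataclass
class EnvelopeSet:
    """Pointwise max/avg/min of a set of curves on a common [0, 1] grid."""

    grid: np.ndarray
    maximum: np.ndarray
    average: np.ndarray
    minimum: np.ndarray
    channel: str = "force"
    n_curves: int = 0


def compute_spectrum(rec: ReamingRecord, channel: str = "force",
                     cutoff_floor: float = CUTOFF_FLOOR,
                     gap_bins: int = GAP_BINS,
                     margin: float = CUTOFF_MARGIN) -> SpectrumReport:
    """Fourier analysis of a channel and per-dataset cutoff choice.

    The channel is linearly de-trended and its one-sided magnitude spectrum
    computed.  The cutoff heuristic separates the slow material response from
    tool-induced oscillations by band structure: bins whose (smoothed) energy
    reaches the mean bin energy are "active"; the base band is the contiguous
    run of active bins from the bottom of the spectrum (holes up to
    ``gap_bins`` tolerated).  If further active content exists above the base
    band (a distinct oscillation band), the cutoff is placed in the middle of
    the gap between them; otherwise at ``margin`` times the base-band edge.
    The choice is logged in the report and can always be overridden.
    """
    if channel not in ("force", "torque"):
        raise ParameterError(f"unknown channel {channel!r}")
    if rec.test_kind == "static" and channel == "torque":
        raise ParameterError("static tests have no torque signal to analyze")
    y = getattr(rec, channel)
    if len(y) < 16:
        raise ParameterError("need at least 16 samples for a spectrum")
    fs = rec.sampling_rate
    nyquist = fs / 2.0
    ceiling = 0.95 * nyquist

    y_detrended = sps.detrend(y, type="linear")
    amp = np.abs(np.fft.rfft(y_detrended)) / len(y)
    freqs = np.fft.rfftfreq(len(y), d=rec.dt)
    energy = amp ** 2
    energy[0] = 0.0  # DC removed by the detrend; guard residue
    total = float(energy.sum())

    if total <= 1e-20 * max(1.0, float(np.max(np.abs(y))) ** 2):
        # constant / purely linear channel: nothing to separate
        cutoff = min(max(cutoff_floor, freqs[1]), ceiling)
        return SpectrumReport(freqs, amp, float(cutoff), channel)

    smoothed = np.convolve(energy, np.ones(SMOOTH_BINS) / SMOOTH_BINS, mode="same")
    mean_bin = total / (len(energy) - 1)
    active = np.flatnonzero(smoothed >= ACTIVE_BIN_FACTOR * mean_bin)

    edge = active[0]
    for k in active[1:]:
        if k - edge <= gap_bins:
            edge = k
        else:
            break
    f_edge = freqs[edge]
    above = active[active > edge]
    if above.size:
        cutoff = 0.5 * (f_edge + freqs[above[0]])  # mid-gap between bands
    else:
        cutoff = margin * f_edge
    cutoff = min(max(cutoff, cutoff_floor, freqs[1]), ceiling)
    return SpectrumReport(freqs, amp, float(cutoff), channel)


def _zero_phase(sos, y: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Forward-backward filtering with cubic-extension padding.

    The stock odd-reflection padding leaves edge transients of order of the
    boundary curvature; extending both ends with a cubic fitted to the
    adjacent second of data makes the extension C2-continuous, so a smooth
    in-band signal passes through essentially unchanged right up to the
    boundary.
    """
    deg = 3
    n_fit = int(min(max(deg + 3, round(1.0 * fs)), max(deg + 3, len(y) // 4)))
    n_pad = int(min(max(round(20.0 / cutoff * fs), 4 * n_fit), 4 * len(y)))
    i = np.arange(n_fit)
    left = np.polyval(np.polyfit(i, y[:n_fit], deg), np.arange(-n_pad, 0))
    right = np.polyval(np.polyfit(i, y[-n_fit:], deg),
                       np.arange(n_fit, n_fit + n_pad))
    padded = np.concatenate([left, y, right])
    return sps.sosfiltfilt(sos, padded, padlen=0)[n_pad:n_pad + len(y)]


def lowpass_filter(rec: ReamingRecord, cutoff: float,
                   order: int = FILTER_ORDER) -> ReamingRecord:
    """Zero-phase Butterworth low-pass of the force and torque channels.

    Time and displacement are returned bit-exactly; forward-backward
    application doubles the attenuation and cancels the phase so forces stay
    aligned with displacement.  DC gain is 1.
    """
    nyquist = rec.sampling_rate / 2.0
    if not (0.0 < cutoff < nyquist):
        raise ParameterError(f"cutoff must lie in (0, {nyquist}) Hz")
    sos = sps.butter(order, cutoff / nyquist, btype="low", output="sos")
    force = _zero_phase(sos, rec.force, rec.sampling_rate, cutoff)
    if rec.test_kind == "static":
        torque = rec.torque  # identically zero by invariant
    else:
        torque = _zero_phase(sos, rec.torque, rec.sampling_rate, cutoff)
    return rec.with_channels(force, torque)


def filter_recording(rec: ReamingRecord, cutoff: Optional[float] = None):
    """Per-dataset conditioning step: pick a cutoff and low-pass the record.

    Static records are passed through unchanged (the reamer is off, there is
    nothing to remove).  Returns ``(filtered_record, SpectrumReport | None)``.
    """
    if rec.test_kind == "static":
        return rec, None
    report = compute_spectrum(rec, "force")
    chosen = cutoff if cutoff is not None else report.chosen_cutoff
    return lowpass_filter(rec, chosen), report


def normalize_curve(rec: ReamingRecord, channel: str = "force") -> MaterialCurve:
    """Displacement-normalized material curve of one (filtered) recording.

    The displacement axis is divided by the test's maximum vertical
    displacement so different samples share the domain [0, 1]; the value axis
    keeps physical units.  Samples at identical displacement are collapsed by
    averaging the value channel, making the output grid strictly increasing.
    """
    if channel not in ("force", "torque"):
        raise ParameterError(f"unknown channel {channel!r}")
    disp = rec.displacement
    if np.any(np.diff(disp) < 0):
        raise ValidationError("displacement must be monotonically non-decreasing")
    dmax = float(disp[-1])
    if dmax <= 0:
        raise ValidationError("maximum displacement must be positive")
    y = getattr(rec, channel)

    grid, inverse = np.unique(disp, return_inverse=True)
    if len(grid) < 2:
        raise ValidationError("displacement is constant over the whole test")
    sums = np.bincount(inverse, weights=y, minlength=len(grid))
    counts = np.bincount(inverse, minlength=len(grid))
    values = sums / counts

    norm = grid / dmax
    norm[-1] = 1.0  # exact by construction; guard float division
    return MaterialCurve(norm, values, channel=channel, source_id=rec.sample_id)


def compute_envelopes(curves: Sequence[MaterialCurve],
                      grid_size: int = 512) -> EnvelopeSet:
    """Pointwise maximum / average / minimum across curves of one test set.

    Every curve is linearly resampled onto a common uniform grid on [0, 1]
    (each curve covers the full domain by construction, so no extrapolation
    occurs) and the envelope statistics are taken per grid point.
    """
    if len(curves) == 0:
        raise ParameterError("need at least one curve")
    channels = {c.channel for c in curves}
    if len(channels) > 1:
        raise ParameterError("cannot mix force and torque curves in one envelope")
    if grid_size < 2:
        raise ParameterError("grid_size must be at least 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    stack = np.vstack([
        np.interp(grid, c.normalized_displacement, c.value) for c in curves
    ])
    return EnvelopeSet(grid=grid,
                       maximum=stack.max(axis=0),
                       average=stack.mean(axis=0),
                       minimum=stack.min(axis=0),
                       channel=channels.pop(),
                       n_curves=len(curves))
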