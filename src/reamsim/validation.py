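"""Data-exclusion rules for reaming recordings.

In the physical test series a sixth of the data sets had to be excluded; the
three observed failure modes become report-only validators here:

* ``feed_rate_variation`` — the feed rate, estimated from the displacement/
  time slope over 1 s windows, deviates from the nominal rate by more than
  20% somewhere during the run (machine feed alteration);
* ``force_breakout`` — the force collapses to near zero well before the
  protocol end after having built up, the signature of a specimen breaking
  out of its resin embedding;
* ``early_termination`` — the run ends before 10 mm of displacement, i.e. the
  cartilage was reamed completely too early for the record to be comparable.

Validation is pure: the recording is never modified, the report only lists
the triggered rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ReamingRecord

#: allowed relative deviation of the windowed feed-rate estimate
FEED_RATE_TOLERANCE = 0.20

#: window length for the feed-rate estimate [s]
FEED_RATE_WINDOW = 1.0

#: a run must reach at least this displacement to count as complete [mm]
MIN_DISPLACEMENT = 10.0

#: breakout detection: force must first exceed this level [N] ...
BREAKOUT_MIN_PEAK = 50.0
#: ... and then fall below this fraction of its maximum over the final window
BREAKOUT_FLOOR_FRACTION = 0.05
#: length of the final window inspected for a collapsed force [s]
BREAKOUT_TAIL = 2.0


@dataclass
class ValidityReport:
    """Outcome of the exclusion rules for one recording."""

    valid: bool
    triggered_rules: list = field(default_factory=list)
    details: dict = field(default_factory=dict)


def _feed_rate_varies(rec: ReamingRecord) -> tuple:
    w = max(2, int(round(FEED_RATE_WINDOW / rec.dt)))
    if len(rec) <= w:
        return False, {}
    disp = rec.displacement
    time = rec.time
    starts = np.arange(0, len(rec) - w, max(1, w // 2))
    slopes = (disp[starts + w] - disp[starts]) / (time[starts + w] - time[starts])
    deviation = np.abs(slopes - rec.feed_rate) / rec.feed_rate
    worst = float(deviation.max())
    return worst > FEED_RATE_TOLERANCE, {"max_feed_rate_deviation": worst}


def _force_breaks_out(rec: ReamingRecord) -> tuple:
    fmax = float(np.max(rec.force))
    if fmax < BREAKOUT_MIN_PEAK:
        return False, {}
    tail = max(2, int(round(BREAKOUT_TAIL / rec.dt)))
    tail_level = float(np.mean(rec.force[-tail:]))
    collapsed = tail_level < BREAKOUT_FLOOR_FRACTION * fmax
    return collapsed, {"final_force_fraction": tail_level / fmax}


def validate_recording(rec: ReamingRecord) -> ValidityReport:
    """Apply the three exclusion rules and report which ones triggered."""
    triggered, details = [], {}

    varies, info = _feed_rate_varies(rec)
    details.update(info)
    if varies:
        triggered.append("feed_rate_variation")

    breaks, info = _force_breaks_out(rec)
    details.update(info)
    if breaks:
        triggered.append("force_breakout")

    reached = float(np.max(rec.displacement))
    details["max_displacement_mm"] = reached
    if reached < MIN_DISPLACEMENT:
        triggered.append("early_termination")

    return ValidityReport(valid=not triggered, triggered_rules=triggered,
                          details=details)
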