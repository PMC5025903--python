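"""Gait-phase timeline and real-time stimulation warping (offline simulation).

Six gait phases are delimited by the initial contact (IC), end contact (EC)
and mid-swing (MS) events of the two legs:

====== ===================================  =========================
phase  interval                             name
====== ===================================  =========================
1      paretic IC    -> non-paretic EC      paretic double support
2      non-paretic EC -> non-paretic MS     non-paretic initial swing
3      non-paretic MS -> non-paretic IC     non-paretic terminal swing
4      non-paretic IC -> paretic EC         non-paretic double support
5      paretic EC    -> paretic MS          paretic initial swing
6      paretic MS    -> paretic IC          paretic terminal swing
====== ===================================  =========================

On entry into a new phase the controller re-estimates that phase's duration
as the mean over the last five strides and stretches or compresses the
matching segment of the 100-point stimulation template so the stimulation
follows the subject's actual gait timing. The simulation here replays this
behaviour causally on a recorded event stream: stride k is warped with
estimates from completed strides only.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envelope import N_CYCLE_POINTS
from .errors import InvalidParameterError, SequenceViolationError
from .stimulation import StimulationStrategy, to_pulse_width

PHASE_NAMES = {
    1: "paretic double support",
    2: "non-paretic initial swing",
    3: "non-paretic terminal swing",
    4: "non-paretic double support",
    5: "paretic initial swing",
    6: "paretic terminal swing",
}

# event (side, type) ending each phase, in cyclic order starting from the
# paretic IC that opens phase 1
_PHASE_END_EVENTS = [
    ("nonparetic", "EC"),  # ends phase 1
    ("nonparetic", "MS"),
    ("nonparetic", "IC"),
    ("paretic", "EC"),
    ("paretic", "MS"),
    ("paretic", "IC"),  # ends phase 6, opens the next stride
]

__all__ = [
    "GaitEvent",
    "GaitEventStream",
    "Phase",
    "PhaseTimeline",
    "PhaseDurationEstimator",
    "phases_from_events",
    "warp_profile",
    "simulate_session",
    "PHASE_NAMES",
]


@dataclass(frozen=True)
class GaitEvent:
    time_s: float
    type: str  # IC, EC, MS
    side: str  # paretic, nonparetic


@dataclass
class GaitEventStream:
    events: list[GaitEvent]

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidParameterError("event times must be strictly increasing")
        for e in self.events:
            if e.type not in ("IC", "EC", "MS") or e.side not in ("paretic", "nonparetic"):
                raise InvalidParameterError(f"invalid event {e}")

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time_s, e.type, e.side) for e in self.events],
            columns=["time_s", "event", "side"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GaitEventStream":
        return cls([
            GaitEvent(float(r.time_s), str(r.event), str(r.side))
            for r in df.itertuples(index=False)
        ])


@dataclass
class Phase:
    phase_id: int
    start_s: float
    duration_s: float


@dataclass
class PhaseTimeline:
    phases: list[Phase] = field(default_factory=list)

    @property
    def n_strides(self) -> int:
        return len(self.phases) // 6

    def durations_by_stride(self) -> np.ndarray:
        """n_strides x 6 array of phase durations."""
        n = self.n_strides
        return np.array(
            [[self.phases[6 * k + p].duration_s for p in range(6)] for k in range(n)]
        )


def phases_from_events(stream: GaitEventStream) -> PhaseTimeline:
    """Decode a gait-event stream into the cyclic 6-phase timeline.

    The stream must begin at (or after) a paretic IC; any deviation from the
    expected event order raises, naming the expected event.
    """
    events = list(stream.events)
    # advance to the first paretic IC
    start = next(
        (i for i, e in enumerate(events) if e.type == "IC" and e.side == "paretic"),
        None,
    )
    if start is None:
        raise SequenceViolationError("stream contains no paretic IC to start from")
    events = events[start:]
    timeline = PhaseTimeline()
    t_prev = events[0].time_s
    idx = 1
    phase_pos = 0  # index into _PHASE_END_EVENTS
    stride_phases: list[Phase] = []
    while idx < len(events):
        exp_side, exp_type = _PHASE_END_EVENTS[phase_pos]
        e = events[idx]
        if (e.side, e.type) != (exp_side, exp_type):
            raise SequenceViolationError(
                f"expected {exp_side} {exp_type} at t={e.time_s:.3f}s, "
                f"got {e.side} {e.type}"
            )
        duration = e.time_s - t_prev
        if duration <= 0:
            raise SequenceViolationError(f"nonpositive phase duration at t={e.time_s:.3f}s")
        stride_phases.append(Phase(phase_pos + 1, t_prev, duration))
        t_prev = e.time_s
        phase_pos += 1
        idx += 1
        if phase_pos == 6:
            timeline.phases.extend(stride_phases)
            stride_phases = []
            phase_pos = 0
    return timeline


class PhaseDurationEstimator:
    """Per-phase moving average over the last five strides."""

    def __init__(self, window: int = 5):
        self.window = window
        self.history: dict[int, deque] = {p: deque(maxlen=window) for p in range(1, 7)}

    def update(self, phase_id: int, duration_s: float) -> float:
        """Push a completed phase duration; returns the refreshed estimate."""
        if duration_s <= 0:
            raise InvalidParameterError(f"phase duration must be positive, got {duration_s}")
        self.history[phase_id].append(duration_s)
        return self.estimate(phase_id)

    def estimate(self, phase_id: int) -> float:
        h = self.history[phase_id]
        if not h:
            raise InvalidParameterError(f"no history for phase {phase_id}")
        return float(np.mean(h))

    def has_history(self) -> bool:
        return all(len(h) > 0 for h in self.history.values())

    def estimates(self) -> np.ndarray:
        return np.array([self.estimate(p) for p in range(1, 7)])


def _segment_boundaries(bounds: np.ndarray, n_points: int = N_CYCLE_POINTS) -> np.ndarray:
    bounds = np.asarray(bounds, dtype=float)
    if bounds.size != 6 or np.any(bounds <= 0) or abs(bounds.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("phase bounds must be 6 positive fractions summing to 1")
    idx = np.rint(np.cumsum(bounds) * n_points).astype(int)
    idx[-1] = n_points
    starts = np.concatenate([[0], idx[:-1]])
    if np.any(idx - starts < 1):
        raise InvalidParameterError("a phase maps to fewer than one template point")
    return np.concatenate([[0], idx])


def warp_profile(
    template: np.ndarray,
    template_phase_bounds,
    phase_durations_s,
    out_rate: float,
) -> np.ndarray:
    """Warp a 100-point template onto actual phase durations.

    The template is split into six segments at the phase bounds; each segment
    is linearly resampled to ``round(duration * out_rate)`` samples and the
    segments are concatenated, so lengthening one phase stretches only that
    phase's stimulation. A phase so short that it maps to zero samples is
    skipped with a warning.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != (N_CYCLE_POINTS,):
        raise InvalidParameterError(f"template must have {N_CYCLE_POINTS} points")
    durations = np.asarray(phase_durations_s, dtype=float)
    if durations.size != 6 or np.any(durations <= 0):
        raise InvalidParameterError("need 6 positive phase durations")
    if out_rate <= 0:
        raise InvalidParameterError("out_rate must be positive")
    cuts = _segment_boundaries(template_phase_bounds)
    pieces = []
    for p in range(6):
        seg = template[cuts[p] : cuts[p + 1]]
        n_out = int(np.rint(durations[p] * out_rate))
        if n_out == 0:
            warnings.warn(
                f"phase {p + 1} duration {durations[p]:.3f}s maps to 0 samples at "
                f"{out_rate:g} Hz; segment skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        x_new = np.linspace(0.0, len(seg) - 1.0, n_out)
        pieces.append(np.interp(x_new, np.arange(len(seg), dtype=float), seg))
    return np.concatenate(pieces) if pieces else np.empty(0)


def simulate_session(
    strategy: StimulationStrategy,
    stream: GaitEventStream,
    out_rate: float | None = None,
) -> pd.DataFrame:
    """Offline replay of the real-time controller on a recorded event stream.

    Per stride: take the per-phase duration estimates (means of the last five
    completed strides; the first stride falls back to the template phase
    proportions scaled to its observed cycle time), warp each channel's
    template, and emit pulse-width commands at the stimulation frequency.
    Returns the command log as a DataFrame with columns
    ``time_s, channel, pulse_width_us, amplitude_ma, frequency_hz``.
    """
    if out_rate is None:
        out_rate = strategy.frequency_hz
    timeline = phases_from_events(stream)
    estimator = PhaseDurationEstimator()
    rows = []
    bounds = np.asarray(strategy.template_phase_bounds, dtype=float)
    for k in range(timeline.n_strides):
        stride = timeline.phases[6 * k : 6 * (k + 1)]
        cycle = sum(p.duration_s for p in stride)
        if estimator.has_history():
            durations = estimator.estimates()
        else:
            durations = bounds * cycle  # first stride: template proportions
        t0 = stride[0].start_s
        for ch in strategy.channels:
            warped = warp_profile(ch.profile, bounds, durations, out_rate)
            pw = to_pulse_width(np.clip(warped, 0.0, 1.0), strategy.pw_max_us)
            for i, w in enumerate(pw):
                rows.append(
                    (k, t0 + i / out_rate, ch.name, int(w), ch.amplitude_ma, strategy.frequency_hz)
                )
        for p in stride:
            estimator.update(p.phase_id, p.duration_s)
    df = pd.DataFrame(
        rows,
        columns=["stride", "time_s", "channel", "pulse_width_us", "amplitude_ma", "frequency_hz"],
    )
    return df.sort_values(["stride", "time_s", "channel"], kind="stable").reset_index(drop=True)
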