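"""Online task rules: feedback classification, the reaction-time-threshold
calibration staircase, practice-block gating and screen-delay adjustment.

Timing limits (all in milliseconds): a reach faster than 10 ms or slower
than 275 ms forfeits the point and draws a negative tone; movement times
above 600 ms or reaction times above 1000 ms additionally trigger an
on-screen warning.  In limited-preparation-time conditions a point further
requires the reaction time to beat a per-participant threshold that is
calibrated by a +/-5 ms staircase bounded to [280, 350] ms.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MT_TOO_FAST_MS = 10.0
MT_TOO_SLOW_MS = 275.0
MT_WARNING_MS = 600.0
RT_WARNING_MS = 1000.0

RT_THRESHOLD_FLOOR_MS = 280.0
RT_THRESHOLD_CEILING_MS = 350.0
RT_THRESHOLD_INITIAL_MS = 350.0
RT_THRESHOLD_STEP_MS = 5.0
RT_WINDOW = 10
RT_WINDOW_CRITERION = 8

SCREEN_DELAY_MS = 154.0
PRACTICE_PASS_FRACTION = 0.65
PRACTICE_ANGLE_LIMIT_DEG = 30.0
CALIBRATION_TRIALS = 84

# Display geometry (fractions of total screen size): start circle 0.015%,
# target circle 0.04%, radial displacement 10x the target size.  A terminal
# cursor position overlaps the target when the reach angle is within
# asin(target_radius / displacement) = asin(1/20) of the target direction.
HIT_WINDOW_DEG = float(np.degrees(np.arcsin(0.05)))


class Timing(str, enum.Enum):
    TOO_FAST = "too_fast"
    TOO_SLOW = "too_slow"
    OK = "ok"


class Warning_(str, enum.Enum):
    NONE = "none"
    MOVE_FASTER = "move_faster"
    REACT_FASTER = "react_faster"


class Tone(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class FeedbackOutcome:
    timing: Timing
    hit: bool
    point_awarded: bool
    warning: Warning_
    tone: Tone


def classify_trial(
    movement_time_ms: float,
    reaction_time_ms: float,
    angular_error_deg: float,
    rt_limited: bool = False,
    rt_threshold_ms: float | None = None,
    hit_window_deg: float = HIT_WINDOW_DEG,
) -> FeedbackOutcome:
    """Classify one trial's outcome per the online feedback rules.

    A point is awarded only when the movement lands inside the target
    (``|angular_error_deg| <= hit_window_deg``) at a valid speed; under
    ``rt_limited`` the reaction time must additionally be at or below
    ``rt_threshold_ms`` (the reach still completes and feedback is shown,
    but no point can be scored).
    """
    if movement_time_ms < 0 or reaction_time_ms < 0:
        raise ValueError("times must be >= 0")
    if rt_limited and rt_threshold_ms is None:
        raise ValueError("rt_threshold_ms required when rt_limited")
    hit = abs(angular_error_deg) <= hit_window_deg

    if movement_time_ms < MT_TOO_FAST_MS:
        timing = Timing.TOO_FAST
    elif movement_time_ms > MT_TOO_SLOW_MS:
        timing = Timing.TOO_SLOW
    else:
        timing = Timing.OK

    warning = Warning_.NONE
    if movement_time_ms > MT_WARNING_MS:
        warning = Warning_.MOVE_FASTER
    elif reaction_time_ms > RT_WARNING_MS:
        warning = Warning_.REACT_FASTER

    point = timing is Timing.OK and hit
    if rt_limited and reaction_time_ms > rt_threshold_ms:
        point = False
        if warning is Warning_.NONE:
            warning = Warning_.REACT_FASTER
    tone = Tone.POSITIVE if point else Tone.NEGATIVE
    return FeedbackOutcome(timing=timing, hit=hit, point_awarded=point, warning=warning, tone=tone)


def practice_pass(
    movement_times_ms, reaction_times_ms, angle_errors_deg
) -> bool:
    """Gate from the practice block to the experiment.

    True iff strictly more than 65% of practice trials are successful, a
    success being MT < 600 ms, RT < 1000 ms and a reach within +/-30 degrees
    of the target.
    """
    n = len(movement_times_ms)
    if n == 0 or not (n == len(reaction_times_ms) == len(angle_errors_deg)):
        raise ValueError("inputs must be non-empty and of equal length")
    ok = sum(
        mt < MT_WARNING_MS and rt < RT_WARNING_MS and abs(err) <= PRACTICE_ANGLE_LIMIT_DEG
        for mt, rt, err in zip(movement_times_ms, reaction_times_ms, angle_errors_deg)
    )
    return ok / n > PRACTICE_PASS_FRACTION


@dataclass
class RTThresholdState:
    """State of the reaction-time threshold staircase.

    The window holds the success flags of the last ``RT_WINDOW`` trials.
    Once full, every subsequent trial moves the threshold down 5 ms when 8
    or more of the windowed trials were successful and up 5 ms otherwise
    (sliding-window mode, the default; set ``block_mode=True`` for an
    update only every 10th trial on non-overlapping blocks).  The threshold
    is clamped to [280, 350] ms at all times.
    """

    threshold_ms: float = RT_THRESHOLD_INITIAL_MS
    floor_ms: float = RT_THRESHOLD_FLOOR_MS
    ceiling_ms: float = RT_THRESHOLD_CEILING_MS
    block_mode: bool = False
    window: deque = field(default_factory=lambda: deque(maxlen=RT_WINDOW))
    history: list[float] = field(default_factory=list)
    successes: list[bool] = field(default_factory=list)
    frozen: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Calibration trace as a tidy table (trial, threshold_ms, success)."""
        return pd.DataFrame(
            {
                "trial": range(1, len(self.history) + 1),
                "threshold_ms": self.history,
                "success": self.successes,
            }
        )


def update_rt_threshold(state: RTThresholdState, trial_success: bool) -> RTThresholdState:
    """Advance the staircase by one trial (mutates and returns ``state``)."""
    state.window.append(bool(trial_success))
    state.successes.append(bool(trial_success))
    full = len(state.window) == RT_WINDOW
    due = full and (not state.block_mode or len(state.successes) % RT_WINDOW == 0)
    if due and not state.frozen:
        if sum(state.window) >= RT_WINDOW_CRITERION:
            state.threshold_ms -= RT_THRESHOLD_STEP_MS
        else:
            state.threshold_ms += RT_THRESHOLD_STEP_MS
        state.threshold_ms = min(max(state.threshold_ms, state.floor_ms), state.ceiling_ms)
    state.history.append(state.threshold_ms)
    return state


def calibration_run(
    rt_stream, state: RTThresholdState | None = None
) -> RTThresholdState:
    """Run the 84-trial calibration (44 practice-half + 40 baseline trials).

    ``rt_stream`` yields per-trial reaction times in ms; a trial is
    'successful' when its RT is at or below the current threshold.  The
    returned state is frozen: the threshold is maintained unchanged once
    the rotation is introduced.
    """
    rts = list(rt_stream)
    if len(rts) < RT_WINDOW:
        raise ValueError(f"calibration stream shorter than window ({RT_WINDOW})")
    state = state or RTThresholdState()
    for rt in rts:
        update_rt_threshold(state, rt <= state.threshold_ms)
    state.frozen = True
    return state


def adjust_for_screen_delay(rt_ms: float, delay_ms: float = SCREEN_DELAY_MS) -> float:
    """Subtract the average display latency from a measured reaction time.

    With the default 154 ms delay the staircase bounds [280, 350] map to
    true preparation times of [126, 196] ms.  The result may be negative;
    downstream consumers flag such values.  This correction is applied in
    analysis only — the online threshold rule operates on raw RTs.
    """
    if rt_ms < 0:
        raise ValueError("rt_ms must be >= 0")
    return rt_ms - delay_ms
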