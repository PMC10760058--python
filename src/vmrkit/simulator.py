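"""Synthetic participants: a two-state (implicit + explicit) state-space
learner driven trial-by-trial over a schedule.

Model
-----
On every feedback trial the target error is the residual rotation left
after both adaptive systems have responded,

    e = r - (x_i + x_e),

and each system updates by retention-plus-learning,

    x_i <- a_i * x_i + b_i * e
    x_e <- a_e * x_e + b_e * e        (when strategy use is enabled)

with retention factors a and error sensitivities b in [0, 1].  On
no-feedback trials e = 0, so both states decay by retention alone.  At
steady state the implicit system satisfies the competition relation

    x_i_ss = p_i * (r - x_e_ss),    p_i = b_i / (1 - a_i + b_i),

which holds for any fixed or co-converging explicit state: the two systems
share a single residual error, so a large strategy starves the implicit
system of its learning substrate.

The explicit system is modeled as the faster, leakier of the two (lower
retention, higher error sensitivity): it responds strongly to error but
retains poorly, which is what produces spontaneous recovery after a brief
counter-rotation and the elevated preparation times of deliberate
re-aiming.  The reaction-time model is linear in the strategy magnitude:
RT = rt_base + rt_strategy_slope * |x_e| + noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import (
    EPOCH_SIZE,
    FeedbackMode,
    InstructionEvent,
    Paradigm,
    Phase,
    TrialSchedule,
)
from . import task_rules


@dataclass
class ParticipantParams:
    """Generative parameters of one synthetic participant.

    Defaults describe a typical adapting participant in a 30 deg rotation
    design, using the canonical slow/fast two-state values from the motor-
    learning literature: a slow, retentive implicit system (a_i = 0.996,
    b_i = 0.02, implicit gain p_i ~ 0.83 before competition) and a fast,
    leaky explicit system (a_e = 0.92, b_e = 0.21).  Motor noise of 3.5 deg
    s.d. per trial is typical of cursor-reach endpoint scatter; 60 ms RT
    noise and an RT cost of ~4 ms per degree of re-aiming give baseline-to-
    rotation preparation-time shifts of tens of ms for strategy users.
    """

    a_i: float = 0.996
    b_i: float = 0.02
    a_e: float = 0.92
    b_e: float = 0.21
    motor_noise_sd_deg: float = 3.5
    rt_base_ms: float = 400.0
    rt_strategy_slope_ms_per_deg: float = 4.0
    rt_noise_sd_ms: float = 60.0
    mt_base_ms: float = 150.0
    mt_noise_sd_ms: float = 25.0
    x_e_initial_deg: float = 0.0
    explicit_enabled: bool = True
    seed: int = 0

    # x_e_initial_deg models an explicit prior (e.g. in-lab experience): a
    # remembered re-aiming magnitude engaged when the first perturbed
    # feedback trial appears (recall is cued by noticing the rotation) and
    # held for the rest of the session.  It adds to the expressed aim and
    # is subtracted from the error the adaptive states see, so experienced
    # participants reach a higher total with less implicit learning.

    def __post_init__(self) -> None:
        for name in ("a_i", "b_i", "a_e", "b_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.motor_noise_sd_deg, self.rt_noise_sd_ms, self.mt_noise_sd_ms) < 0:
            raise ValueError("noise s.d. must be >= 0")


@dataclass
class SimState:
    """Latent state of the learner between trials (all in degrees)."""

    x_i: float = 0.0
    x_e: float = 0.0
    e: float = 0.0
    r: float = 0.0


@dataclass
class ConditionModifiers:
    """Condition-specific multipliers on the learner, all scales in [0, 1]
    unless noted.

    ``delayed_feedback_bi_scale`` shrinks implicit error sensitivity when
    endpoint feedback is delayed (default 0.1, i.e. ~90% aftereffect
    reduction).  ``variance_bi_scale`` / ``variance_be_scale`` model the
    disruption from a high-variance perturbation.  ``limited_rt_explicit``
    disables strategy use when preparation time is capped.  ``nonresponder``
    models the unresponsive delayed-feedback phenotype (no strategy, near-
    zero implicit sensitivity).  The second-exposure scales (may exceed 1)
    apply from the second rotation onward: an up-regulated explicit system
    produces savings; down-regulated sensitivities produce anterograde
    interference.
    """

    delayed_feedback_bi_scale: float = 0.1
    variance_bi_scale: float = 0.8
    variance_be_scale: float = 0.5
    limited_rt_explicit: bool = False
    nonresponder: bool = False
    second_exposure_bi_scale: float = 1.0
    second_exposure_be_scale: float = 1.0


SECOND_EXPOSURE_PHASES = (Phase.ROTATION2, Phase.COUNTER_ROTATION)


def modifiers_for_paradigm(paradigm: Paradigm | str) -> ConditionModifiers:
    """Default condition modifiers that reproduce each paradigm's
    characteristic cohort-level signature.

    Savings: the washed-out explicit memory is re-engaged more strongly on
    re-exposure (second-exposure explicit sensitivity doubled).
    Interference: the just-learned memory blunts both systems' response to
    the opposite error (sensitivities halved on the second exposure).
    Limited preparation time disables strategy use.  Other paradigms keep
    the neutral defaults.
    """
    paradigm = Paradigm(paradigm)
    if paradigm is Paradigm.SAVINGS:
        return ConditionModifiers(second_exposure_be_scale=2.0)
    if paradigm is Paradigm.INTERFERENCE:
        return ConditionModifiers(
            second_exposure_bi_scale=0.5, second_exposure_be_scale=0.5
        )
    if paradigm in (Paradigm.LIMITED_RT_AIMSTRAIGHT, Paradigm.LIMITED_RT_KEEPAIM):
        return ConditionModifiers(limited_rt_explicit=True)
    return ConditionModifiers()


def steady_state_implicit(a_i: float, b_i: float, r: float, x_e: float) -> float:
    """Closed-form implicit steady state p_i * (r - x_e)."""
    denom = 1.0 - a_i + b_i
    if denom <= 0:
        raise ValueError("1 - a_i + b_i must be > 0")
    return b_i / denom * (r - x_e)


def implicit_gain(a_i: float, b_i: float) -> float:
    """The implicit learning gain p_i = b_i / (1 - a_i + b_i)."""
    denom = 1.0 - a_i + b_i
    if denom <= 0:
        raise ValueError("1 - a_i + b_i must be > 0")
    return b_i / denom


def step(
    state: SimState,
    rotation_deg: float,
    feedback_mode: FeedbackMode,
    params: ParticipantParams,
    b_i: float | None = None,
    b_e: float | None = None,
) -> SimState:
    """One trial of the two-state update; returns a new state.

    ``b_i``/``b_e`` override the participant's sensitivities for this trial
    (used by condition modifiers).  No-feedback trials deliver no error;
    error-clamp trials deliver an error equal to the clamp angle regardless
    of hand position.
    """
    b_i = params.b_i if b_i is None else b_i
    b_e = params.b_e if b_e is None else b_e
    if feedback_mode is FeedbackMode.NONE:
        e = 0.0
    elif feedback_mode is FeedbackMode.ERROR_CLAMP:
        e = rotation_deg
    else:
        e = rotation_deg - (state.x_i + state.x_e)
    x_i = params.a_i * state.x_i + b_i * e
    if params.explicit_enabled:
        x_e = params.a_e * state.x_e + b_e * e
    else:
        x_e = state.x_e
    return SimState(x_i=x_i, x_e=x_e, e=e, r=rotation_deg)


@dataclass
class SessionData:
    """One simulated (or recorded) participant session.

    ``trials`` is a per-trial table with movement angle, reaction and
    movement times, validity and point flags, plus — for simulated data —
    the latent implicit/explicit states.
    """

    trials: pd.DataFrame
    paradigm_name: str
    participant_id: str = "sim"
    seed: int = 0
    epoch_size: int = EPOCH_SIZE
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_epochs(self) -> int:
        return len(self.trials) // self.epoch_size


def _active_scales(
    spec_phase: Phase,
    feedback_mode: FeedbackMode,
    paradigm: str,
    mods: ConditionModifiers,
) -> tuple[float, float]:
    bi_scale = be_scale = 1.0
    if feedback_mode is FeedbackMode.DELAYED:
        bi_scale *= mods.delayed_feedback_bi_scale
    if paradigm == Paradigm.HIGH_VARIANCE.value:
        bi_scale *= mods.variance_bi_scale
        be_scale *= mods.variance_be_scale
    if spec_phase in SECOND_EXPOSURE_PHASES:
        bi_scale *= mods.second_exposure_bi_scale
        be_scale *= mods.second_exposure_be_scale
    return bi_scale, be_scale


def simulate_session(
    schedule: TrialSchedule,
    params: ParticipantParams,
    modifiers: ConditionModifiers | None = None,
    participant_id: str = "sim",
) -> SessionData:
    """Run one synthetic participant through a schedule.

    The expressed movement angle is x_i + x_e plus Gaussian motor noise,
    except after an aim-straight instruction, where the strategy is
    withheld (angle = x_i + noise) while the implicit state is preserved;
    after a keep-aiming instruction the full angle continues to be
    expressed with no feedback-driven update.  The 30 s pause at the
    instruction costs the implicit state one extra retention step.
    Deterministic given ``params.seed``.
    """
    mods = modifiers or ConditionModifiers()
    params = replace(params)
    if mods.nonresponder:
        params.explicit_enabled = False
        params.b_i = 0.0005  # near-zero implicit sensitivity: flat curves
    if mods.limited_rt_explicit:
        params.explicit_enabled = False

    rng = np.random.default_rng(params.seed)
    state = SimState()
    aim_straight = False
    prior = params.x_e_initial_deg if params.explicit_enabled else 0.0
    prior_engaged = False
    rows = []
    for spec in schedule.trials:
        if (
            not prior_engaged
            and prior != 0.0
            and spec.rotation_deg != 0.0
            and spec.feedback_mode is not FeedbackMode.NONE
        ):
            prior_engaged = True
        if spec.instruction_event is InstructionEvent.AIM_STRAIGHT:
            aim_straight = True
            state = replace(state, x_i=params.a_i * state.x_i)
        elif spec.instruction_event is InstructionEvent.KEEP_AIMING:
            state = replace(state, x_i=params.a_i * state.x_i)

        active_prior = prior if prior_engaged else 0.0
        if aim_straight or not params.explicit_enabled:
            expressed_xe = 0.0
        else:
            expressed_xe = state.x_e + active_prior
        angle = state.x_i + expressed_xe + rng.normal(0.0, params.motor_noise_sd_deg)
        rt = (
            params.rt_base_ms
            + params.rt_strategy_slope_ms_per_deg * abs(expressed_xe)
            + rng.normal(0.0, params.rt_noise_sd_ms)
        )
        rt = max(rt, 0.0)
        mt = max(params.mt_base_ms + rng.normal(0.0, params.mt_noise_sd_ms), 0.0)
        # error relative to the target: the rotated cursor lands at angle -
        # rotation, so the on-screen angular error is rotation - angle
        err = spec.rotation_deg - angle if spec.feedback_mode is not FeedbackMode.NONE else np.nan
        outcome = task_rules.classify_trial(
            mt,
            rt,
            0.0 if np.isnan(err) else err,
            rt_limited=spec.rt_limited,
            rt_threshold_ms=task_rules.RT_THRESHOLD_CEILING_MS if spec.rt_limited else None,
        )
        rows.append(
            {
                "trial": spec.index,
                "target_id": spec.target_id,
                "rotation_deg": spec.rotation_deg,
                "phase": spec.phase.value,
                "feedback_mode": spec.feedback_mode.value,
                "movement_angle_deg": angle,
                "reaction_time_ms": rt,
                "movement_time_ms": mt,
                "valid": True,
                "point_awarded": outcome.point_awarded,
                "x_i": state.x_i,
                "x_e": state.x_e,
            }
        )
        bi_scale, be_scale = _active_scales(
            spec.phase, spec.feedback_mode, schedule.paradigm_name, mods
        )
        # a held prior aim shifts the error the adaptive states experience
        effective_rot = spec.rotation_deg
        if spec.feedback_mode in (FeedbackMode.ONLINE, FeedbackMode.DELAYED):
            effective_rot -= active_prior
        state = step(
            state,
            effective_rot,
            spec.feedback_mode,
            params,
            b_i=params.b_i * bi_scale,
            b_e=params.b_e * be_scale,
        )
    return SessionData(
        trials=pd.DataFrame(rows),
        paradigm_name=schedule.paradigm_name,
        participant_id=participant_id,
        seed=params.seed,
        epoch_size=schedule.epoch_size,
        meta={"a_i": params.a_i, "b_i": params.b_i, "a_e": params.a_e, "b_e": params.b_e},
    )


@dataclass
class CohortDistribution:
    """Independent truncated-normal priors over participant parameters.

    Retention/sensitivity draws are clipped to [0, 1]; noise parameters are
    held fixed across the cohort.
    """

    base: ParticipantParams = field(default_factory=ParticipantParams)
    a_i_sd: float = 0.005
    b_i_sd: float = 0.01
    a_e_sd: float = 0.02
    b_e_sd: float = 0.05
    x_e_initial_sd_deg: float = 0.0

    def draw(self, rng: np.random.Generator, seed: int) -> ParticipantParams:
        clip = lambda v: float(np.clip(v, 0.0, 1.0))
        b = self.base
        return replace(
            b,
            a_i=clip(rng.normal(b.a_i, self.a_i_sd)),
            b_i=clip(rng.normal(b.b_i, self.b_i_sd)),
            a_e=clip(rng.normal(b.a_e, self.a_e_sd)),
            b_e=clip(rng.normal(b.b_e, self.b_e_sd)),
            x_e_initial_deg=float(rng.normal(b.x_e_initial_deg, self.x_e_initial_sd_deg)),
            seed=seed,
        )


def simulate_cohort(
    n: int,
    schedule: TrialSchedule,
    distribution: CohortDistribution | None = None,
    modifiers: ConditionModifiers | None = None,
    seed: int = 0,
) -> list[SessionData]:
    """Simulate ``n`` participants with i.i.d. parameter draws.

    Each participant receives a reproducible child seed, so the cohort is
    bit-identical for a fixed master seed and invariant to consuming only a
    prefix of it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = distribution or CohortDistribution()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    sessions = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        p_seed = int(rng.integers(2**31))
        params = dist.draw(rng, seed=p_seed)
        sessions.append(
            simulate_session(schedule, params, modifiers, participant_id=f"sim{i:03d}")
        )
    return sessions
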