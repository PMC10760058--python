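"""Trial-schedule generation for visuomotor-rotation paradigms.

A schedule is an ordered list of :class:`TrialSpec` grouped into epochs
(cycles) of 4 trials, one reach to each of the 4 cardinal targets per epoch
in randomized order.  The rotation sign convention is global: counter-
clockwise (CCW) cursor rotations are positive, and adaptive hand-angle
responses that oppose a CCW rotation are likewise reported as positive.

Schedules are fully determined by a paradigm, its parameters and a master
seed; the seed is split into independent streams for target-order
randomization and trial-wise rotation sampling so that changing one does
not perturb the other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EPOCH_SIZE = 4
N_TARGETS = 4


class FeedbackMode(str, enum.Enum):
    ONLINE = "online"
    DELAYED = "delayed"
    NONE = "none"
    ERROR_CLAMP = "error_clamp"


class Phase(str, enum.Enum):
    BASELINE = "baseline"
    ROTATION1 = "rotation1"
    WASHOUT = "washout"
    ROTATION2 = "rotation2"
    COUNTER_ROTATION = "counter_rotation"
    NO_FEEDBACK = "no_feedback"


class InstructionEvent(str, enum.Enum):
    NONE = "none"
    AIM_STRAIGHT = "aim_straight"
    KEEP_AIMING = "keep_aiming"


class Paradigm(str, enum.Enum):
    SAVINGS = "savings"
    INTERFERENCE = "interference"
    SPONTANEOUS_RECOVERY = "spontaneous_recovery"
    STANDARD = "standard"
    DELAYED_FEEDBACK = "delayed_feedback"
    LIMITED_RT_AIMSTRAIGHT = "limited_rt_aimstraight"
    LIMITED_RT_KEEPAIM = "limited_rt_keepaim"
    HIGH_VARIANCE = "high_variance"
    GRADUAL = "gradual"
    ERROR_CLAMP = "error_clamp"


@dataclass
class TrialSpec:
    """One planned trial.

    ``rotation_deg`` is the signed cursor rotation (CCW positive).  On
    ``feedback_mode == NONE`` trials the rotation is irrelevant to the
    display but is still recorded.  ``break_after`` marks a 30 s rest that
    follows this trial (breaks are flags, never phantom trials, so trial
    indices stay aligned with the protocol descriptions).
    """

    index: int  # 1-based
    target_id: int
    rotation_deg: float
    feedback_mode: FeedbackMode
    phase: Phase
    delay_ms: float = 0.0
    rt_limited: bool = False
    instruction_event: InstructionEvent = InstructionEvent.NONE
    break_after: bool = False

    def __post_init__(self) -> None:
        if self.target_id not in range(N_TARGETS):
            raise ValueError(f"target_id must be in 0..3, got {self.target_id}")
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be >= 0")


@dataclass
class TrialSchedule:
    trials: list[TrialSpec]
    paradigm_name: str
    seed: int
    epoch_size: int = EPOCH_SIZE
    practice: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_epochs(self) -> int:
        return len(self.trials) // self.epoch_size

    def epoch_phases(self) -> list[Phase]:
        """Phase label of each epoch (the phase of its first trial)."""
        return [self.trials[k * self.epoch_size].phase for k in range(self.n_epochs)]

    def validate(self) -> None:
        """Raise ValueError on any structural-invariant violation."""
        n = len(self.trials)
        if n % self.epoch_size:
            raise ValueError(f"trial count {n} not divisible by epoch size {self.epoch_size}")
        for k in range(n // self.epoch_size):
            epoch = self.trials[k * self.epoch_size : (k + 1) * self.epoch_size]
            if sorted(t.target_id for t in epoch) != list(range(N_TARGETS)):
                raise ValueError(f"epoch {k + 1} does not contain each target exactly once")
            if len({t.phase for t in epoch}) != 1:
                raise ValueError(f"epoch {k + 1} spans a phase boundary")
        seen: list[Phase] = []
        for ph in self.epoch_phases():
            if seen and ph != seen[-1] and ph in seen:
                raise ValueError(f"phase {ph.value} is not a contiguous block")
            if not seen or ph != seen[-1]:
                seen.append(ph)
        for t, expected in zip(self.trials, range(1, n + 1)):
            if t.index != expected:
                raise ValueError("trial indices must be 1..n in order")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "target_id": [t.target_id for t in self.trials],
                "rotation_deg": [t.rotation_deg for t in self.trials],
                "feedback_mode": [t.feedback_mode.value for t in self.trials],
                "delay_ms": [t.delay_ms for t in self.trials],
                "rt_limited": [t.rt_limited for t in self.trials],
                "phase": [t.phase.value for t in self.trials],
                "instruction_event": [t.instruction_event.value for t in self.trials],
                "break_after": [t.break_after for t in self.trials],
            }
        )


@dataclass
class ParadigmParams:
    """Parameters of a named paradigm.

    ``block_epochs`` overrides the default per-phase epoch counts (a mapping
    from phase to epoch count, in block order).  ``breaks_after_trials``
    lists 1-based trial indices after which a 30 s rest is given.
    """

    paradigm: Paradigm | str = Paradigm.STANDARD
    rotation_deg: float = 30.0
    rotation_sd_deg: float = 0.0
    block_epochs: dict[str, int] | None = None
    breaks_after_trials: list[int] | None = None
    feedback_delay_ms: float = 1055.0
    practice: bool = False

    def __post_init__(self) -> None:
        self.paradigm = Paradigm(self.paradigm)
        if self.rotation_sd_deg < 0:
            raise ValueError("rotation_sd_deg must be >= 0")
        if self.block_epochs is not None:
            if any(v <= 0 for v in self.block_epochs.values()):
                raise ValueError("block_epochs must all be positive")


# (phase, epochs, rotation multiplier, feedback mode) blocks per paradigm.
# Multiplier scales params.rotation_deg; washout/baseline blocks are null.
_BLOCKS: dict[Paradigm, list[tuple[Phase, int, float, FeedbackMode]]] = {
    Paradigm.SAVINGS: [
        (Phase.BASELINE, 10, 0.0, FeedbackMode.ONLINE),
        (Phase.ROTATION1, 30, 1.0, FeedbackMode.ONLINE),
        (Phase.WASHOUT, 30, 0.0, FeedbackMode.ONLINE),
        (Phase.ROTATION2, 30, 1.0, FeedbackMode.ONLINE),
    ],
    Paradigm.INTERFERENCE: [
        (Phase.BASELINE, 10, 0.0, FeedbackMode.ONLINE),
        (Phase.ROTATION1, 30, 1.0, FeedbackMode.ONLINE),
        (Phase.WASHOUT, 30, 0.0, FeedbackMode.ONLINE),
        (Phase.ROTATION2, 30, -1.0, FeedbackMode.ONLINE),
    ],
    Paradigm.SPONTANEOUS_RECOVERY: [
        (Phase.BASELINE, 10, 0.0, FeedbackMode.ONLINE),
        (Phase.ROTATION1, 60, 1.0, FeedbackMode.ONLINE),
        (Phase.COUNTER_ROTATION, 10, -1.0, FeedbackMode.ONLINE),
        (Phase.NO_FEEDBACK, 20, 0.0, FeedbackMode.NONE),
    ],
    Paradigm.STANDARD: [
        (Phase.BASELINE, 10, 0.0, FeedbackMode.ONLINE),
        (Phase.ROTATION1, 60, 1.0, FeedbackMode.ONLINE),
        (Phase.NO_FEEDBACK, 20, 0.0, FeedbackMode.NONE),
    ],
    Paradigm.ERROR_CLAMP: [
        (Phase.BASELINE, 10, 0.0, FeedbackMode.ONLINE),
        (Phase.ROTATION1, 60, 1.0, FeedbackMode.ERROR_CLAMP),
        (Phase.NO_FEEDBACK, 20, 0.0, FeedbackMode.NONE),
    ],
}
# These share the standard block structure and differ in flags only.
for _p in (
    Paradigm.DELAYED_FEEDBACK,
    Paradigm.LIMITED_RT_AIMSTRAIGHT,
    Paradigm.LIMITED_RT_KEEPAIM,
    Paradigm.HIGH_VARIANCE,
):
    _BLOCKS[_p] = _BLOCKS[Paradigm.STANDARD]

_DEFAULT_BREAKS: dict[Paradigm, list[int]] = {
    Paradigm.SAVINGS: [160, 260],
    Paradigm.INTERFERENCE: [160, 260],
    Paradigm.SPONTANEOUS_RECOVERY: [160],
}


def _split_seed(seed: int, n: int = 2) -> list[np.random.Generator]:
    """Independent generator streams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_variable_rotations(
    mean_deg: float, sd_deg: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Trial-wise rotation angles drawn i.i.d. from N(mean_deg, sd_deg**2).

    This is the high-variance perturbation generator (default configuration
    mean 30 deg, s.d. 12 deg).  Deterministic given the seed.
    """
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(mean_deg, sd_deg, size=n)


def randomize_targets(schedule: TrialSchedule, seed: int) -> TrialSchedule:
    """Re-randomize target order independently within every 4-trial epoch."""
    if schedule.n_trials % N_TARGETS:
        raise ValueError("schedule length must be divisible by 4")
    rng = np.random.default_rng(seed)
    trials = []
    for k in range(schedule.n_epochs):
        order = rng.permutation(N_TARGETS)
        for j, t in enumerate(
            schedule.trials[k * EPOCH_SIZE : (k + 1) * EPOCH_SIZE]
        ):
            trials.append(replace(t, target_id=int(order[j])))
    return replace(schedule, trials=trials, seed=seed)


def build_paradigm_schedule(params: ParadigmParams, seed: int) -> TrialSchedule:
    """Construct the complete trial plan of a named paradigm.

    The per-phase epoch counts, rotation signs, feedback modes, break flags
    and instruction events follow the protocol definitions: e.g. savings and
    interference run 100 epochs (400 trials) with rests after trials 160 and
    260; the standard aftereffect design runs 90 epochs (360 trials) with
    phases baseline(10) / rotation(60) / no-feedback(20).
    """
    if params.paradigm is Paradigm.GRADUAL:
        return build_gradual_schedule(params, seed=seed)
    blocks = _BLOCKS.get(params.paradigm)
    if blocks is None:
        raise ValueError(f"unknown paradigm: {params.paradigm}")
    if params.block_epochs is not None:
        blocks = [
            (ph, params.block_epochs.get(ph.value, n), mult, fb)
            for ph, n, mult, fb in blocks
        ]
    if any(n <= 0 for _, n, _, _ in blocks):
        raise ValueError("epoch counts must be positive")

    target_rng, rot_rng = _split_seed(seed)
    rt_limited = params.paradigm in (
        Paradigm.LIMITED_RT_AIMSTRAIGHT,
        Paradigm.LIMITED_RT_KEEPAIM,
    )
    delayed = params.paradigm is Paradigm.DELAYED_FEEDBACK
    variable = params.paradigm is Paradigm.HIGH_VARIANCE or params.rotation_sd_deg > 0
    no_fb_instruction = (
        InstructionEvent.KEEP_AIMING
        if params.paradigm is Paradigm.LIMITED_RT_KEEPAIM
        else InstructionEvent.AIM_STRAIGHT
    )

    trials: list[TrialSpec] = []
    idx = 1
    for phase, n_epochs, mult, fb in blocks:
        n = n_epochs * EPOCH_SIZE
        base_rot = mult * params.rotation_deg
        if variable and mult != 0.0:
            rots = sample_variable_rotations(
                base_rot, params.rotation_sd_deg or 12.0, n, rot_rng
            )
        else:
            rots = np.full(n, base_rot)
        if delayed and fb is FeedbackMode.ONLINE:
            fb, delay = FeedbackMode.DELAYED, params.feedback_delay_ms
        else:
            delay = 0.0
        for j in range(n):
            instruction = InstructionEvent.NONE
            if phase is Phase.NO_FEEDBACK and j == 0:
                instruction = no_fb_instruction
            trials.append(
                TrialSpec(
                    index=idx,
                    target_id=j % N_TARGETS,  # placeholder; randomized below
                    rotation_deg=float(rots[j]),
                    feedback_mode=fb,
                    phase=phase,
                    delay_ms=delay,
                    rt_limited=rt_limited,
                    instruction_event=instruction,
                )
            )
            idx += 1

    breaks = (
        params.breaks_after_trials
        if params.breaks_after_trials is not None
        else _DEFAULT_BREAKS.get(params.paradigm, [])
    )
    for b in breaks:
        if not 1 <= b <= len(trials):
            raise ValueError(f"break index {b} outside schedule")
        trials[b - 1] = replace(trials[b - 1], break_after=True)

    sched = TrialSchedule(
        trials=trials,
        paradigm_name=params.paradigm.value,
        seed=seed,
        practice=params.practice,
    )
    sched = randomize_targets(sched, seed=int(target_rng.integers(2**31)))
    sched.seed = seed
    sched.validate()
    return sched


def build_practice_schedule(seed: int) -> TrialSchedule:
    """The dynamic practice block: 80 null trials + 8 no-feedback trials."""
    params = ParadigmParams(
        paradigm=Paradigm.STANDARD,
        rotation_deg=0.0,
        block_epochs={"baseline": 19, "rotation1": 1, "no_feedback": 2},
        practice=True,
    )
    sched = build_paradigm_schedule(params, seed)
    # the single dummy rotation epoch is null here; relabel it baseline
    trials = [
        replace(t, phase=Phase.BASELINE) if t.phase is Phase.ROTATION1 else t
        for t in sched.trials
    ]
    out = replace(sched, trials=trials, paradigm_name="practice")
    out.validate()
    return out


def build_gradual_schedule(
    params: ParadigmParams,
    seed: int,
    ramp_epochs: int = 30,
    hold_epochs: int = 30,
    baseline_epochs: int = 10,
) -> TrialSchedule:
    """Gradual-rotation schedule: the rotation ramps linearly per epoch from
    0 up to ``params.rotation_deg`` over ``ramp_epochs``, then holds.

    Epoch k of the ramp (1-based) applies ``k * final / ramp_epochs``
    degrees; ``ramp_epochs == 1`` degenerates to an abrupt schedule.
    """
    if ramp_epochs <= 0:
        raise ValueError("ramp_epochs must be > 0")
    if hold_epochs < 0 or baseline_epochs <= 0:
        raise ValueError("epoch counts must be positive")
    final = params.rotation_deg
    trials: list[TrialSpec] = []
    idx = 1

    def _epoch(phase: Phase, rot: float) -> None:
        nonlocal idx
        for j in range(EPOCH_SIZE):
            trials.append(
                TrialSpec(
                    index=idx,
                    target_id=j,
                    rotation_deg=rot,
                    feedback_mode=FeedbackMode.ONLINE,
                    phase=phase,
                )
            )
            idx += 1

    for _ in range(baseline_epochs):
        _epoch(Phase.BASELINE, 0.0)
    for k in range(1, ramp_epochs + 1):
        _epoch(Phase.ROTATION1, k * final / ramp_epochs)
    for _ in range(hold_epochs):
        _epoch(Phase.ROTATION1, final)

    sched = TrialSchedule(trials=trials, paradigm_name="gradual", seed=seed)
    target_rng, _ = _split_seed(seed)
    sched = randomize_targets(sched, seed=int(target_rng.integers(2**31)))
    sched.seed = seed
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# Target file: the plain-text description that fully determines an experiment.

_TARGET_COLUMNS = [
    "trial",
    "target_id",
    "rotation_deg",
    "feedback_mode",
    "delay_ms",
    "rt_limited",
    "phase",
    "instruction_event",
    "break_after",
]


def write_target_file(schedule: TrialSchedule, path) -> None:
    """Write a schedule as a comma-delimited target file with a ``#`` header."""
    df = schedule.to_dataframe()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# paradigm={schedule.paradigm_name}\n")
        fh.write(f"# epoch_size={schedule.epoch_size}\n")
        fh.write(f"# seed={schedule.seed}\n")
        df.to_csv(fh, index=False)


def read_target_file(path) -> TrialSchedule:
    """Read a target file (comma- or whitespace-delimited) back into a schedule."""
    header: dict[str, str] = {}
    rows: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
            else:
                rows.append(line)
    if not rows:
        raise ValueError(f"{path}: no trial rows found")
    delim = "," if "," in rows[0] else None
    parsed = [r.split(delim) for r in rows]
    columns = parsed[0]
    if columns[0] != "trial":
        raise ValueError(f"{path}: missing column header row")
    df = pd.DataFrame(parsed[1:], columns=columns)
    missing = set(_TARGET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def _bool(s: str) -> bool:
        return s.strip().lower() in ("true", "1", "yes")

    trials = [
        TrialSpec(
            index=int(row["trial"]),
            target_id=int(row["target_id"]),
            rotation_deg=float(row["rotation_deg"]),
            feedback_mode=FeedbackMode(row["feedback_mode"]),
            delay_ms=float(row["delay_ms"]),
            rt_limited=_bool(row["rt_limited"]),
            phase=Phase(row["phase"]),
            instruction_event=InstructionEvent(row["instruction_event"]),
            break_after=_bool(row["break_after"]),
        )
        for _, row in df.iterrows()
    ]
    sched = TrialSchedule(
        trials=trials,
        paradigm_name=header.get("paradigm", "unknown"),
        seed=int(header.get("seed", 0)),
        epoch_size=int(header.get("epoch_size", EPOCH_SIZE)),
    )
    sched.validate()
    return sched
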