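"""Per-participant measurement pipeline.

Turns per-trial records into epoch (4-trial cycle) averages and the
standard summary measures: total adaptation, implicit aftereffect,
inferred explicit strategy, savings / interference metrics (delta-angle
and delta-rate from constrained exponential fits), spontaneous-recovery
period means, and preparation-time summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .schedule import EPOCH_SIZE, Phase, TrialSchedule
from .simulator import SessionData
from . import task_rules

RT_INIT_FRACTION = 0.05  # radial fraction defining movement initiation
ANGLE_FRACTION = 0.95  # radial fraction at which the movement angle is read


def extract_movement_angle(
    trajectory,
    start,
    target,
    radial_disp: float | None = None,
    fraction: float = ANGLE_FRACTION,
) -> float:
    """Signed hand angle (CCW positive) relative to the target direction.

    The angle is read at the first moment the hand exceeds ``fraction``
    (default 95%) of the start-to-target radial displacement, linearly
    interpolating between the bracketing samples.  ``trajectory`` is a
    sequence of (t, x, y); ``start``/``target`` are (x, y).
    """
    traj = np.asarray([(x, y) for _, x, y in trajectory], dtype=float)
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if radial_disp is None:
        radial_disp = float(np.linalg.norm(target - start))
    threshold = fraction * radial_disp
    radii = np.linalg.norm(traj - start, axis=1)
    crossing = np.nonzero(radii >= threshold)[0]
    if crossing.size == 0:
        raise ValueError("trajectory never crosses the angle-measurement radius")
    j = int(crossing[0])
    if j == 0:
        p = traj[0]
    else:
        r0, r1 = radii[j - 1], radii[j]
        w = (threshold - r0) / (r1 - r0)
        p = traj[j - 1] + w * (traj[j] - traj[j - 1])
    hand = p - start
    tvec = target - start
    ang = math.atan2(hand[1], hand[0]) - math.atan2(tvec[1], tvec[0])
    return math.degrees(math.atan2(math.sin(ang), math.cos(ang)))


def movement_initiation_index(
    trajectory, start, radial_disp: float, fraction: float = RT_INIT_FRACTION
) -> int:
    """Index of the first sample beyond ``fraction`` of the radial
    displacement — the movement-initiation sample used for reaction time."""
    traj = np.asarray([(x, y) for _, x, y in trajectory], dtype=float)
    radii = np.linalg.norm(traj - np.asarray(start, dtype=float), axis=1)
    idx = np.nonzero(radii >= fraction * radial_disp)[0]
    if idx.size == 0:
        raise ValueError("no movement initiation detected")
    return int(idx[0])


@dataclass
class EpochSeries:
    """Cycle-averaged movement angles with phase labels."""

    values: np.ndarray
    phases: list[Phase]
    epoch_size: int = EPOCH_SIZE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.phases):
            raise ValueError("values and phases must align")

    def __len__(self) -> int:
        return len(self.values)

    def phase_values(self, phase: Phase) -> np.ndarray:
        mask = np.array([p == phase for p in self.phases])
        return self.values[mask]

    def phase_start(self, phase: Phase) -> int:
        for k, p in enumerate(self.phases):
            if p == phase:
                return k
        raise ValueError(f"phase {phase} not present")


@dataclass
class MetricsResult:
    participant_id: str = ""
    total_adaptation_deg: float = np.nan
    implicit_early_deg: float = np.nan
    implicit_late_deg: float = np.nan
    implicit_full_deg: float = np.nan
    explicit_deg: float = np.nan
    delta_angle_deg: float = np.nan
    rate_1: float = np.nan
    rate_2: float = np.nan
    delta_rate: float = np.nan
    period_means: dict = field(default_factory=dict)
    rt_baseline_median_ms: float = np.nan
    rt_rotation_median_ms: float = np.nan
    rt_change_ms: float = np.nan

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "period_means"}
        for name, v in self.period_means.items():
            row[f"period_{name}"] = v
        return row


def epoch_average(session: SessionData) -> EpochSeries:
    """Mean movement angle per 4-trial epoch.

    Invalid trials are excluded from the mean; an epoch with no valid
    trials propagates as NaN.
    """
    df = session.trials
    n = len(df)
    if n % session.epoch_size:
        raise ValueError("trial count not divisible by epoch size")
    angles = df["movement_angle_deg"].to_numpy(dtype=float).copy()
    if "valid" in df:
        angles[~df["valid"].to_numpy(dtype=bool)] = np.nan
    grouped = angles.reshape(-1, session.epoch_size)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(grouped, axis=1)
    phases = [Phase(df["phase"].iloc[k * session.epoch_size]) for k in range(len(means))]
    return EpochSeries(values=means, phases=phases, epoch_size=session.epoch_size)


def baseline_subtract(
    series: EpochSeries,
    rotation_start_epoch: int,
    n_pre: int = 3,
    sign_flip: bool = False,
) -> EpochSeries:
    """Remove reach bias: subtract the mean of the ``n_pre`` epochs
    immediately preceding rotation onset from every epoch.

    ``rotation_start_epoch`` is the 0-based epoch index of rotation onset.
    For a second exposure to an opposite rotation, set ``sign_flip`` to
    reverse the series sign before subtraction so both exposures read as
    positive adaptation.
    """
    if rotation_start_epoch < n_pre:
        raise ValueError("not enough pre-rotation epochs for baseline estimation")
    values = -series.values if sign_flip else series.values
    pre = values[rotation_start_epoch - n_pre : rotation_start_epoch]
    return EpochSeries(
        values=values - np.nanmean(pre), phases=list(series.phases), epoch_size=series.epoch_size
    )


def early_change(series: EpochSeries, rotation_start_epoch: int, n: int = 3) -> float:
    """Mean angle over the first ``n`` rotation epochs minus the mean of the
    ``n`` epochs immediately preceding rotation onset."""
    if rotation_start_epoch < n or rotation_start_epoch + n > len(series):
        raise ValueError("need >= 3 epochs on each side of rotation onset")
    post = series.values[rotation_start_epoch : rotation_start_epoch + n]
    pre = series.values[rotation_start_epoch - n : rotation_start_epoch]
    return float(np.nanmean(post) - np.nanmean(pre))


def delta_angle(
    series1: EpochSeries,
    series2: EpochSeries,
    rotation_start_epoch1: int,
    rotation_start_epoch2: int,
    n: int = 3,
) -> float:
    """Savings / interference angular metric: the early change in hand
    angle (3 epochs post minus 3 epochs pre rotation onset) on the second
    exposure minus the same change on the first.  Positive values indicate
    faster early re-adaptation (savings); negative, interference."""
    return early_change(series2, rotation_start_epoch2, n) - early_change(
        series1, rotation_start_epoch1, n
    )


def fit_exponential(
    values,
    y_pre: float,
    n_starts: int = 8,
    rate_bounds: tuple[float, float] = (0.0, 10.0),
    asymptote_bounds: tuple[float, float] = (-90.0, 90.0),
) -> tuple[float, float, np.ndarray]:
    """Constrained exponential fit y(t) = A + (y_pre - A) exp(-rho t).

    ``values`` are the rotation-period epoch means, t = 1, 2, ... epochs
    after onset; the curve is constrained to begin at ``y_pre`` (the epoch
    just prior to rotation onset), leaving rho (rate) and A (asymptote)
    free.  Least squares with multiple starts over the rate range; returns
    (rho, A, fitted curve).  A flat series equal to y_pre leaves rho
    unidentifiable and returns rho = 0 (slowest-rate tie-break).
    """
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 5:
        raise ValueError("need at least 5 finite epochs to fit")
    if not np.isfinite(y_pre):
        raise ValueError("y_pre must be finite")
    t = np.arange(1, len(y) + 1, dtype=float)[ok]
    yv = y[ok]

    def model(tt, rho, A):
        return A + (y_pre - A) * np.exp(-rho * tt)

    if np.allclose(yv, y_pre, atol=1e-12):
        return 0.0, float(y_pre), model(np.arange(1, len(y) + 1, dtype=float), 0.0, y_pre)

    lo = (rate_bounds[0], asymptote_bounds[0])
    hi = (rate_bounds[1], asymptote_bounds[1])
    a0 = float(np.clip(np.mean(yv[-3:]), *asymptote_bounds))
    best, best_sse = None, np.inf
    rho_grid = np.geomspace(1e-3, rate_bounds[1], n_starts)
    for rho0 in rho_grid:
        try:
            popt, _ = curve_fit(
                model, t, yv, p0=(rho0, a0), bounds=(lo, hi), maxfev=5000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(t, *popt) - yv) ** 2))
        if sse < best_sse - 1e-12 or (
            best is not None and abs(sse - best_sse) <= 1e-12 and popt[0] < best[0]
        ):
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError(
            f"exponential fit failed to converge from {n_starts} starts "
            f"(n={ok.sum()}, y_pre={y_pre:.3g})"
        )
    rho, A = float(best[0]), float(best[1])
    return rho, A, model(np.arange(1, len(y) + 1, dtype=float), rho, A)


def decompose(
    series: EpochSeries,
    n_epochs: int = 5,
    implicit_variant: str = "early",
) -> MetricsResult:
    """Implicit / explicit decomposition from the aftereffect design.

    Total adaptation is the mean angle over the last 5 rotation epochs;
    the implicit measure is the mean over the first 5 (early), last 5
    (late) or all (full) no-feedback epochs; explicit strategy is total
    minus the designated implicit measure, exactly.
    """
    rot = np.concatenate(
        [series.phase_values(p) for p in (Phase.ROTATION1, Phase.ROTATION2) if p in series.phases]
        or [np.array([])]
    )
    nofb = series.phase_values(Phase.NO_FEEDBACK)
    if rot.size == 0 or nofb.size == 0:
        raise ValueError("series must contain rotation and no-feedback phases")
    res = MetricsResult()
    res.total_adaptation_deg = float(np.nanmean(rot[-n_epochs:]))
    res.implicit_early_deg = float(np.nanmean(nofb[:n_epochs]))
    res.implicit_late_deg = float(np.nanmean(nofb[-n_epochs:]))
    res.implicit_full_deg = float(np.nanmean(nofb))
    implicit = {
        "early": res.implicit_early_deg,
        "late": res.implicit_late_deg,
        "full": res.implicit_full_deg,
    }[implicit_variant]
    res.explicit_deg = res.total_adaptation_deg - implicit
    return res


def decorrelated_measures(no_fb_epochs, total: float) -> tuple[float, float]:
    """Implicit / explicit measures sharing no epochs (hence no motor
    noise): implicit is the mean of no-feedback epochs 2, 4, 6; explicit is
    total adaptation minus the mean of epochs 1, 3, 5."""
    v = np.asarray(no_fb_epochs, dtype=float)
    if len(v) < 6:
        raise ValueError("need at least 6 no-feedback epochs")
    implicit = float(np.nanmean(v[[1, 3, 5]]))
    explicit = float(total - np.nanmean(v[[0, 2, 4]]))
    return implicit, explicit


SPONTANEOUS_RECOVERY_PERIODS = {
    "baseline": (0, 10),  # cycles 1-10
    "counter_rotation_end": (78, 80),  # cycles 79-80
    "no_feedback": (80, 100),  # cycles 81-100
}


def spontaneous_recovery_periods(series: EpochSeries) -> dict[str, float]:
    """Mean movement angle over the three spontaneous-recovery periods:
    baseline (cycles 1-10), end of counter-rotation (79-80) and the
    no-aiming period (81-100)."""
    if len(series) < 100:
        raise ValueError("spontaneous-recovery series must have >= 100 epochs")
    return {
        name: float(np.nanmean(series.values[a:b]))
        for name, (a, b) in SPONTANEOUS_RECOVERY_PERIODS.items()
    }


def preparation_time_summary(
    session: SessionData, adjust_screen_delay: bool = False
) -> tuple[float, float, float]:
    """Median reaction time over the baseline and rotation periods and the
    rotation-minus-baseline change.

    Medians are used because RTs show occasional extreme values.  With
    ``adjust_screen_delay`` the average display latency is subtracted from
    both medians (the change is unaffected).
    """
    df = session.trials
    rt = df["reaction_time_ms"].to_numpy(dtype=float)
    if "valid" in df:
        rt = np.where(df["valid"].to_numpy(dtype=bool), rt, np.nan)
    phases = df["phase"].to_numpy()
    base = rt[phases == Phase.BASELINE.value]
    rot = rt[np.isin(phases, [Phase.ROTATION1.value, Phase.ROTATION2.value])]
    med = lambda v: float(np.nanmedian(v)) if np.isfinite(v).any() else np.nan
    b, r = med(base), med(rot)
    if adjust_screen_delay:
        b = task_rules.adjust_for_screen_delay(b) if np.isfinite(b) else b
        r = task_rules.adjust_for_screen_delay(r) if np.isfinite(r) else r
    return b, r, r - b


def session_metrics(
    session: SessionData,
    schedule: TrialSchedule | None = None,
    n_pre: int = 3,
    implicit_variant: str = "early",
) -> MetricsResult:
    """Full per-participant summary for a single-exposure aftereffect
    session (decomposition, periods where applicable, RT medians).

    Savings / interference metrics require two exposures; use
    :func:`two_exposure_metrics` for those designs.
    """
    series = epoch_average(session)
    res = MetricsResult(participant_id=session.participant_id)
    if Phase.NO_FEEDBACK in series.phases:
        start = series.phase_start(
            Phase.ROTATION1 if Phase.ROTATION1 in series.phases else Phase.ROTATION2
        )
        adjusted = baseline_subtract(series, start, n_pre=n_pre)
        dec = decompose(adjusted, implicit_variant=implicit_variant)
        res.total_adaptation_deg = dec.total_adaptation_deg
        res.implicit_early_deg = dec.implicit_early_deg
        res.implicit_late_deg = dec.implicit_late_deg
        res.implicit_full_deg = dec.implicit_full_deg
        res.explicit_deg = dec.explicit_deg
    if len(series) >= 100 and Phase.COUNTER_ROTATION in series.phases:
        res.period_means = spontaneous_recovery_periods(series)
    res.rt_baseline_median_ms, res.rt_rotation_median_ms, res.rt_change_ms = (
        preparation_time_summary(session)
    )
    return res


def two_exposure_metrics(session: SessionData, n_pre: int = 3) -> MetricsResult:
    """Savings / interference metrics from a two-exposure session.

    Each exposure is baseline-subtracted against the 3 epochs preceding its
    onset (baseline for exposure 1, washout for exposure 2); an
    opposite-signed second rotation is sign-reversed first so both
    exposures read as positive adaptation.  Delta-angle compares the early
    change and delta-rate the constrained-exponential rates across the
    exposures (second minus first).
    """
    series = epoch_average(session)
    if Phase.ROTATION2 not in series.phases:
        raise ValueError("two-exposure metrics need a rotation2 phase")
    start1 = series.phase_start(Phase.ROTATION1)
    start2 = series.phase_start(Phase.ROTATION2)
    rot2 = session.trials.loc[
        session.trials["phase"] == Phase.ROTATION2.value, "rotation_deg"
    ]
    rot1 = session.trials.loc[
        session.trials["phase"] == Phase.ROTATION1.value, "rotation_deg"
    ]
    flip = float(rot1.mean()) * float(rot2.mean()) < 0

    s1 = baseline_subtract(series, start1, n_pre=n_pre)
    s2 = baseline_subtract(series, start2, n_pre=n_pre, sign_flip=flip)

    res = MetricsResult(participant_id=session.participant_id)
    res.delta_angle_deg = delta_angle(s1, s2, start1, start2)

    n1 = int(np.sum([p == Phase.ROTATION1 for p in series.phases]))
    n2 = int(np.sum([p == Phase.ROTATION2 for p in series.phases]))
    res.rate_1, _, _ = fit_exponential(
        s1.values[start1 : start1 + n1], y_pre=float(s1.values[start1 - 1])
    )
    res.rate_2, _, _ = fit_exponential(
        s2.values[start2 : start2 + n2], y_pre=float(s2.values[start2 - 1])
    )
    res.delta_rate = res.rate_2 - res.rate_1
    res.rt_baseline_median_ms, res.rt_rotation_median_ms, res.rt_change_ms = (
        preparation_time_summary(session)
    )
    return res


def cohort_metrics(
    sessions: list[SessionData], two_exposure: bool | None = None, **kwargs
) -> pd.DataFrame:
    """Per-participant metric rows for a cohort, as a tidy table."""
    rows = []
    for s in sessions:
        if two_exposure is None:
            auto = Phase.ROTATION2.value in set(s.trials["phase"])
        else:
            auto = two_exposure
        res = two_exposure_metrics(s, **kwargs) if auto else session_metrics(s, **kwargs)
        rows.append(res.to_row())
    return pd.DataFrame(rows)
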