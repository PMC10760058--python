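"""Session-file and report I/O.

Per-trial session records use a plain-text, comma-delimited dialect with a
``#``-prefixed header block of experiment-level keys (participant id,
paradigm, seed, device metadata).  Files are diff-able, spreadsheet-safe
and round-trip lossless; unknown columns are preserved.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .simulator import SessionData

SESSION_COLUMNS = [
    "trial",
    "target_id",
    "rotation_deg",
    "phase",
    "feedback_mode",
    "movement_angle_deg",
    "reaction_time_ms",
    "movement_time_ms",
    "valid",
    "point_awarded",
]


def write_session(session: SessionData, path) -> None:
    """Write one participant session as a commented-header CSV (.txt/.csv)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# participant_id={session.participant_id}\n")
        fh.write(f"# paradigm={session.paradigm_name}\n")
        fh.write(f"# seed={session.seed}\n")
        fh.write(f"# epoch_size={session.epoch_size}\n")
        for key, val in session.meta.items():
            fh.write(f"# {key}={val}\n")
        cols = SESSION_COLUMNS + [c for c in session.trials.columns if c not in SESSION_COLUMNS]
        session.trials.to_csv(fh, index=False, columns=cols)


def read_session(path) -> SessionData:
    """Read a session file back; malformed rows raise with the line number."""
    header: dict[str, str] = {}
    body_lines: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                key, _, val = stripped.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
            else:
                body_lines.append((lineno, stripped))
    if not body_lines:
        raise ValueError(f"{path}: no trial rows")
    n_fields = len(body_lines[0][1].split(","))
    for lineno, row in body_lines[1:]:
        if len(row.split(",")) != n_fields:
            raise ValueError(f"{path}: malformed row at line {lineno}")
    df = pd.read_csv(_io.StringIO("\n".join(r for _, r in body_lines)))
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return SessionData(
        trials=df,
        paradigm_name=header.pop("paradigm", "unknown"),
        participant_id=header.pop("participant_id", Path(path).stem),
        seed=int(header.pop("seed", 0)),
        epoch_size=int(header.pop("epoch_size", 4)),
        meta=header,
    )


@dataclass
class RunConfig:
    """Declarative description of a full design/simulate/analyze run."""

    paradigm: str = "standard"
    seed: int = 0
    n_participants: int = 25
    rotation_deg: float = 30.0
    rotation_sd_deg: float = 0.0
    implicit_variant: str = "early"
    adjust_screen_delay: bool = False
    n_pre: int = 3
    modifiers: dict = field(default_factory=dict)
    simulator: dict = field(default_factory=dict)
    out_dir: str = "."

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def write_stats_report(results: list[dict] | dict, path) -> None:
    """Emit test results as a tidy JSON report."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, default=str)
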