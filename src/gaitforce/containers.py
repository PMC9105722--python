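"""Shared domain containers.

Conventions used throughout the package:

* All sample indices are 0-based; intervals are half-open ``[on, off)``.
* GRF components are ordered (vertical, anterior-posterior, medial-lateral);
  the anterior-posterior sign convention is propulsion positive.
* Stance-phase curves are time-normalized to 101 nodes (0-100 % of stance).
* Model-facing pressure is the five region sums divided by body mass
  (kPa/kg); model-facing GRF is in body weights (BW).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

N_SENSORS = 99
N_NODES = 101
GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class Condition:
    """A treadmill condition: belt speed (m/s) and slope (degrees).

    Negative slope is decline. The simulator accepts slopes in [-15, 15].
    """

    speed: float
    slope: float

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError(f"speed must be positive, got {self.speed}")
        if not -15.0 <= self.slope <= 15.0:
            raise ValueError(f"slope must lie in [-15, 15] deg, got {self.slope}")

    @property
    def key(self) -> str:
        return f"v{self.speed:.1f}_s{self.slope:+.0f}"


def protocol_conditions() -> list[Condition]:
    """The eleven graded-running conditions of the study protocol.

    Level ground at 2.6, 3.0, 3.4 and 3.8 m/s; six degrees inclined at
    2.6, 2.8 and 3.0 m/s; six degrees declined at 2.6, 2.8, 3.0 and 3.4 m/s.
    """
    level = [Condition(v, 0.0) for v in (2.6, 3.0, 3.4, 3.8)]
    uphill = [Condition(v, 6.0) for v in (2.6, 2.8, 3.0)]
    downhill = [Condition(v, -6.0) for v in (2.6, 2.8, 3.0, 3.4)]
    return level + uphill + downhill


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata.

    ``idiosyncratic_gain`` scales the subject's pressure-to-force
    relationship (insoles under-read for gain > 1); it is the simulator's
    handle for subject-specific model error.
    """

    subject_id: str
    mass: float  # kg
    footstrike: str = "rearfoot"  # {rearfoot, forefoot}
    idiosyncratic_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.idiosyncratic_gain <= 0:
            raise ValueError("idiosyncratic_gain must be positive")
        if self.footstrike not in ("rearfoot", "forefoot"):
            raise ValueError(f"unknown footstrike {self.footstrike!r}")


@dataclass
class RawTrial:
    """One dual-rate recording: insole pressure and force-plate GRF.

    ``pressure`` is [T_p x 99] kPa at ``fs_pressure``; ``grf`` is [T_g x 3] N
    (vertical, A/P, M/L) in the treadmill (belt-aligned) frame at ``fs_grf``.
    ``true_lag`` / ``true_step_intervals`` are simulator-only ground truth.
    """

    pressure: np.ndarray
    grf: np.ndarray
    condition: Condition
    subject: SubjectMeta
    foot: str
    fs_pressure: float = 100.0
    fs_grf: float = 2400.0
    true_lag: int | None = None
    true_step_intervals: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.grf = np.asarray(self.grf, dtype=float)
        if self.pressure.ndim != 2 or self.pressure.shape[1] != N_SENSORS:
            raise ValueError(f"pressure must be [T x {N_SENSORS}]")
        if self.grf.ndim != 2 or self.grf.shape[1] != 3:
            raise ValueError("grf must be [T x 3]")
        if self.foot not in ("left", "right"):
            raise ValueError(f"foot must be left or right, got {self.foot!r}")


@dataclass
class Step:
    """One stance phase, time-normalized to 101 nodes.

    ``pr`` holds the five mass-normalized pressure-region curves PR1-PR5
    [5 x 101]; ``grf_vert`` and ``grf_ap`` are the target GRF components in BW.
    """

    pr: np.ndarray
    grf_vert: np.ndarray
    grf_ap: np.ndarray
    condition: Condition
    subject_id: str
    foot: str
    stance_duration: float
    mass: float | None = None  # kg; carried along for sequence models

    def __post_init__(self) -> None:
        self.pr = np.asarray(self.pr, dtype=float)
        self.grf_vert = np.asarray(self.grf_vert, dtype=float)
        self.grf_ap = np.asarray(self.grf_ap, dtype=float)
        if self.pr.shape != (5, N_NODES):
            raise ValueError(f"pr must be [5 x {N_NODES}], got {self.pr.shape}")
        if self.grf_vert.shape != (N_NODES,) or self.grf_ap.shape != (N_NODES,):
            raise ValueError(f"GRF channels must have {N_NODES} nodes")


class StepDataset:
    """A collection of steps with subject/condition/foot indexing."""

    def __init__(self, steps: Sequence[Step]):
        self.steps: list[Step] = list(steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterator[Step]:
        return iter(self.steps)

    def __getitem__(self, i: int) -> Step:
        return self.steps[i]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.steps:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    @property
    def conditions(self) -> list[Condition]:
        seen: dict[str, Condition] = {}
        for s in self.steps:
            seen.setdefault(s.condition.key, s.condition)
        return list(seen.values())

    def filter(
        self,
        subjects: Sequence[str] | None = None,
        condition: Condition | None = None,
        foot: str | None = None,
    ) -> "StepDataset":
        out = []
        subj = set(subjects) if subjects is not None else None
        for s in self.steps:
            if subj is not None and s.subject_id not in subj:
                continue
            if condition is not None and s.condition.key != condition.key:
                continue
            if foot is not None and s.foot != foot:
                continue
            out.append(s)
        return StepDataset(out)

    def counts(self) -> pd.DataFrame:
        """Step counts per (subject, condition, foot)."""
        rows = [
            {
                "subject": s.subject_id,
                "condition": s.condition.key,
                "foot": s.foot,
            }
            for s in self.steps
        ]
        if not rows:
            return pd.DataFrame(columns=["subject", "condition", "foot", "n_steps"])
        df = pd.DataFrame(rows)
        return (
            df.groupby(["subject", "condition", "foot"])
            .size()
            .rename("n_steps")
            .reset_index()
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """Stack into pr [N x 5 x 101], grf [N x 2 x 101] and a metadata table."""
        pr = np.stack([s.pr for s in self.steps])
        grf = np.stack([np.vstack([s.grf_vert, s.grf_ap]) for s in self.steps])
        meta = pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.steps],
                "speed": [s.condition.speed for s in self.steps],
                "slope": [s.condition.slope for s in self.steps],
                "foot": [s.foot for s in self.steps],
                "stance_duration": [s.stance_duration for s in self.steps],
            }
        )
        return pr, grf, meta
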