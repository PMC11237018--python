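"""Trial-sequence generation for the eight-alternative response task (8ART).

The task presents eight shapes above eight white squares; on each trial one
shape appears inside one of the squares and the participant responds with the
finger assigned to that shape.  Two within-subject conditions are generated:

* **Motor inhibition (MI)** — shapes usually appear beneath their matching
  shape (congruent trials), inducing a prepotent location-driven response.
  Every third to fifth trial the shape appears elsewhere (incongruent trial)
  and the location-driven tendency must be overridden.
* **Interference suppression (IS)** — each shape has a mirrored counterpart
  acting as a perceptually similar distractor.  Shapes never appear beneath
  their own square nor beneath their mirror's square, so every trial carries
  distractor interference.

Locations are indexed 0–7 left to right.  All randomness is driven by a
caller-supplied seed, so sequences are byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ShapeSet",
    "MIDesign",
    "ISDesign",
    "TrialSpec",
    "ConstraintReport",
    "generate_mi_sequence",
    "generate_is_sequence",
    "validate_sequence",
    "trials_to_frame",
    "frame_to_trials",
]


class ConfigurationError(ValueError):
    """Raised when a design or shape set is internally inconsistent."""


@dataclass(frozen=True)
class ShapeSet:
    """The eight task shapes, their mirror pairing and home squares.

    ``mirror_of`` must be an involution without fixed points (each shape is
    the mirror of exactly one *other* shape); ``home_location`` must be a
    bijection onto 0–7.
    """

    shapes: tuple[str, ...] = tuple(f"shape{i}" for i in range(8))
    mirror_of: dict[str, str] = field(default_factory=dict)
    home_location: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.mirror_of:
            # default pairing: left-half shape i <-> right-half shape i+4
            object.__setattr__(
                self,
                "mirror_of",
                {
                    **{self.shapes[i]: self.shapes[i + 4] for i in range(4)},
                    **{self.shapes[i + 4]: self.shapes[i] for i in range(4)},
                },
            )
        if not self.home_location:
            object.__setattr__(
                self, "home_location", {s: i for i, s in enumerate(self.shapes)}
            )
        self.validate()

    def validate(self) -> None:
        if len(self.shapes) != 8 or len(set(self.shapes)) != 8:
            raise ConfigurationError("need exactly 8 distinct shapes")
        for s in self.shapes:
            m = self.mirror_of.get(s)
            if m is None or m == s or self.mirror_of.get(m) != s:
                raise ConfigurationError(
                    "mirror_of must be a fixed-point-free involution"
                )
        if sorted(self.home_location.get(s, -1) for s in self.shapes) != list(
            range(8)
        ):
            raise ConfigurationError("home_location must be a bijection onto 0..7")

    def shape_at(self, location: int) -> str:
        """Shape whose home square is ``location``."""
        for s, loc in self.home_location.items():
            if loc == location:
                return s
        raise KeyError(location)


@dataclass(frozen=True)
class MIDesign:
    """Motor-inhibition condition layout: 10 blocks × 80 trials."""

    n_blocks: int = 10
    trials_per_block: int = 80
    incongruent_gap_choices: tuple[int, ...] = (3, 4, 5)
    iti_choices_ms: tuple[int, ...] = (550, 600, 650)
    rt_limit_ms: float = 1000.0

    def __post_init__(self):
        if self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ConfigurationError("counts must be positive")
        if not self.incongruent_gap_choices or min(self.incongruent_gap_choices) < 1:
            raise ConfigurationError("gap choices must be >= 1")


@dataclass(frozen=True)
class ISDesign:
    """Interference-suppression condition layout: 6 blocks × 80 trials."""

    n_blocks: int = 6
    trials_per_block: int = 80
    iti_choices_ms: tuple[int, ...] = (550, 600, 650)
    rt_limit_ms: float = 1000.0

    def __post_init__(self):
        if self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ConfigurationError("counts must be positive")


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial."""

    condition: str  # "MI" | "IS"
    block: int
    trial_index: int  # within condition
    target_shape: str
    location: int
    congruent: Optional[bool]  # MI only; None for IS
    distractor_shape: Optional[str]  # IS only; shape owning the square used
    iti_ms: int
    practice: bool = False


@dataclass
class ConstraintReport:
    violations: list[tuple[int, str, str]]
    incongruent_fraction: Optional[float]

    @property
    def ok(self) -> bool:
        return not self.violations


def _draw_gap(rng: np.random.Generator, choices: tuple[int, ...]) -> int:
    return int(choices[rng.integers(len(choices))])


def generate_mi_sequence(
    design: MIDesign,
    shapes: ShapeSet,
    seed: int,
    practice: bool = False,
) -> list[TrialSpec]:
    """Generate the motor-inhibition trial sequence.

    Congruent trials place the target on its home square.  Between consecutive
    incongruent trials there are ``g - 1`` congruent trials, with ``g`` drawn
    uniformly from ``design.incongruent_gap_choices``; the first incongruent
    trial is placed after an initial gap drawn the same way, so the sequence
    never starts incongruent and the prepotent tendency is induced first.
    Block boundaries do not reset the gap counter.
    """
    rng = np.random.default_rng(seed)
    n = design.n_blocks * design.trials_per_block
    trials: list[TrialSpec] = []
    next_incongruent = _draw_gap(rng, design.incongruent_gap_choices)
    for i in range(n):
        target = shapes.shapes[rng.integers(8)]
        home = shapes.home_location[target]
        if i + 1 == next_incongruent:
            # place on one of the 7 non-home squares, uniformly
            offset = 1 + rng.integers(7)
            location = (home + int(offset)) % 8
            congruent = False
            next_incongruent += _draw_gap(rng, design.incongruent_gap_choices)
        else:
            location = home
            congruent = True
        trials.append(
            TrialSpec(
                condition="MI",
                block=i // design.trials_per_block,
                trial_index=i,
                target_shape=target,
                location=location,
                congruent=congruent,
                distractor_shape=None,
                iti_ms=int(design.iti_choices_ms[rng.integers(len(design.iti_choices_ms))]),
                practice=practice,
            )
        )
    return trials


def generate_is_sequence(
    design: ISDesign,
    shapes: ShapeSet,
    seed: int,
    practice: bool = False,
) -> list[TrialSpec]:
    """Generate the interference-suppression trial sequence.

    Targets are uniform over the eight shapes; the location is uniform over
    the six squares excluding the target's home square and its mirror's home
    square.  The shape whose home square is used becomes the distractor.
    """
    shapes.validate()
    rng = np.random.default_rng(seed)
    n = design.n_blocks * design.trials_per_block
    trials: list[TrialSpec] = []
    for i in range(n):
        target = shapes.shapes[rng.integers(8)]
        banned = {
            shapes.home_location[target],
            shapes.home_location[shapes.mirror_of[target]],
        }
        admissible = [loc for loc in range(8) if loc not in banned]
        location = int(admissible[rng.integers(len(admissible))])
        trials.append(
            TrialSpec(
                condition="IS",
                block=i // design.trials_per_block,
                trial_index=i,
                target_shape=target,
                location=location,
                congruent=None,
                distractor_shape=shapes.shape_at(location),
                iti_ms=int(design.iti_choices_ms[rng.integers(len(design.iti_choices_ms))]),
                practice=practice,
            )
        )
    return trials


def validate_sequence(
    trials: list[TrialSpec],
    shapes: ShapeSet,
    gap_choices: Optional[tuple[int, ...]] = (3, 4, 5),
) -> ConstraintReport:
    """Check a trial sequence against the task's placement and gap rules."""
    if not trials:
        raise ValueError("empty sequence")
    violations: list[tuple[int, str, str]] = []
    condition = trials[0].condition
    incong = 0
    last_incong: Optional[int] = None
    for t in trials:
        home = shapes.home_location[t.target_shape]
        if t.condition != condition:
            violations.append((t.trial_index, "condition", "mixed conditions"))
        if t.condition == "MI":
            if t.congruent and t.location != home:
                violations.append(
                    (t.trial_index, "placement", "congruent trial off home square")
                )
            if not t.congruent:
                incong += 1
                if t.location == home:
                    violations.append(
                        (t.trial_index, "placement", "incongruent trial on home square")
                    )
                if last_incong is not None and gap_choices:
                    gap = t.trial_index - last_incong
                    if gap not in gap_choices:
                        violations.append(
                            (
                                t.trial_index,
                                "gap",
                                f"inter-incongruent gap {gap} not in {sorted(gap_choices)}",
                            )
                        )
                last_incong = t.trial_index
        else:  # IS
            mirror_home = shapes.home_location[shapes.mirror_of[t.target_shape]]
            if t.location == home:
                violations.append(
                    (t.trial_index, "placement", "target on its home square")
                )
            if t.location == mirror_home:
                violations.append(
                    (t.trial_index, "placement", "target on its mirror's home square")
                )
            if t.distractor_shape != shapes.shape_at(t.location):
                violations.append(
                    (t.trial_index, "distractor", "distractor/location mismatch")
                )
    frac = incong / len(trials) if condition == "MI" else None
    return ConstraintReport(violations=violations, incongruent_fraction=frac)


_COLUMNS = [
    "condition",
    "block",
    "trial_index",
    "target_shape",
    "location",
    "congruent",
    "distractor_shape",
    "iti_ms",
]


def trials_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """Trial table as a DataFrame (TSV-serialisable, stable column order)."""
    return pd.DataFrame(
        [
            {
                "condition": t.condition,
                "block": t.block,
                "trial_index": t.trial_index,
                "target_shape": t.target_shape,
                "location": t.location,
                "congruent": t.congruent,
                "distractor_shape": t.distractor_shape,
                "iti_ms": t.iti_ms,
            }
            for t in trials
        ],
        columns=_COLUMNS,
    )


def frame_to_trials(df: pd.DataFrame) -> list[TrialSpec]:
    out = []
    for row in df.itertuples(index=False):
        congruent = None if pd.isna(row.congruent) else bool(row.congruent)
        distractor = (
            None
            if (row.distractor_shape is None or pd.isna(row.distractor_shape))
            else str(row.distractor_shape)
        )
        out.append(
            TrialSpec(
                condition=str(row.condition),
                block=int(row.block),
                trial_index=int(row.trial_index),
                target_shape=str(row.target_shape),
                location=int(row.location),
                congruent=congruent,
                distractor_shape=distractor,
                iti_ms=int(row.iti_ms),
            )
        )
    return out
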