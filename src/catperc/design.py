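"""Stimulus continua and trial schedules for categorical-perception experiments.

Two speech continua are modelled: a 7-step Mandarin Tone 1-2 (F0 onset)
continuum and a 10-step /pa/-/pʰa/ voice-onset-time (VOT) continuum.  Only
the acoustic design parameters are represented — the analysis consumes
stimulus indices, never waveforms.

Schedules are multisets of trials in a seeded random order: the trial
multiset is a deterministic function of the design, the order a
deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "ContinuumSpec",
    "Trial",
    "TrialSchedule",
    "make_tone_continuum",
    "make_vot_continuum",
    "make_identification_schedule",
    "make_discrimination_schedule",
    "make_practice_blocks",
    "discrimination_pairs",
    "schedule_to_frame",
    "schedule_from_frame",
]

#: Stimuli whose practice-block identification must reach the screening rate.
SCREENED_STIMULI = {"tone": (1, 2, 6, 7), "vot": (1, 2, 9, 10)}

#: Practice-block identification stimulus lists (each played twice).
PRACTICE_ID_STIMULI = {"tone": (1, 2, 4, 6, 7), "vot": (1, 2, 5, 6, 9, 10)}

#: Practice-block discrimination pair lists (each repeated three times).
PRACTICE_DISC_PAIRS = {
    "tone": ((1, 1), (2, 4), (3, 5), (1, 7)),
    "vot": ((1, 1), (5, 7), (6, 8), (10, 10), (1, 10)),
}

SCHEDULE_COLUMNS = [
    "experiment",
    "task",
    "block",
    "trial_index",
    "stimulus_a",
    "stimulus_b",
    "pair_kind",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Acoustic description of one continuum step (1-based ``index``).

    F0 fields apply to the tone continuum (Hz), ``vot_ms`` to the VOT
    continuum; unused fields are None.
    """

    index: int
    onset_f0: Optional[float] = None
    offset_f0: Optional[float] = None
    vot_ms: Optional[float] = None
    duration_ms: float = 0.0
    intensity_db: Optional[float] = None


@dataclass(frozen=True)
class ContinuumSpec:
    """An ordered stimulus continuum (``continuum_id`` is 'tone' or 'vot')."""

    continuum_id: str
    stimuli: tuple[StimulusSpec, ...]

    @property
    def n_steps(self) -> int:
        return len(self.stimuli)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.stimuli)

    def __post_init__(self) -> None:
        if self.indices != tuple(range(1, len(self.stimuli) + 1)):
            raise ValueError("stimuli must be indexed 1..n_steps in order")


@dataclass(frozen=True)
class Trial:
    """One presentation: a single stimulus (identification, ``stimulus_b``
    None) or an ordered pair (discrimination)."""

    trial_index: int
    stimulus_a: int
    stimulus_b: Optional[int] = None
    pair_kind: Optional[str] = None  # "same" | "different" | None

    def __post_init__(self) -> None:
        if self.stimulus_b is not None:
            expected = "same" if self.stimulus_a == self.stimulus_b else "different"
            if self.pair_kind != expected:
                raise ValueError(
                    f"pair ({self.stimulus_a}, {self.stimulus_b}) must have "
                    f"pair_kind {expected!r}, got {self.pair_kind!r}"
                )


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered list of trials for one task block of one experiment."""

    experiment: str
    task: str  # "identification" | "discrimination"
    block: str  # "practice" | "formal"
    trials: tuple[Trial, ...]
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.trials)


def make_tone_continuum() -> ContinuumSpec:
    """The 7-step Tone 1-2 continuum.

    Onset F0 of stimulus k is 140 − 10·(k − 1) Hz; the offset is fixed at
    140 Hz, so stimulus 1 is a level tone and stimulus 7 a rising tone.
    Every token is 500 ms long at 70 dB.
    """
    stimuli = tuple(
        StimulusSpec(
            index=k,
            onset_f0=140.0 - 10.0 * (k - 1),
            offset_f0=140.0,
            duration_ms=500.0,
            intensity_db=70.0,
        )
        for k in range(1, 8)
    )
    return ContinuumSpec("tone", stimuli)


def make_vot_continuum() -> ContinuumSpec:
    """The 10-step VOT continuum: 0–90 ms in 10-ms increments, 300-ms vowel."""
    stimuli = tuple(
        StimulusSpec(index=k, vot_ms=10.0 * (k - 1), duration_ms=300.0)
        for k in range(1, 11)
    )
    return ContinuumSpec("vot", stimuli)


def get_continuum(experiment: str) -> ContinuumSpec:
    if experiment == "tone":
        return make_tone_continuum()
    if experiment == "vot":
        return make_vot_continuum()
    raise ValueError(f"unknown experiment {experiment!r}; expected 'tone' or 'vot'")


def _shuffled(trials: list[tuple], seed: Optional[int]) -> list[tuple]:
    """Seeded Fisher-Yates permutation (order varies with seed, multiset
    does not)."""
    out = list(trials)
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(out)
    return out


def _build(experiment, task, block, raw, seed) -> TrialSchedule:
    shuffled = _shuffled(raw, seed)
    trials = tuple(
        Trial(
            trial_index=i + 1,
            stimulus_a=a,
            stimulus_b=b,
            pair_kind=None if b is None else ("same" if a == b else "different"),
        )
        for i, (a, b) in enumerate(shuffled)
    )
    return TrialSchedule(experiment, task, block, trials, seed)


def make_identification_schedule(
    continuum: ContinuumSpec, reps: int = 8, seed: Optional[int] = 0
) -> TrialSchedule:
    """Formal identification block: every stimulus ``reps`` times in seeded
    random order (7 stimuli × 8 reps = 56 trials; 10 × 8 = 80)."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    raw = [(k, None) for k in continuum.indices for _ in range(reps)]
    return _build(continuum.continuum_id, "identification", "formal", raw, seed)


def discrimination_pairs(continuum: ContinuumSpec, step: int = 2) -> list[tuple[int, int]]:
    """The comparison list of an AX block: forward pairs (i, i+step),
    reverse pairs (i+step, i) and every identical pair (i, i).

    17 comparisons for the tone continuum at step 2 (10 different + 7
    identical), 26 for VOT (16 + 10).
    """
    n = continuum.n_steps
    if not 1 <= step < n:
        raise ValueError(f"step must be in [1, {n - 1}], got {step}")
    forward = [(i, i + step) for i in range(1, n - step + 1)]
    reverse = [(j, i) for i, j in forward]
    identical = [(i, i) for i in range(1, n + 1)]
    return forward + reverse + identical


def make_discrimination_schedule(
    continuum: ContinuumSpec, step: int = 2, reps: int = 5, seed: Optional[int] = 0
) -> TrialSchedule:
    """Formal AX block: every comparison repeated ``reps`` times in seeded
    random order (tone: 17 × 5 = 85 trials; vot: 26 × 5 = 130)."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    pairs = discrimination_pairs(continuum, step)
    raw = [(a, b) for a, b in pairs for _ in range(reps)]
    return _build(continuum.continuum_id, "discrimination", "formal", raw, seed)


def make_practice_blocks(
    experiment: str, seed: Optional[int] = 0
) -> tuple[TrialSchedule, TrialSchedule]:
    """Practice blocks for one experiment.

    Identification practice plays a fixed near-endpoint-heavy stimulus list
    twice (tone: 1, 2, 4, 6, 7; vot: 1, 2, 5, 6, 9, 10); discrimination
    practice repeats a fixed pair list three times (tone: 12 trials; vot:
    15 trials).  Passing the screening rule is checked offline via
    :func:`catperc.identification.screen_practice`.
    """
    if experiment not in PRACTICE_ID_STIMULI:
        raise ValueError(f"unknown experiment {experiment!r}")
    id_raw = [(k, None) for k in PRACTICE_ID_STIMULI[experiment] for _ in range(2)]
    disc_raw = [(a, b) for a, b in PRACTICE_DISC_PAIRS[experiment] for _ in range(3)]
    ident = _build(experiment, "identification", "practice", id_raw, seed)
    disc = _build(
        experiment, "discrimination", "practice", disc_raw, None if seed is None else seed + 1
    )
    return ident, disc


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """One row per trial, lossless (see :func:`schedule_from_frame`)."""
    rows = [
        {
            "experiment": schedule.experiment,
            "task": schedule.task,
            "block": schedule.block,
            "trial_index": t.trial_index,
            "stimulus_a": t.stimulus_a,
            "stimulus_b": t.stimulus_b if t.stimulus_b is not None else pd.NA,
            "pair_kind": t.pair_kind if t.pair_kind is not None else pd.NA,
        }
        for t in schedule.trials
    ]
    df = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    df["stimulus_b"] = df["stimulus_b"].astype("Int64")
    return df


def schedule_from_frame(df: pd.DataFrame, seed: Optional[int] = None) -> TrialSchedule:
    if df.empty:
        raise ValueError("empty schedule table")
    for col in ("experiment", "task", "block"):
        if df[col].nunique() != 1:
            raise ValueError(f"schedule table mixes several values of {col!r}")
    trials = tuple(
        Trial(
            trial_index=int(r.trial_index),
            stimulus_a=int(r.stimulus_a),
            stimulus_b=None if pd.isna(r.stimulus_b) else int(r.stimulus_b),
            pair_kind=None if pd.isna(r.pair_kind) else str(r.pair_kind),
        )
        for r in df.itertuples()
    )
    first = df.iloc[0]
    return TrialSchedule(
        str(first["experiment"]), str(first["task"]), str(first["block"]), trials, seed
    )


def write_schedule(schedule: TrialSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def read_schedule(path) -> TrialSchedule:
    return schedule_from_frame(pd.read_csv(path))
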