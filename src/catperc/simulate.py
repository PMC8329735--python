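"""Synthetic listeners with a dual-process AX response model.

Identification follows a two-parameter cumulative-normal psychometric
function with an optional lapse floor/ceiling.  Discrimination combines
two routes, mirroring the dual-memory account of AX performance:

* a *categorical* route — each stimulus of the pair receives an
  independent covert category label drawn from the listener's own
  identification function, and the pair sounds "different" whenever the
  labels disagree (the classic Haskins prediction);
* an *auditory-trace* route — a residual raw-acoustic difference signal
  that fires with probability ``aud_resid · min(1, |i−j|/step)``,
  independent of category structure (never for physically identical
  pairs).

The listener answers "different" if either route fires, otherwise
answers "different" with probability ``false_alarm``.  With
``aud_resid = false_alarm = lapse = 0`` the model collapses exactly to
the Haskins covert-label prediction, which provides a closed-form
oracle for tests.

Boundary width is parameterised as the 25th-to-75th percentile distance
of the identification curve; the probit scale is ``width / (2 z_{0.75})``
with the exact normal quantile, so generator and analysis agree to
machine precision.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ContinuumSpec, TrialSchedule, get_continuum

__all__ = [
    "Z75",
    "ListenerProfile",
    "GroupSpec",
    "ident_prob",
    "simulate_identification",
    "simulate_discrimination",
    "make_cohort",
    "default_group_specs",
    "haskins_different_prob",
]

#: 75th percentile of the standard normal; links width to the probit scale.
Z75 = float(norm.ppf(0.75))

RESPONSE_COLUMNS = [
    "listener_id",
    "group",
    "experiment",
    "task",
    "block",
    "trial_index",
    "stimulus_a",
    "stimulus_b",
    "response",
]


@dataclass(frozen=True)
class ListenerProfile:
    """Generative parameters of one synthetic participant.

    ``mu`` is the category boundary and ``width`` the 25th–75th percentile
    distance, both in stimulus-index units.  ``lapse`` is the probability
    of a stimulus-independent identification guess; ``aud_resid`` scales
    the auditory-trace route and ``false_alarm`` the baseline "different"
    rate in discrimination.
    """

    listener_id: str
    group: str
    mu: float
    width: float
    lapse: float = 0.0
    aud_resid: float = 0.0
    false_alarm: float = 0.0
    seed: int = 0
    age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if not 0 <= self.lapse <= 0.2:
            raise ValueError("lapse must be in [0, 0.2]")
        if not 0 <= self.aud_resid <= 1:
            raise ValueError("aud_resid must be in [0, 1]")
        if not 0 <= self.false_alarm <= 0.5:
            raise ValueError("false_alarm must be in [0, 0.5]")

    @property
    def sigma(self) -> float:
        """Probit scale implied by the percentile-distance width."""
        return self.width / (2.0 * Z75)

    def rng(self, task: str) -> np.random.Generator:
        """Listener-private stream keyed by (seed, listener_id, task)."""
        key = zlib.crc32(f"{self.listener_id}|{task}".encode())
        return np.random.default_rng([self.seed, key])


def ident_prob(profile: ListenerProfile, stimulus_index) -> np.ndarray | float:
    """Probability of a category-2 response to a stimulus index.

    ``lapse/2 + (1 − lapse) Φ((x − mu)/sigma)``; monotone nondecreasing in
    the index.  Accepts scalars or arrays.
    """
    x = np.asarray(stimulus_index, dtype=float)
    p = profile.lapse / 2.0 + (1.0 - profile.lapse) * norm.cdf(
        (x - profile.mu) / profile.sigma
    )
    return p if p.ndim else float(p)


def _response_frame(profile, schedule, stim_a, stim_b, responses) -> pd.DataFrame:
    n = len(responses)
    return pd.DataFrame(
        {
            "listener_id": np.repeat(profile.listener_id, n),
            "group": np.repeat(profile.group, n),
            "experiment": np.repeat(schedule.experiment, n),
            "task": np.repeat(schedule.task, n),
            "block": np.repeat(schedule.block, n),
            "trial_index": np.arange(1, n + 1),
            "stimulus_a": stim_a,
            "stimulus_b": stim_b,
            "response": responses,
        },
        columns=RESPONSE_COLUMNS,
    )


def simulate_identification(
    profile: ListenerProfile, schedule: TrialSchedule
) -> pd.DataFrame:
    """Draw one identification response per trial (labels cat1/cat2)."""
    if schedule.task != "identification":
        raise ValueError(f"expected an identification schedule, got {schedule.task!r}")
    rng = profile.rng(f"identification|{schedule.block}|{schedule.experiment}")
    x = np.array([t.stimulus_a for t in schedule.trials], dtype=float)
    p2 = np.asarray(ident_prob(profile, x))
    responses = np.where(rng.random(len(x)) < p2, "cat2", "cat1")
    return _response_frame(
        profile, schedule, x.astype(int), pd.array([pd.NA] * len(x), dtype="Int64"), responses
    )


def simulate_discrimination(
    profile: ListenerProfile, schedule: TrialSchedule, step: int = 2
) -> pd.DataFrame:
    """Draw one same/different response per AX trial via the dual-process
    model; ``step`` is the design step that normalises the auditory route."""
    if schedule.task != "discrimination":
        raise ValueError(f"expected a discrimination schedule, got {schedule.task!r}")
    rng = profile.rng(f"discrimination|{schedule.block}|{schedule.experiment}")
    a = np.array([t.stimulus_a for t in schedule.trials], dtype=float)
    b = np.array([t.stimulus_b for t in schedule.trials], dtype=float)
    n = len(a)

    label_a = rng.random(n) < np.asarray(ident_prob(profile, a))
    label_b = rng.random(n) < np.asarray(ident_prob(profile, b))
    categorical = label_a != label_b

    gap = np.abs(a - b)
    p_aud = np.where(gap > 0, profile.aud_resid * np.minimum(1.0, gap / step), 0.0)
    auditory = rng.random(n) < p_aud

    fires = categorical | auditory
    guess = rng.random(n) < profile.false_alarm
    responses = np.where(fires | guess, "different", "same")
    return _response_frame(profile, schedule, a.astype(int), b.astype(int), responses)


def haskins_different_prob(p_i: float, p_j: float) -> float:
    """Haskins covert-label prediction P("different") = p_i(1−p_j) + p_j(1−p_i)."""
    return p_i * (1.0 - p_j) + p_j * (1.0 - p_i)


@dataclass(frozen=True)
class GroupSpec:
    """Uniform parameter ranges for one cohort group.

    Point ranges (lo == hi) give identical listeners; ``n`` is the group
    size and ``age_years`` the range of chronological age.
    """

    n: int
    mu: tuple[float, float]
    width: tuple[float, float]
    lapse: tuple[float, float] = (0.0, 0.0)
    aud_resid: tuple[float, float] = (0.0, 0.0)
    false_alarm: tuple[float, float] = (0.0, 0.0)
    age_years: tuple[float, float] = (20.0, 30.0)


def default_group_specs(experiment: str = "tone") -> dict[str, GroupSpec]:
    """Study-condition cohort: 14 four-year-olds, 16 five-year-olds, 17
    six-year-olds and 14 adults.

    Width ranges encode the qualitative developmental ordering: for the
    tone continuum the younger two groups are wide and age-6 is
    adult-like; for the VOT continuum all three child groups stay wider
    than adults.  Boundary positions sit mid-continuum for every group.
    """
    if experiment == "tone":
        widths = {
            "age-4": (1.6, 2.4),
            "age-5": (1.6, 2.4),
            "age-6": (0.8, 1.2),
            "adult": (0.7, 1.1),
        }
        mu = (3.5, 4.2)
    elif experiment == "vot":
        widths = {
            "age-4": (2.0, 2.8),
            "age-5": (1.9, 2.7),
            "age-6": (1.8, 2.6),
            "adult": (1.0, 1.4),
        }
        mu = (3.3, 4.0)
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    sizes = {"age-4": 14, "age-5": 16, "age-6": 17, "adult": 14}
    ages = {
        "age-4": (4.4, 5.0),
        "age-5": (4.9, 6.1),
        "age-6": (6.0, 7.1),
        "adult": (18.0, 30.0),
    }
    return {
        g: GroupSpec(
            n=sizes[g],
            mu=mu,
            width=widths[g],
            lapse=(0.0, 0.04),
            aud_resid=(0.15, 0.3),
            false_alarm=(0.02, 0.1),
            age_years=ages[g],
        )
        for g in ("age-4", "age-5", "age-6", "adult")
    }


def make_cohort(
    group_specs: Mapping[str, GroupSpec],
    seed: int = 0,
    n_per_group: Optional[int] = None,
) -> list[ListenerProfile]:
    """Draw a cohort of listener profiles, uniform within each group's
    ranges; deterministic given ``seed`` (one parameter stream per group,
    so cohorts are stable under group reordering)."""
    profiles: list[ListenerProfile] = []
    for group in sorted(group_specs):
        spec = group_specs[group]
        n = n_per_group if n_per_group is not None else spec.n
        if n < 1:
            raise ValueError("group size must be >= 1")
        grng = np.random.default_rng([seed, zlib.crc32(group.encode())])

        def draw(lo_hi: tuple[float, float], size: int) -> np.ndarray:
            lo, hi = lo_hi
            if hi < lo:
                raise ValueError(f"empty range {lo_hi}")
            return grng.uniform(lo, hi, size) if hi > lo else np.full(size, float(lo))

        mus = draw(spec.mu, n)
        widths = draw(spec.width, n)
        lapses = draw(spec.lapse, n)
        auds = draw(spec.aud_resid, n)
        fas = draw(spec.false_alarm, n)
        ages = draw(spec.age_years, n)
        for k in range(n):
            profiles.append(
                ListenerProfile(
                    listener_id=f"{group}-{k + 1:03d}",
                    group=group,
                    mu=float(mus[k]),
                    width=float(widths[k]),
                    lapse=float(lapses[k]),
                    aud_resid=float(auds[k]),
                    false_alarm=float(fas[k]),
                    seed=seed,
                    age_years=float(ages[k]),
                )
            )
    return profiles


def cohort_metadata(profiles: Sequence[ListenerProfile]) -> pd.DataFrame:
    """Participant metadata table (listener, group, age) for group stats."""
    return pd.DataFrame(
        {
            "listener_id": [p.listener_id for p in profiles],
            "group": [p.group for p in profiles],
            "age_years": [p.age_years for p in profiles],
        }
    )


def simulate_cohort_responses(
    profiles: Sequence[ListenerProfile],
    id_schedule: TrialSchedule,
    disc_schedule: TrialSchedule,
    step: int = 2,
) -> pd.DataFrame:
    """Identification + discrimination responses for a whole cohort, one
    tidy table."""
    frames = []
    for p in profiles:
        frames.append(simulate_identification(p, id_schedule))
        frames.append(simulate_discrimination(p, disc_schedule, step=step))
    return pd.concat(frames, ignore_index=True)
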