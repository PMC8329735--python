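"""Comparison-unit discrimination scoring and between/within-category
profiles.

An AX block with step-``s`` pairs is divided into comparison units, one
per two-step pair ``(i, i+s)``.  A unit owns four trial types: AB
(``i→i+s``), BA (reverse), and the identical pairs AA (``i,i``) and BB
(``i+s,i+s``).  Adjacent units share identical-pair trials (unit
``(i, i+2)``'s BB trials are unit ``(i+2, i+4)``'s AA trials), so unit
scores are not statistically independent.

The unit's discrimination score is

    P = P("S"|S)·P(S) + P("D"|D)·P(D)

with P("S"|S) the fraction of same pairs answered "same", P("D"|D) the
fraction of different pairs answered "different", and P(S)/P(D) the
empirical share of each trial kind in the unit (exactly 0.5 each in the
balanced design used here).  Chance level is 0.5; a perfectly
categorical listener scores 1 on units straddling the boundary and 0.5
on distant within-category units.

A unit ``(i, j)`` counts as *between-category* iff the participant's own
fitted boundary lies strictly inside ``(i, j)``; everything else —
including a boundary exactly on a unit edge — is within-category.
``P_bc`` and ``P_wc`` are unweighted means of the unit scores in each
class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import ContinuumSpec
from .identification import IdentificationFit

__all__ = [
    "ComparisonUnit",
    "CPProfile",
    "build_comparison_units",
    "unit_trials",
    "unit_score",
    "classify_units",
    "cp_profile",
    "cp_profile_cohort",
    "group_discrimination_curve",
]


@dataclass(frozen=True)
class ComparisonUnit:
    """One comparison unit: the pair of stimulus indices (lower, upper)."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("upper must exceed lower")

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper}"


def build_comparison_units(continuum: ContinuumSpec, step: int = 2) -> list[ComparisonUnit]:
    """Units (i, i+step) for i = 1..n−step: five for the 7-step tone
    continuum at step 2, eight for the 10-step VOT continuum."""
    n = continuum.n_steps
    if not 1 <= step < n:
        raise ValueError(f"step must be in [1, {n - 1}], got {step}")
    return [ComparisonUnit(i, i + step) for i in range(1, n - step + 1)]


def unit_trials(responses: pd.DataFrame, unit: ComparisonUnit) -> pd.DataFrame:
    """The discrimination trials belonging to one unit: AB, BA, AA, BB."""
    a = responses["stimulus_a"]
    b = responses["stimulus_b"]
    members = {unit.lower, unit.upper}
    different = (a.isin(members)) & (b.isin(members)) & (a != b)
    same = (a == b) & a.isin(members)
    return responses[different | same]


def unit_score(unit_responses: pd.DataFrame) -> float:
    """Discrimination score P of one unit's trials (see module docstring).

    Requires at least one same and one different trial; the trial shares
    P(S)/P(D) are taken from the data, so unbalanced units remain valid.
    """
    if "pair_kind" in unit_responses.columns:
        kinds = unit_responses["pair_kind"]
    else:
        kinds = np.where(
            unit_responses["stimulus_a"] == unit_responses["stimulus_b"], "same", "different"
        )
        kinds = pd.Series(kinds, index=unit_responses.index)
    same = unit_responses[kinds == "same"]
    diff = unit_responses[kinds == "different"]
    if same.empty or diff.empty:
        raise ValueError("unit needs at least one same and one different trial")
    n = len(unit_responses)
    p_s, p_d = len(same) / n, len(diff) / n
    hit_s = float((same["response"] == "same").mean())
    hit_d = float((diff["response"] == "different").mean())
    return hit_s * p_s + hit_d * p_d


def classify_units(
    units: Sequence[ComparisonUnit], boundary_position: float
) -> list[str]:
    """Label each unit "between" (boundary strictly inside the unit) or
    "within".  A NaN/degenerate boundary labels every unit "within"."""
    labels = []
    for u in units:
        if np.isfinite(boundary_position) and u.lower < boundary_position < u.upper:
            labels.append("between")
        else:
            labels.append("within")
    return labels


@dataclass(frozen=True)
class CPProfile:
    """Per-participant discrimination summary."""

    listener_id: str
    unit_labels: tuple[str, ...]  # e.g. "1-3"
    unit_scores: tuple[float, ...]
    unit_classes: tuple[str, ...]  # "between" | "within"
    peak_unit: str
    peak_score: float
    p_bc: float
    p_wc: float
    boundary_used: float
    degenerate: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "listener_id": self.listener_id,
                "unit": self.unit_labels,
                "score": self.unit_scores,
                "classification": self.unit_classes,
            }
        )


def cp_profile(
    responses: pd.DataFrame,
    fit: IdentificationFit | float,
    continuum: ContinuumSpec,
    step: int = 2,
) -> CPProfile:
    """Score every comparison unit for one participant and derive P_bc,
    P_wc and the peak.

    ``fit`` is the participant's own identification fit (or a bare
    boundary position).  Peak ties are broken toward the unit whose
    midpoint is nearest the boundary.  Units with no trials are dropped
    with a warning; a degenerate boundary classifies all units as within
    and propagates the flag.
    """
    disc = responses[responses["task"] == "discrimination"]
    if disc.empty:
        raise ValueError("no discrimination responses")
    listeners = disc["listener_id"].unique()
    if len(listeners) != 1:
        raise ValueError("cp_profile expects a single participant")
    if isinstance(fit, IdentificationFit):
        boundary = fit.boundary_position
        degenerate = fit.degenerate
    else:
        boundary = float(fit)
        degenerate = not np.isfinite(boundary)

    units = build_comparison_units(continuum, step)
    kept_units, scores = [], []
    for u in units:
        trials = unit_trials(disc, u)
        if trials.empty:
            warnings.warn(f"unit {u.label} has no trials; dropped", stacklevel=2)
            continue
        kept_units.append(u)
        scores.append(unit_score(trials))
    if not kept_units:
        raise ValueError("no comparison unit has trials")

    classes = classify_units(kept_units, float("nan") if degenerate else boundary)
    scores_arr = np.asarray(scores)
    best = scores_arr.max()
    candidates = [i for i, s in enumerate(scores) if s == best]
    if len(candidates) > 1 and np.isfinite(boundary):
        candidates.sort(key=lambda i: abs(kept_units[i].midpoint - boundary))
    peak_i = candidates[0]

    between = [s for s, c in zip(scores, classes) if c == "between"]
    within = [s for s, c in zip(scores, classes) if c == "within"]
    return CPProfile(
        listener_id=str(listeners[0]),
        unit_labels=tuple(u.label for u in kept_units),
        unit_scores=tuple(float(s) for s in scores),
        unit_classes=tuple(classes),
        peak_unit=kept_units[peak_i].label,
        peak_score=float(best),
        p_bc=float(np.mean(between)) if between else float("nan"),
        p_wc=float(np.mean(within)) if within else float("nan"),
        boundary_used=float(boundary),
        degenerate=bool(degenerate),
    )


def cp_profile_cohort(
    responses: pd.DataFrame,
    fits: pd.DataFrame,
    continuum: ContinuumSpec,
    step: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CP profiles for every participant in a tidy response table.

    ``fits`` is the per-participant fit table from
    :func:`catperc.identification.fit_cohort`.  Returns ``(units, summary)``
    frames: per-unit scores with classifications, and one summary row per
    participant (p_bc, p_wc, peak_unit, peak_score, degenerate).
    """
    fits_ix = fits.set_index("listener_id")
    disc = responses[responses["task"] == "discrimination"]
    unit_rows, summary_rows = [], []
    for listener, sub in disc.groupby("listener_id", sort=True):
        if listener not in fits_ix.index:
            raise ValueError(f"no identification fit for participant {listener!r}")
        frow = fits_ix.loc[listener]
        fit_obj = IdentificationFit(
            a=float(frow["a"]),
            b=float(frow["b"]),
            boundary_position=float(frow["boundary_position"]),
            boundary_width=float(frow["boundary_width"]),
            converged=bool(frow["converged"]),
            degenerate=bool(frow["degenerate"]),
            n_levels=0,
            n_steps=continuum.n_steps,
        )
        prof = cp_profile(sub, fit_obj, continuum, step)
        group = sub["group"].iat[0]
        u = prof.as_frame()
        u.insert(1, "group", group)
        unit_rows.append(u)
        summary_rows.append(
            {
                "listener_id": listener,
                "group": group,
                "experiment": sub["experiment"].iat[0],
                "p_bc": prof.p_bc,
                "p_wc": prof.p_wc,
                "peak_unit": prof.peak_unit,
                "peak_score": prof.peak_score,
                "boundary_used": prof.boundary_used,
                "degenerate": prof.degenerate,
            }
        )
    return pd.concat(unit_rows, ignore_index=True), pd.DataFrame(summary_rows)


def group_discrimination_curve(
    unit_table: pd.DataFrame, method: str = "mean"
) -> pd.DataFrame:
    """Group-level discrimination curve from the per-unit score table.

    ``method="mean"`` (default) averages individual unit scores within
    each group — the convention used throughout this package; ``"median"``
    is exposed for robustness checks.
    """
    if method not in {"mean", "median"}:
        raise ValueError("method must be 'mean' or 'median'")
    agg = getattr(unit_table.groupby(["group", "unit"], sort=True)["score"], method)()
    return agg.reset_index().rename(columns={"score": f"score_{method}"})


def pooled_group_curve(
    responses: pd.DataFrame, continuum: ContinuumSpec, step: int = 2
) -> pd.DataFrame:
    """Alternative group curve: pool every participant's trials within a
    group and score each unit once on the pooled counts.  Differs from
    the mean-of-individual-scores curve when participants contribute
    unequal trial numbers."""
    disc = responses[responses["task"] == "discrimination"]
    units = build_comparison_units(continuum, step)
    rows = []
    for group, sub in disc.groupby("group", sort=True):
        for u in units:
            trials = unit_trials(sub, u)
            if trials.empty:
                continue
            rows.append({"group": group, "unit": u.label, "score_pooled": unit_score(trials)})
    return pd.DataFrame(rows)
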