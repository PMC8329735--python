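"""Per-participant identification analysis.

The identification curve is the per-stimulus proportion of category-2
responses; the psychometric model is a two-parameter probit,
``P(cat2 | x) = Φ(a + b·x)``, fitted by maximum likelihood on the
binomial counts (classic Finney-style probit analysis).  Two derived
quantities summarise the curve:

* **boundary position** — the 50% crossover, ``−a/b``;
* **boundary width** — the distance between the 25th and 75th
  percentiles of the fitted curve, ``2 z_{0.75} / b``.

Perfect separation (a step-like data set) drives the ML slope to
infinity; the fit then caps the slope at ``slope_cap`` (refitting the
intercept at the capped slope) and flags the result as degenerate, as
are fits with non-positive slope or a boundary outside the continuum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .design import SCREENED_STIMULI

__all__ = [
    "IdentificationFit",
    "tabulate_identification",
    "fit_probit",
    "screen_practice",
    "fit_cohort",
]

_Z75 = float(norm.ppf(0.75))
_PCLIP = 1e-12


def tabulate_identification(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus counts and category-2 proportion for one participant.

    Returns a frame indexed by stimulus index with columns ``n_trials``,
    ``n_cat2``, ``prop_cat2``.  Order-invariant; raises on empty input or
    a table mixing participants/experiments/tasks.
    """
    if responses.empty:
        raise ValueError("empty response table")
    for col in ("listener_id", "experiment", "task"):
        if responses[col].nunique() != 1:
            raise ValueError(f"response table mixes several values of {col!r}")
    if responses["task"].iat[0] != "identification":
        raise ValueError("expected identification responses")
    bad = set(responses["response"].unique()) - {"cat1", "cat2"}
    if bad:
        raise ValueError(f"unexpected identification responses: {sorted(bad)}")
    grouped = responses.groupby("stimulus_a", sort=True)["response"]
    table = pd.DataFrame(
        {
            "n_trials": grouped.size(),
            "n_cat2": grouped.apply(lambda s: int((s == "cat2").sum())),
        }
    )
    table.index.name = "stimulus"
    table["prop_cat2"] = table["n_cat2"] / table["n_trials"]
    return table


@dataclass(frozen=True)
class IdentificationFit:
    """Fitted probit ``P(cat2|x) = Φ(a + b·x)`` with derived boundary
    position and width (stimulus units).  ``degenerate`` fits carry NaN
    derived values and are excluded from group statistics downstream."""

    a: float
    b: float
    boundary_position: float
    boundary_width: float
    converged: bool
    degenerate: bool
    n_levels: int
    n_steps: int

    @property
    def slope(self) -> float:
        return self.b


def _neg_loglik(params, x, n, k):
    a, b = params
    p = np.clip(norm.cdf(a + b * x), _PCLIP, 1 - _PCLIP)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _working_probit_start(x, n, k):
    # Finney's adjusted empirical probits give a robust starting point.
    z = norm.ppf((k + 0.5) / (n + 1.0))
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return coef


def fit_probit(
    responses: pd.DataFrame,
    slope_cap: float = 20.0,
    n_steps: Optional[int] = None,
) -> IdentificationFit:
    """Maximum-likelihood probit fit of one participant's identification
    data.

    Works on the binomial counts per stimulus level (equivalent to
    trial-level ML).  ``slope_cap`` bounds the slope magnitude so that
    separated data yield a finite, flagged fit instead of a divergence.
    ``n_steps`` (default: the largest stimulus index seen) delimits the
    plausible boundary range [1, n_steps].
    """
    table = tabulate_identification(responses)
    if len(table) < 2:
        raise ValueError("need responses at >= 2 distinct stimulus levels")
    x = table.index.to_numpy(dtype=float)
    n = table["n_trials"].to_numpy(dtype=float)
    k = table["n_cat2"].to_numpy(dtype=float)
    if n_steps is None:
        n_steps = int(x.max())

    a0, b0 = _working_probit_start(x, n, k)
    a0 = float(np.clip(a0, -40, 40))
    b0 = float(np.clip(b0, -slope_cap + 1e-6, slope_cap - 1e-6))
    a_bound = 10.0 + slope_cap * (n_steps + 2.0)
    # Complete separation: every level is all-cat1 or all-cat2 and the
    # all-cat2 levels sit entirely above the all-cat1 levels.  The ML
    # slope is then unbounded and the fit goes straight to the capped
    # profile below.
    pure = np.all((k == 0) | (k == n))
    separated = bool(
        pure and np.any(k == 0) and np.any(k == n) and x[k == 0].max() < x[k == n].min()
    )
    if separated:
        a, b = a0, slope_cap
        converged = True
    else:
        res = minimize(
            _neg_loglik,
            x0=np.array([a0, b0]),
            args=(x, n, k),
            method="L-BFGS-B",
            bounds=[(-a_bound, a_bound), (-slope_cap, slope_cap)],
        )
        a, b = (float(v) for v in res.x)
        converged = bool(res.success)
    capped = separated or abs(b) >= slope_cap - 1e-6
    if capped and b > 0:
        # Separation: refit the crossover at the capped slope.  The
        # profile likelihood is flat over the whole separation gap, so
        # take the midpoint of the argmin set — a symmetric step curve
        # then yields the midpoint boundary.
        b = slope_cap
        grid = np.linspace(0.0, n_steps + 1.0, 4001)
        nll = np.array([_neg_loglik((-b * c, b), x, n, k) for c in grid])
        flat = grid[nll <= nll.min() + 1e-9]
        a = -b * float((flat.min() + flat.max()) / 2.0)

    if b > 0:
        boundary = -a / b
        width = 2.0 * _Z75 / b
    else:
        boundary = float("nan")
        width = float("nan")
    degenerate = bool(
        capped or b <= 0 or not np.isfinite(boundary) or not (1.0 <= boundary <= n_steps)
    )
    return IdentificationFit(
        a=a,
        b=b,
        boundary_position=boundary,
        boundary_width=width,
        converged=converged,
        degenerate=degenerate,
        n_levels=len(table),
        n_steps=n_steps,
    )


def screen_practice(
    responses: pd.DataFrame, required_rate: float = 0.9
) -> pd.DataFrame:
    """Post-hoc practice-block screening.

    A participant passes iff every screened near-endpoint stimulus (tone:
    1, 2, 6, 7; vot: 1, 2, 9, 10) was identified correctly on at least
    ``required_rate`` of its presentations (inclusive bound).  Stimuli on
    the category-1 half of the continuum count "cat1" as correct, the
    category-2 half "cat2".  Returns one row per participant with columns
    ``passed`` and ``min_rate``.
    """
    if responses.empty:
        raise ValueError("empty response table")
    experiments = responses["experiment"].unique()
    if len(experiments) != 1:
        raise ValueError("screen one experiment at a time")
    experiment = experiments[0]
    if experiment not in SCREENED_STIMULI:
        raise ValueError(f"unknown experiment {experiment!r}")
    screened = SCREENED_STIMULI[experiment]
    midpoint = (screened[0] + screened[-1]) / 2.0  # endpoints span the continuum

    rows = []
    for listener, sub in responses.groupby("listener_id", sort=True):
        rates = {}
        for s in screened:
            trials = sub[sub["stimulus_a"] == s]
            if trials.empty:
                raise ValueError(
                    f"participant {listener!r} has no practice trials for "
                    f"screened stimulus {s}"
                )
            correct = "cat1" if s < midpoint else "cat2"
            rates[s] = float((trials["response"] == correct).mean())
        min_rate = min(rates.values())
        rows.append(
            {
                "listener_id": listener,
                "min_rate": min_rate,
                "passed": bool(min_rate >= required_rate),
            }
        )
    return pd.DataFrame(rows).set_index("listener_id")


def fit_cohort(
    responses: pd.DataFrame, slope_cap: float = 20.0, n_steps: Optional[int] = None
) -> pd.DataFrame:
    """Probit fits for every participant in a tidy identification table.

    Returns one row per participant: group, experiment, a, b,
    boundary_position, boundary_width, converged, degenerate.
    """
    ident = responses[responses["task"] == "identification"]
    rows = []
    for listener, sub in ident.groupby("listener_id", sort=True):
        fit = fit_probit(sub, slope_cap=slope_cap, n_steps=n_steps)
        rows.append(
            {
                "listener_id": listener,
                "group": sub["group"].iat[0],
                "experiment": sub["experiment"].iat[0],
                "a": fit.a,
                "b": fit.b,
                "boundary_position": fit.boundary_position,
                "boundary_width": fit.boundary_width,
                "converged": fit.converged,
                "degenerate": fit.degenerate,
            }
        )
    return pd.DataFrame(rows)
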