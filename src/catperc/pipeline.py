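"""End-to-end orchestration: design → simulate (or ingest) → fit →
score → group statistics, as one reproducible run.

A run is fully determined by its :class:`RunConfig` (including seeds):
rerunning the same config produces byte-identical tables.  Every run
writes a manifest recording the config echo, per-stage row counts,
excluded participants and SHA-256 checksums of each output table, so a
silently dropped participant cannot go unnoticed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import design, discrimination, groupstats, identification, simulate

__all__ = ["RunConfig", "run_pipeline", "validate_responses", "load_config"]

log = logging.getLogger("catperc")

#: Child groups entering the age regressions (adults are controls).
CHILD_GROUPS = ("age-4", "age-5", "age-6")


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a pipeline run."""

    experiments: tuple[str, ...] = ("tone", "vot")
    reps_id: int = 8
    reps_disc: int = 5
    step: int = 2
    seed: int = 0
    out_dir: str = "catperc_run"
    slope_cap: float = 20.0
    group_curve_method: str = "mean"  # "mean" | "pooled"
    #: group → GroupSpec overrides per experiment; None = study defaults.
    cohort: Optional[Mapping[str, Mapping[str, simulate.GroupSpec]]] = None
    #: experiment → path of a response CSV; overrides simulation.
    response_files: Optional[Mapping[str, str]] = None
    #: path of a participant metadata CSV (listener_id, group, age_years);
    #: required when response_files is given and age regressions are wanted.
    metadata_file: Optional[str] = None

    def group_specs(self, experiment: str) -> dict[str, simulate.GroupSpec]:
        if self.cohort and experiment in self.cohort:
            return dict(self.cohort[experiment])
        return simulate.default_group_specs(experiment)


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file; cohort entries become GroupSpecs."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "experiments" in raw:
        raw["experiments"] = tuple(raw["experiments"])
    if raw.get("cohort"):
        cohort = {}
        for exp, groups in raw["cohort"].items():
            cohort[exp] = {
                g: simulate.GroupSpec(
                    n=int(s["n"]),
                    mu=tuple(s["mu"]),
                    width=tuple(s["width"]),
                    lapse=tuple(s.get("lapse", (0.0, 0.0))),
                    aud_resid=tuple(s.get("aud_resid", (0.0, 0.0))),
                    false_alarm=tuple(s.get("false_alarm", (0.0, 0.0))),
                    age_years=tuple(s.get("age_years", (20.0, 30.0))),
                )
                for g, s in groups.items()
            }
        raw["cohort"] = cohort
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    if echo.get("cohort"):
        echo["cohort"] = {
            exp: {g: asdict(s) if not isinstance(s, dict) else s for g, s in groups.items()}
            for exp, groups in echo["cohort"].items()
        }
    return echo


EXPECTED_RESPONSES = {"identification": {"cat1", "cat2"}, "discrimination": {"same", "different"}}


def validate_responses(
    path,
    experiment: Optional[str] = None,
    reps_id: Optional[int] = None,
    reps_disc: Optional[int] = None,
    step: int = 2,
) -> dict:
    """Structural validation of a trial-level response file.

    Checks the header, stimulus-index ranges for the experiment's
    continuum, response labels per task, and (when the declared schedule
    repetitions are given) per-participant formal-block trial counts.
    Returns ``{"n_rows": ..., "violations": [...]}``; each violation names
    the file and row.
    """
    path = Path(path)
    violations: list[str] = []
    df = pd.read_csv(path)
    missing = [c for c in simulate.RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        return {
            "n_rows": len(df),
            "violations": [f"{path.name}: missing columns {missing}"],
        }

    experiments = df["experiment"].unique() if experiment is None else [experiment]
    for exp in experiments:
        sub = df[df["experiment"] == exp]
        try:
            cont = design.get_continuum(str(exp))
        except ValueError:
            violations.append(f"{path.name}: unknown experiment {exp!r}")
            continue
        n = cont.n_steps
        for col in ("stimulus_a", "stimulus_b"):
            vals = pd.to_numeric(sub[col], errors="coerce")
            bad = sub[(vals.notna()) & ((vals < 1) | (vals > n))]
            for row in bad.index:
                violations.append(
                    f"{path.name} row {row + 2}: {col}={sub.loc[row, col]} outside 1..{n} for {exp}"
                )
        for task, allowed in EXPECTED_RESPONSES.items():
            tsub = sub[sub["task"] == task]
            bad = tsub[~tsub["response"].isin(allowed)]
            for row in bad.index:
                violations.append(
                    f"{path.name} row {row + 2}: response {tsub.loc[row, 'response']!r} "
                    f"invalid for {task}"
                )
        expected = {}
        if reps_id is not None:
            expected["identification"] = n * reps_id
        if reps_disc is not None:
            expected["discrimination"] = (2 * (n - step) + n) * reps_disc
        formal = sub[sub["block"] == "formal"] if "block" in sub.columns else sub
        for task, want in expected.items():
            counts = formal[formal["task"] == task].groupby("listener_id").size()
            for listener, got in counts.items():
                if got != want:
                    violations.append(
                        f"{path.name}: participant {listener!r} has {got} formal "
                        f"{task} trials in {exp}, expected {want}"
                    )
    return {"n_rows": len(df), "violations": violations}


def _group_statistics(
    fits: pd.DataFrame, summary: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """ANOVAs + Tukey on the four CP metrics; age regressions on children."""
    ok_fits = fits[~fits["degenerate"]]
    excluded = sorted(fits.loc[fits["degenerate"], "listener_id"])
    merged = ok_fits.merge(
        summary[["listener_id", "p_bc", "p_wc"]], on="listener_id", how="left"
    ).merge(meta[["listener_id", "age_years"]], on="listener_id", how="left")

    metrics = {
        "boundary_position": "boundary_position",
        "boundary_width": "boundary_width",
        "p_bc": "p_bc",
        "p_wc": "p_wc",
    }
    anovas = {}
    for name, col in metrics.items():
        by_group = {
            g: sub[col].to_numpy() for g, sub in merged.groupby("group") if len(sub) >= 2
        }
        if len(by_group) >= 2:
            anovas[name] = groupstats.one_way_anova(by_group)

    children = merged[merged["group"].isin(CHILD_GROUPS)]
    reg_rows = []
    if len(children) >= 3 and children["age_years"].notna().all() and np.ptp(
        children["age_years"].to_numpy(dtype=float)
    ) > 0:
        for name, col in metrics.items():
            vals = children[col].to_numpy(dtype=float)
            if np.isfinite(vals).sum() >= 3:
                r = groupstats.simple_regression(children["age_years"], vals)
                reg_rows.append(
                    {
                        "metric": name,
                        "beta0": r.beta0,
                        "beta1": r.beta1,
                        "r_sq": r.r_sq,
                        "F": r.F,
                        "p": r.p,
                        "n": r.n,
                    }
                )
    info = {
        "n_participants": int(len(fits)),
        "n_excluded_degenerate": int(fits["degenerate"].sum()),
        "excluded": excluded,
        "n_per_group": {g: int(n) for g, n in merged.groupby("group").size().items()},
    }
    return (
        groupstats.anova_table(anovas),
        groupstats.pairwise_table(anovas),
        pd.DataFrame(reg_rows),
        info,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every configured experiment; returns the manifest.

    Per experiment the run writes ``responses_<exp>.csv`` (when
    simulated), ``fits_<exp>.csv``, ``cp_units_<exp>.csv``,
    ``cp_summary_<exp>.csv``, ``anova_<exp>.csv``, ``tukey_<exp>.csv``,
    ``regressions_<exp>.csv`` and ``group_curve_<exp>.csv``, plus a
    single ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_echo(config),
        "experiments": {},
        "checksums": {},
    }

    for exp in config.experiments:
        cont = design.get_continuum(exp)
        id_sched = design.make_identification_schedule(
            cont, reps=config.reps_id, seed=config.seed
        )
        disc_sched = design.make_discrimination_schedule(
            cont, step=config.step, reps=config.reps_disc, seed=config.seed + 1
        )

        if config.response_files and exp in config.response_files:
            responses = pd.read_csv(config.response_files[exp])
            responses = responses[responses["experiment"] == exp]
            if config.metadata_file:
                meta = pd.read_csv(config.metadata_file)
            else:
                meta = pd.DataFrame(
                    {
                        "listener_id": responses["listener_id"].unique(),
                        "group": [
                            responses.loc[responses["listener_id"] == l, "group"].iat[0]
                            for l in responses["listener_id"].unique()
                        ],
                        "age_years": np.nan,
                    }
                )
            source = str(config.response_files[exp])
        else:
            profiles = simulate.make_cohort(config.group_specs(exp), seed=config.seed)
            responses = simulate.simulate_cohort_responses(
                profiles, id_sched, disc_sched, step=config.step
            )
            meta = simulate.cohort_metadata(profiles)
            source = "simulated"
            responses.to_csv(out / f"responses_{exp}.csv", index=False)
            meta.to_csv(out / f"metadata_{exp}.csv", index=False)

        log.info("experiment %s: %d response rows (%s)", exp, len(responses), source)
        fits = identification.fit_cohort(
            responses, slope_cap=config.slope_cap, n_steps=cont.n_steps
        )
        units, summary = discrimination.cp_profile_cohort(
            responses, fits, cont, step=config.step
        )
        if config.group_curve_method == "pooled":
            curve = discrimination.pooled_group_curve(responses, cont, step=config.step)
        else:
            curve = discrimination.group_discrimination_curve(units)

        anova_df, tukey_df, reg_df, info = _group_statistics(fits, summary, meta)

        tables = {
            f"fits_{exp}.csv": fits,
            f"cp_units_{exp}.csv": units,
            f"cp_summary_{exp}.csv": summary,
            f"anova_{exp}.csv": anova_df,
            f"tukey_{exp}.csv": tukey_df,
            f"regressions_{exp}.csv": reg_df,
            f"group_curve_{exp}.csv": curve,
        }
        for name, table in tables.items():
            table.to_csv(out / name, index=False)
        manifest["experiments"][exp] = {
            "source": source,
            "n_response_rows": int(len(responses)),
            "n_identification_trials": len(id_sched),
            "n_discrimination_trials": len(disc_sched),
            **info,
        }
        for name in tables:
            manifest["checksums"][name] = _sha256(out / name)
        if source == "simulated":
            manifest["checksums"][f"responses_{exp}.csv"] = _sha256(
                out / f"responses_{exp}.csv"
            )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
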