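"""Comparison units, discrimination scores and CP profiles."""

import numpy as np
import pandas as pd
import pytest

from catperc.design import (
    ContinuumSpec,
    StimulusSpec,
    make_discrimination_schedule,
)
from catperc.discrimination import (
    build_comparison_units,
    classify_units,
    cp_profile,
    unit_score,
    unit_trials,
)
from catperc.identification import IdentificationFit
from catperc.simulate import ListenerProfile, simulate_discrimination

from conftest import discrimination_frame


def make_fit(boundary, degenerate=False, n_steps=7):
    width = 1.0 if not degenerate else float("nan")
    b = 1.349 if not degenerate else float("nan")
    return IdentificationFit(
        a=-(b * boundary) if not degenerate else float("nan"),
        b=b,
        boundary_position=boundary,
        boundary_width=width,
        converged=True,
        degenerate=degenerate,
        n_levels=n_steps,
        n_steps=n_steps,
    )


class TestUnits:
    @pytest.mark.parametrize(
        "fixture, step, expected", [("tone", 2, 5), ("vot", 2, 8)]
    )
    def test_unit_counts(self, fixture, step, expected, request):
        cont = request.getfixturevalue(fixture)
        units = build_comparison_units(cont, step)
        assert len(units) == expected
        assert units[0].lower == 1 and units[-1].upper == cont.n_steps

    def test_minimal_continuum_single_unit(self):
        cont = ContinuumSpec("tone", tuple(StimulusSpec(index=i) for i in (1, 2, 3)))
        units = build_comparison_units(cont, 2)
        assert [(u.lower, u.upper) for u in units] == [(1, 3)]

    def test_step_out_of_range(self, tone):
        with pytest.raises(ValueError):
            build_comparison_units(tone, 7)

    def test_adjacent_units_share_identical_pair_trials(self, tone, tone_disc_schedule):
        """Unit (1,3)'s BB trials are unit (3,5)'s AA trials."""
        p = ListenerProfile("s", "g", mu=4.0, width=1.0, seed=3)
        resp = simulate_discrimination(p, tone_disc_schedule, step=2)
        units = build_comparison_units(tone, 2)
        t13 = unit_trials(resp, units[0])
        t35 = unit_trials(resp, units[2])
        bb13 = t13[(t13["stimulus_a"] == 3) & (t13["stimulus_b"] == 3)]
        aa35 = t35[(t35["stimulus_a"] == 3) & (t35["stimulus_b"] == 3)]
        pd.testing.assert_frame_equal(bb13, aa35)


class TestUnitScore:
    def test_all_correct_scores_one(self):
        trials = [(1, 3, "different"), (3, 1, "different"), (1, 1, "same"), (3, 3, "same")]
        assert unit_score(discrimination_frame(trials)) == 1.0

    def test_printed_equation_arithmetic(self):
        # P("S"|S)=0.8, P("D"|D)=0.6, equal shares → P = 0.7
        same = [(1, 1, "same")] * 8 + [(1, 1, "different")] * 2
        diff = [(1, 3, "different")] * 6 + [(1, 3, "same")] * 4
        assert unit_score(discrimination_frame(same + diff)) == pytest.approx(0.7)

    def test_unbalanced_shares_are_empirical(self):
        # 3 same (all correct), 1 different (wrong): P = 1·(3/4) + 0·(1/4)
        trials = [(1, 1, "same")] * 3 + [(1, 3, "same")]
        assert unit_score(discrimination_frame(trials)) == pytest.approx(0.75)

    def test_missing_trial_kind_rejected(self):
        with pytest.raises(ValueError):
            unit_score(discrimination_frame([(1, 1, "same")]))

    def test_matches_brute_force_oracle_on_random_tables(self):
        """Independent oracle: explicit counting of correct responses per
        kind, weighted by the kind's trial share."""
        rng = np.random.default_rng(77)
        for _ in range(30):
            n_same = rng.integers(1, 20)
            n_diff = rng.integers(1, 20)
            trials = []
            for _ in range(n_same):
                trials.append((2, 2, rng.choice(["same", "different"])))
            for _ in range(n_diff):
                trials.append((2, 4, rng.choice(["same", "different"])))
            df = discrimination_frame(trials)

            correct_same = sum(1 for a, b, r in trials if a == b and r == "same")
            correct_diff = sum(1 for a, b, r in trials if a != b and r == "different")
            n = len(trials)
            oracle = (correct_same / n_same) * (n_same / n) + (
                correct_diff / n_diff
            ) * (n_diff / n)
            assert unit_score(df) == pytest.approx(oracle, abs=1e-12)

    def test_random_responding_scores_at_chance(self):
        """E[P] = 0.5 under uniform guessing (Monte-Carlo oracle)."""
        rng = np.random.default_rng(99)
        n = 100_000
        responses = rng.choice(["same", "different"], size=n)
        trials = [
            (2, 2 if i < n // 2 else 4, responses[i]) for i in range(n)
        ]
        assert unit_score(discrimination_frame(trials)) == pytest.approx(0.5, abs=0.01)


class TestClassifyUnits:
    def test_boundary_371_splits_tone_units(self, tone):
        units = build_comparison_units(tone, 2)
        labels = classify_units(units, 3.71)
        assert dict(zip([u.label for u in units], labels)) == {
            "1-3": "within",
            "2-4": "between",
            "3-5": "between",
            "4-6": "within",
            "5-7": "within",
        }

    def test_boundary_outside_continuum_gives_no_between_units(self, tone):
        labels = classify_units(build_comparison_units(tone, 2), 0.5)
        assert set(labels) == {"within"}

    def test_boundary_on_stimulus_uses_strict_interior(self, tone):
        labels = classify_units(build_comparison_units(tone, 2), 3.0)
        assert labels == ["within", "between", "within", "within", "within"]


class TestCPProfile:
    def test_perfect_categorical_listener(self, tone, tone_disc_schedule):
        """Step identification at mu=4 with no auditory residual: units
        straddling 4 score 1, distant units 0.5 (all answered "same")."""
        p = ListenerProfile("perf", "g", mu=3.9, width=1e-9, seed=5)
        resp = simulate_discrimination(p, tone_disc_schedule, step=2)
        prof = cp_profile(resp, make_fit(3.9), tone, 2)
        scores = dict(zip(prof.unit_labels, prof.unit_scores))
        assert scores["2-4"] == 1.0 and scores["3-5"] == 1.0
        assert scores["1-3"] == 0.5 and scores["5-7"] == 0.5
        assert prof.p_bc == 1.0
        assert prof.p_wc == pytest.approx(0.5)
        assert prof.peak_unit in {"2-4", "3-5"}

    def test_partition_covers_all_units(self, tone, tone_disc_schedule):
        p = ListenerProfile("q", "g", mu=4.0, width=1.5, seed=6)
        resp = simulate_discrimination(p, tone_disc_schedule, step=2)
        prof = cp_profile(resp, make_fit(3.8), tone, 2)
        n_b = sum(c == "between" for c in prof.unit_classes)
        n_w = sum(c == "within" for c in prof.unit_classes)
        assert n_b + n_w == tone.n_steps - 2

    def test_order_invariance(self, tone, tone_disc_schedule):
        p = ListenerProfile("r", "g", mu=4.0, width=1.5, seed=8)
        resp = simulate_discrimination(p, tone_disc_schedule, step=2)
        shuffled = resp.sample(frac=1.0, random_state=2)
        assert cp_profile(resp, make_fit(3.8), tone, 2) == cp_profile(
            shuffled, make_fit(3.8), tone, 2
        )

    def test_degenerate_boundary_marks_all_units_within(self, tone, tone_disc_schedule):
        p = ListenerProfile("d", "g", mu=4.0, width=1.5, seed=9)
        resp = simulate_discrimination(p, tone_disc_schedule, step=2)
        prof = cp_profile(resp, make_fit(float("nan"), degenerate=True), tone, 2)
        assert prof.degenerate
        assert set(prof.unit_classes) == {"within"}
        assert np.isnan(prof.p_bc)

    def test_peak_tie_broken_toward_boundary(self, tone):
        # All-correct trials in units 1-3 and 3-5 tie at P=1; boundary 3.9
        trials = (
            [(1, 3, "different"), (3, 1, "different"), (1, 1, "same"), (3, 3, "same")]
            + [(3, 5, "different"), (5, 3, "different"), (5, 5, "same")]
            + [(2, 4, "same"), (4, 2, "same"), (2, 2, "same"), (4, 4, "same")]
            + [(4, 6, "same"), (6, 4, "same"), (6, 6, "same")]
            + [(5, 7, "same"), (7, 5, "same"), (7, 7, "same")]
        )
        resp = discrimination_frame(trials)
        prof = cp_profile(resp, make_fit(3.9), tone, 2)
        assert prof.peak_score == 1.0
        assert prof.peak_unit == "3-5"

    def test_between_category_advantage_in_adult_cohort(self, tone, tone_disc_schedule):
        """Sign test over simulated adult-like listeners: P_bc > P_wc."""
        from scipy.stats import binomtest

        wins = total = 0
        for i in range(200):
            p = ListenerProfile(
                f"a{i}", "adult", mu=3.8, width=0.9, aud_resid=0.2,
                false_alarm=0.05, seed=60,
            )
            resp = simulate_discrimination(p, tone_disc_schedule, step=2)
            prof = cp_profile(resp, make_fit(3.8), tone, 2)
            if prof.p_bc != prof.p_wc:
                wins += prof.p_bc > prof.p_wc
                total += 1
        assert binomtest(wins, total, 0.5, alternative="greater").pvalue < 0.01
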