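"""Synthetic-listener generative model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from catperc.design import make_discrimination_schedule, make_identification_schedule
from catperc.simulate import (
    GroupSpec,
    ListenerProfile,
    Z75,
    haskins_different_prob,
    ident_prob,
    make_cohort,
    simulate_discrimination,
    simulate_identification,
)


def profile(**kw):
    base = dict(listener_id="x", group="g", mu=4.0, width=1.0, seed=0)
    base.update(kw)
    return ListenerProfile(**base)


class TestIdentProb:
    def test_midpoint_is_half(self):
        assert ident_prob(profile(), 4.0) == pytest.approx(0.5)

    def test_width_is_quartile_distance(self):
        p = profile(width=1.7)
        assert ident_prob(p, p.mu + p.width / 2) == pytest.approx(0.75, abs=1e-9)
        assert ident_prob(p, p.mu - p.width / 2) == pytest.approx(0.25, abs=1e-9)

    def test_unit_sigma_case_matches_normal_table(self):
        # width 2·z_{0.75} gives sigma 1, so one step above mu is Φ(1)
        p = profile(width=2 * Z75)
        assert ident_prob(p, 5.0) == pytest.approx(norm.cdf(1.0), abs=1e-9)

    def test_lapse_compresses_range(self):
        p = profile(lapse=0.2)
        assert ident_prob(p, -50) == pytest.approx(0.1, abs=1e-6)
        assert ident_prob(p, 50) == pytest.approx(0.9, abs=1e-6)

    @given(
        mu=st.floats(1.0, 7.0),
        width=st.floats(0.05, 5.0),
        lapse=st.floats(0.0, 0.2),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_stimulus_index(self, mu, width, lapse):
        p = profile(mu=mu, width=width, lapse=lapse)
        probs = np.asarray(ident_prob(p, np.linspace(0, 11, 45)))
        assert np.all(np.diff(probs) >= -1e-12)

    @pytest.mark.parametrize(
        "kw",
        [dict(width=0.0), dict(lapse=0.3), dict(aud_resid=1.5), dict(false_alarm=0.6)],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            profile(**kw)


class TestSimulateIdentification:
    def test_step_limit_listener_partitions_continuum(self, tone, tone_id_schedule):
        p = profile(width=1e-6)
        resp = simulate_identification(p, tone_id_schedule)
        below = resp[resp["stimulus_a"] < 4]
        above = resp[resp["stimulus_a"] > 4]
        assert (below["response"] == "cat1").all()
        assert (above["response"] == "cat2").all()

    def test_determinism_same_profile_same_table(self, tone_id_schedule):
        p = profile(width=1.3, seed=11)
        r1 = simulate_identification(p, tone_id_schedule)
        r2 = simulate_identification(p, tone_id_schedule)
        pd.testing.assert_frame_equal(r1, r2)

    def test_task_mismatch_rejected(self, tone, tone_disc_schedule):
        with pytest.raises(ValueError):
            simulate_identification(profile(), tone_disc_schedule)

    def test_pooled_proportion_at_boundary_is_half(self, tone, tone_id_schedule):
        # 200 listeners × 8 presentations of stimulus 4 → 1600 Bernoulli(0.5)
        hits = total = 0
        for i in range(200):
            p = profile(listener_id=f"l{i}", width=1.5, seed=31)
            resp = simulate_identification(p, tone_id_schedule)
            at4 = resp[resp["stimulus_a"] == 4]
            hits += int((at4["response"] == "cat2").sum())
            total += len(at4)
        assert total == 1600
        assert hits / total == pytest.approx(0.5, abs=0.03)


class TestSimulateDiscrimination:
    def test_identical_pairs_always_same_without_false_alarms(self, tone):
        sched = make_discrimination_schedule(tone, step=2, reps=20, seed=1)
        # mu off the stimulus grid: every identical pair gets equal labels
        p = profile(mu=3.6, width=1e-6, aud_resid=0.8)
        resp = simulate_discrimination(p, sched, step=2)
        same = resp[resp["stimulus_a"] == resp["stimulus_b"]]
        assert (same["response"] == "same").all()

    def test_cross_boundary_endpoints_always_different(self, tone):
        sched = make_discrimination_schedule(tone, step=6, reps=20, seed=2)
        p = profile(width=1e-6)
        resp = simulate_discrimination(p, sched, step=6)
        pair17 = resp[resp["stimulus_a"] != resp["stimulus_b"]]
        assert (pair17["response"] == "different").all()

    def test_task_mismatch_rejected(self, tone_id_schedule):
        with pytest.raises(ValueError):
            simulate_discrimination(profile(), tone_id_schedule)

    def test_haskins_limit_matches_label_enumeration(self, tone):
        """With no auditory trace, guessing or lapse, the "different" rate
        for pair (i, j) equals p_i(1−p_j) + p_j(1−p_i) — the covert-label
        prediction enumerated over the four label outcomes."""
        p = profile(mu=3.8, width=1.5, seed=13)
        sched = make_discrimination_schedule(tone, step=2, reps=2000, seed=3)
        resp = simulate_discrimination(p, sched, step=2)
        diff = resp[resp["stimulus_a"] != resp["stimulus_b"]]
        for (a, b), sub in diff.groupby(["stimulus_a", "stimulus_b"]):
            p_i = float(ident_prob(p, a))
            p_j = float(ident_prob(p, b))
            # enumeration of (L_i, L_j) ∈ {1,2}²: labels differ in two cells
            expected = (
                p_i * (1 - p_j) + (1 - p_i) * p_j
            )
            assert expected == pytest.approx(haskins_different_prob(p_i, p_j), abs=1e-15)
            assert (sub["response"] == "different").mean() == pytest.approx(
                expected, abs=0.035
            )

    def test_dual_process_closed_form_matches_simulation(self, tone):
        """Within-category pair far from mu: P("different") =
        1 − (1 − p_hask)(1 − aud)(1 − fa), checked against a large draw."""
        p = profile(mu=6.5, width=0.8, aud_resid=0.2, false_alarm=0.1, seed=17)
        sched = make_discrimination_schedule(tone, step=2, reps=4000, seed=4)
        resp = simulate_discrimination(p, sched, step=2)
        sub = resp[(resp["stimulus_a"] == 1) & (resp["stimulus_b"] == 3)]
        p_hask = haskins_different_prob(float(ident_prob(p, 1)), float(ident_prob(p, 3)))
        expected = 1 - (1 - p_hask) * (1 - 0.2) * (1 - 0.1)
        assert (sub["response"] == "different").mean() == pytest.approx(expected, abs=0.02)


class TestCohort:
    def test_group_sizes_respected(self):
        specs = {"adult": GroupSpec(n=14, mu=(3.5, 4.2), width=(0.7, 1.1))}
        cohort = make_cohort(specs, seed=0)
        assert len(cohort) == 14
        assert all(p.group == "adult" for p in cohort)

    def test_point_ranges_give_identical_listeners(self):
        specs = {"g": GroupSpec(n=5, mu=(4.0, 4.0), width=(1.2, 1.2))}
        cohort = make_cohort(specs, seed=3)
        assert {(p.mu, p.width) for p in cohort} == {(4.0, 1.2)}

    def test_same_seed_same_cohort(self):
        specs = {
            "a": GroupSpec(n=4, mu=(3.0, 5.0), width=(0.5, 2.0)),
            "b": GroupSpec(n=4, mu=(3.0, 5.0), width=(0.5, 2.0)),
        }
        c1 = make_cohort(specs, seed=9)
        c2 = make_cohort(specs, seed=9)
        assert c1 == c2

    def test_cohort_stable_under_group_reordering(self):
        sa = GroupSpec(n=3, mu=(3.0, 5.0), width=(0.5, 2.0))
        c1 = make_cohort({"a": sa, "b": sa}, seed=1)
        c2 = make_cohort({"b": sa, "a": sa}, seed=1)
        assert c1 == c2

    def test_empty_range_rejected(self):
        specs = {"g": GroupSpec(n=2, mu=(5.0, 3.0), width=(1.0, 1.0))}
        with pytest.raises(ValueError):
            make_cohort(specs, seed=0)
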