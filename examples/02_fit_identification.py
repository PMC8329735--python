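"""Simulate one listener's identification block and fit the probit.

The listener's true boundary sits at stimulus 3.8 with a 25th–75th
percentile width of 1.2 stimulus steps.  The fit recovers both from 56
trials; the printed error shows the sampling noise at 8 repetitions
per stimulus.
"""

from catperc import (
    ListenerProfile,
    fit_probit,
    make_identification_schedule,
    make_tone_continuum,
    simulate_identification,
    tabulate_identification,
)

tone = make_tone_continuum()
schedule = make_identification_schedule(tone, reps=8, seed=10)
listener = ListenerProfile("demo", "adult", mu=3.8, width=1.2, seed=42)

responses = simulate_identification(listener, schedule)
curve = tabulate_identification(responses)
print("per-stimulus P(category 2):")
for stim, row in curve.iterrows():
    print(f"  stimulus {stim}: {row.prop_cat2:.3f}  ({int(row.n_cat2)}/{int(row.n_trials)})")

fit = fit_probit(responses, n_steps=tone.n_steps)
print(f"\nprobit fit: P(cat2|x) = Phi({fit.a:+.3f} {fit.b:+.3f}*x)")
print(f"boundary position {fit.boundary_position:.3f} (true {listener.mu})")
print(f"boundary width    {fit.boundary_width:.3f} (true {listener.width})")
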