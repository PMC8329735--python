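"""Score a listener's AX discrimination block by comparison unit.

The tone continuum yields five two-step units (1-3 .. 5-7).  Units
whose span contains the listener's fitted boundary are between-category;
the between-category mean P_bc should exceed the within-category mean
P_wc for a categorical listener, and the peak unit should straddle the
boundary.
"""

from catperc import (
    ListenerProfile,
    cp_profile,
    fit_probit,
    make_discrimination_schedule,
    make_identification_schedule,
    make_tone_continuum,
    simulate_discrimination,
    simulate_identification,
)

tone = make_tone_continuum()
listener = ListenerProfile(
    "demo", "adult", mu=3.8, width=1.0, aud_resid=0.2, false_alarm=0.05, seed=42
)

fit = fit_probit(
    simulate_identification(listener, make_identification_schedule(tone, 8, seed=10)),
    n_steps=tone.n_steps,
)
responses = simulate_discrimination(
    listener, make_discrimination_schedule(tone, step=2, reps=5, seed=11), step=2
)
profile = cp_profile(responses, fit, tone, step=2)

print(f"boundary used: {profile.boundary_used:.3f}")
for unit, score, cls in zip(profile.unit_labels, profile.unit_scores, profile.unit_classes):
    print(f"  unit {unit}: P = {score:.3f}  [{cls}]")
print(f"peak: unit {profile.peak_unit} (P = {profile.peak_score:.3f})")
print(f"P_bc = {profile.p_bc:.3f}, P_wc = {profile.p_wc:.3f}")
print("between-category advantage:", f"{profile.p_bc - profile.p_wc:+.3f}")
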