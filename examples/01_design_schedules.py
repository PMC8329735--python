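"""Build the two stimulus continua and their trial schedules.

The tone continuum varies onset F0 from 140 Hz (level tone) down to
80 Hz (rising tone) in 10-Hz steps; the VOT continuum varies voice
onset time from 0 to 90 ms in 10-ms steps.  The printed counts are the
experiment's design constants: 56/80 identification trials, 85/130
discrimination trials, and 12/15 discrimination practice pairs.
"""

from catperc import (
    make_discrimination_schedule,
    make_identification_schedule,
    make_practice_blocks,
    make_tone_continuum,
    make_vot_continuum,
)

for cont in (make_tone_continuum(), make_vot_continuum()):
    name = cont.continuum_id
    if name == "tone":
        params = [f"{s.onset_f0:.0f}Hz" for s in cont.stimuli]
    else:
        params = [f"{s.vot_ms:.0f}ms" for s in cont.stimuli]
    print(f"{name}: {cont.n_steps} stimuli -> {' '.join(params)}")

    ident = make_identification_schedule(cont, reps=8, seed=1)
    disc = make_discrimination_schedule(cont, step=2, reps=5, seed=2)
    prac_id, prac_disc = make_practice_blocks(name, seed=3)
    print(
        f"  identification: {len(ident)} trials | discrimination: {len(disc)} trials"
        f" | practice: {len(prac_id)} id + {len(prac_disc)} disc"
    )
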