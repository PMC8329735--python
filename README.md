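# catperc

Categorical-perception (CP) analysis for speech continua: experiment
design, synthetic listeners, per-participant psychometric fitting,
AX-discrimination scoring, and group-level statistics.

## The problem

When listeners hear stimuli drawn from a continuous acoustic continuum —
a Mandarin Tone 1→2 pitch continuum, or a /pa/→/pʰa/ voice-onset-time
(VOT) continuum — they typically perceive discrete categories: a
two-alternative identification task produces a sharp sigmoid, and an AX
("same or different?") discrimination task shows a peak for pairs that
straddle the category boundary. Developmental work asks how the
sharpness of this mapping matures, comparing children's boundary
positions, boundary widths and between/within-category discrimination
scores with adults'.

`catperc` implements the complete analysis pipeline for this paradigm,
plus a parametric listener simulator so every stage can be verified by
parameter recovery without access to raw participant data.

## The model

**Identification.** Each participant's responses are fitted with a
two-parameter probit (binomial maximum likelihood on trial-level data):

    P(category 2 | x) = Φ(a + b·x)

The **boundary position** is the 50% crossover, `−a/b`; the **boundary
width** is the 25th–75th percentile distance, `2·z₀.₇₅/b` (z₀.₇₅ ≈
0.6745). Perfect separation is handled by a slope cap plus a
`degenerate` flag; degenerate fits are excluded from group statistics
and logged.

**Discrimination.** Two-step AX trials are grouped into comparison
units (i, i+2), each owning AB, BA, AA and BB trials (identical-pair
trials are shared between adjacent units). The unit score is

    P = P("S"|S)·P(S) + P("D"|D)·P(D)

with hit rates for same and different pairs weighted by the empirical
trial shares (0.5 each in this design; chance = 0.5). Units whose span
strictly contains the participant's own fitted boundary are
between-category; `P_bc` and `P_wc` are the unweighted unit-score means
of the two classes.

**Group statistics.** One-way ANOVA with η² = SS_between/SS_total,
Tukey HSD (Tukey–Kramer for unbalanced groups) pairwise comparisons,
and simple linear regressions of each CP metric on chronological age.

**Synthetic listeners.** A dual-process generative model: covert
category labels drawn from the listener's own identification function
(the Haskins prediction) OR-combined with a residual auditory-trace
signal and a false-alarm floor. With the auditory and guessing
parameters at zero it reduces exactly to the Haskins covert-label
model, giving closed-form oracles for testing.

## Worked example

`examples/04_full_pipeline.py` simulates the study-sized cohort — 14
four-year-olds, 16 five-year-olds, 17 six-year-olds and 14 adults, with
generative boundary widths wide for ages 4–5 and adult-like by age 6 —
and runs the full pipeline on the tone continuum:

```text
participants: 61 (excluded degenerate: 0)

one-way ANOVAs (group effect):
  boundary_position  F(3,57) =   1.07, p = 0.3695, eta2 = 0.053
  boundary_width     F(3,57) =  17.86, p = 0.0000, eta2 = 0.485
  p_bc               F(3,57) =   8.41, p = 0.0001, eta2 = 0.307
  p_wc               F(3,57) =   0.87, p = 0.4624, eta2 = 0.044

age regressions (children only):
  boundary_position  beta1 = +0.089, r2 = 0.032, p = 0.2278
  boundary_width     beta1 = -0.609, r2 = 0.303, p = 0.0001
  p_bc               beta1 = +0.045, r2 = 0.142, p = 0.0089
  p_wc               beta1 = -0.007, r2 = 0.009, p = 0.5358
```

Reading the table: boundary *position* shows no group effect (all ages
place the category boundary in the same place), boundary *width* shows
a strong one (younger children have shallower identification slopes),
the between-category score `p_bc` improves with age while the
within-category score `p_wc` does not, and width narrows significantly
with age in the regression — the qualitative developmental signature
the pipeline is designed to detect.

The other examples cover schedule design (`01`), single-listener probit
fitting (`02`), comparison-unit scoring (`03`) and parameter recovery
(`05`). A thin CLI wraps the same functions:

```bash
catperc design --experiment tone --seed 1 --out schedule.csv
catperc run --seed 7 --out run_dir      # full pipeline, synthetic cohort
catperc validate run_dir/responses_tone.csv --reps-id 8 --reps-disc 5
```

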