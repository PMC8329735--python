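# Methods

This note records the models, conventions and numerical choices behind
`catperc`, and what the synthetic-listener tests do and do not show
about real data.

## Experimental design objects

The two continua are represented purely by their acoustic design
parameters; no audio is synthesised or consumed, because the analysis
operates on stimulus indices only.

* **Tone continuum** — 7 stimuli; onset F0 of stimulus *k* is
  140 − 10·(k − 1) Hz with the offset fixed at 140 Hz, 500 ms duration,
  70 dB. Stimulus 1 is a level tone, stimulus 7 a rising tone.
* **VOT continuum** — 10 stimuli; VOT of stimulus *k* is 10·(k − 1) ms
  (0–90 ms), vowel duration 300 ms.

Schedules are trial multisets in a seeded Fisher–Yates order: the
multiset is a function of the design only, the order of the seed only.
The formal identification block presents every stimulus 8 times (56 and
80 trials); the formal AX block presents every comparison 5 times,
where the comparison list contains all forward and reverse two-step
pairs plus every identical pair (17 comparisons / 85 trials for tone,
26 / 130 for VOT). Practice blocks use fixed stimulus lists
(identification: tone 1, 2, 4, 6, 7 and VOT 1, 2, 5, 6, 9, 10, twice
each; discrimination: tone 1-1, 2-4, 3-5, 1-7 and VOT 1-1, 5-7, 6-8,
10-10, 1-10, three times each). The ≥90% endpoint-identification rule
is implemented as an offline screening operation
(`screen_practice`, inclusive bound) over the near-endpoint stimuli
(tone 1, 2, 6, 7; VOT 1, 2, 9, 10) rather than an interactive gate,
since the artifact is an offline analysis tool.

## Identification analysis

The psychometric model is a two-parameter probit
P(cat2 | x) = Φ(a + b·x), fitted by maximizing the binomial likelihood
of the per-level counts (equivalent to trial-level ML). Derived
quantities: boundary position −a/b, boundary width 2·z₀.₇₅/b. z₀.₇₅ is
always computed from the normal quantile function, never hard-coded, so
the generator's width→sigma mapping (σ = width/(2·z₀.₇₅)) and the
analysis agree to machine precision.

No lapse parameter is fitted: the two-parameter model is the classic
probit analysis, while the generator *can* lapse — a deliberate
model-mismatch stress test. Recovery results below include that
mismatch.

Numerical choices:

* Optimisation by L-BFGS-B from Finney-style working-probit start
  values, with the slope bounded to ±`slope_cap` (default 20 per
  stimulus unit) and the intercept bounded accordingly.
* **Complete separation** (every level all-cat1 or all-cat2, split by a
  threshold) is detected from the counts before optimisation. The slope
  is set to the cap and the crossover is profiled on a grid; because the
  likelihood is flat across the whole separation gap, the midpoint of
  the argmin set is taken, so a symmetric step curve yields the
  gap-midpoint boundary. Such fits are flagged `degenerate`.
* A fit is degenerate when the slope is capped or non-positive, or the
  boundary falls outside [1, n_steps]. Degenerate participants are
  excluded listwise from group statistics and recorded in the run
  manifest.

The suite cross-checks the fit against a statsmodels binomial GLM with
probit link (IRLS) on non-separated data, and the closed-form width
against numerical inversion of the fitted curve's 25%/75% crossings.

## Discrimination analysis

Comparison units (i, i+step) for i = 1..n−step, step 2 by default.
Identical-pair trials are counted in every unit containing that
stimulus, so adjacent units share AA/BB trials and unit scores are not
statistically independent — a property of the design, preserved here.

The unit score is P = P("S"|S)·P(S) + P("D"|D)·P(D) with empirical
trial shares, so unbalanced ingested data remain valid; the shares are
exactly 0.5 in the built-in design.

Classification conventions (the design was genuinely open here):

* A unit (i, j) is between-category iff the participant's own fitted
  boundary lies **strictly** inside (i, j). A boundary exactly on a
  stimulus index means that stimulus is at 50%, so a pair having it as
  an endpoint does not cross categories and counts as within.
* Classification always uses the participant's own boundary, not a
  group boundary.
* The peak is the maximum unit score, ties broken toward the unit whose
  midpoint is nearest the boundary.
* Group discrimination curves average individual unit scores; pooled
  scoring over a group's raw trials is exposed as an alternative
  (`pooled_group_curve`, or `group_curve_method: pooled` in the run
  config) and differs only for unbalanced contributions.
* P_bc / P_wc are unweighted means over their unit classes; with a
  degenerate boundary all units are within-category and P_bc is NaN.

## Group statistics

One-way fixed-effects ANOVA via the classical SS decomposition with
η² = SS_between/SS_total; Tukey HSD adjusted p-values from the
studentized-range distribution (scipy), using the Tukey–Kramer standard
error for unbalanced groups; simple regressions by closed-form least
squares with the model F = (r²/(1−r²))·(n−2). Age enters as decimal
years and regressions use the child groups only (adults are controls).
No correction is applied across the family of ANOVAs, and this is noted
in the outputs rather than silently changed.

## Synthetic listeners

The generator exists to make every analysis stage verifiable by
parameter recovery. Identification responses are Bernoulli draws from
lapse/2 + (1 − lapse)·Φ((x − μ)/σ). Discrimination uses a dual-process
construction motivated by the two-store (auditory trace + phonetic
code) account of AX performance:

1. covert labels for the two stimuli, drawn independently from the
   listener's identification function — labels disagreeing is the
   *categorical* "different" signal;
2. an *auditory* signal firing with probability
   `aud_resid · min(1, |i−j|/step)` (never for identical pairs);
3. the listener answers "different" if either signal fires, else with
   probability `false_alarm`.

The either-signal-fires disjunction was chosen because with
`aud_resid = false_alarm = lapse = 0` it collapses exactly to the
Haskins covert-label prediction p_i(1−p_j) + p_j(1−p_i), which is
enumerable and serves as the closed-form oracle. Each listener owns a
private random stream keyed by (seed, listener id, task), so cohorts
are reproducible under reordering.

### Default cohort (the study conditions)

Group sizes mirror the study population: 14 four-year-olds, 16
five-year-olds, 17 six-year-olds, 14 adults (61 participants). The
generative parameter ranges are calibration choices — the source data
give no quantitative listener model — fixed once from the qualitative
group differences and not revisited:

| group | tone width | VOT width | μ (both) | lapse | aud_resid | false_alarm |
|-------|-----------|-----------|----------|-------|-----------|-------------|
| age-4 | 1.6–2.4 | 2.0–2.8 | 3.5–4.2 (tone), 3.3–4.0 (VOT) | 0–0.04 | 0.15–0.3 | 0.02–0.1 |
| age-5 | 1.6–2.4 | 1.9–2.7 | 〃 | 〃 | 〃 | 〃 |
| age-6 | 0.8–1.2 | 1.8–2.6 | 〃 | 〃 | 〃 | 〃 |
| adult | 0.7–1.1 | 1.0–1.4 | 〃 | 〃 | 〃 | 〃 |

Widths encode the developmental ordering (tone: age-4 ≈ age-5 > age-6 ≈
adult; VOT: all child groups > adult); boundary positions sit
mid-continuum for every group, matching the observation that position
does not depend on age. Ages are drawn uniformly per group (4.4–5.0,
4.9–6.1, 6.0–7.1, 18–30 years).

### What the simulations do and do not show

Passing recovery tests shows the pipeline is internally consistent:
what the generator puts in, the analysis gets back at the study's trial
numbers. The generator does **not** model reaction times, fatigue or
attention drift, training dynamics, serial dependence between trials,
or acoustic-level variability, so the tests say nothing about
robustness to those features of real data. Ingested real response
files take the same path as simulated ones (`validate_responses`,
then the identical analysis stages).

## Verification experiments and problem sizes

The built-in studies (`catperc.recovery`) use sizes chosen to make the
stochastic checks stable while keeping a full verification run around a
minute on one CPU:

* **Recovery study** — 200 listeners per group (800 total), tone
  continuum, 8/5 repetitions. Typical results: median absolute boundary
  error ≈ 0.19–0.21 stimulus units, median relative width error ≈ 21–22%,
  strongly positive P_bc − P_wc (one-sided sign test p ≪ 0.01).
* **Peak–boundary alignment** — 400 covert-label (Haskins) listeners
  with adult-like widths (0.7–1.1): the peak unit straddles the
  generative boundary for ≈ 98–99% of non-degenerate listeners. The
  rate is width-limited: it stays above 90% up to widths ≈ 1.5 and
  falls to ≈ 77% under the full dual-process cohort, whose deliberately
  wide child boundaries flatten the discrimination curve — a property
  of the listeners, not of the scoring.
* **Pattern recovery** — 50 replicate study-sized cohorts; the
  boundary-width ANOVA + Tukey stage reproduces exactly the generative
  significance pattern (wide pair vs narrow pair significant at
  α = 0.05, within-pair contrasts not) in ≈ 94–98% of runs.

## Known limitations

* The probit fit is per-participant ML; no shrinkage or hierarchical
  pooling, so very flat listeners at 8 repetitions can produce
  degenerate fits which are excluded rather than stabilised.
* Whether the original probit analyses used trial-level ML or weighted
  least squares on proportions is unknown; at 8 repetitions per level
  the difference is negligible, but it is untested against other
  software.
* The AX model ignores order effects (AB vs BA asymmetries) and
  interstimulus-interval dependence of the auditory trace.
* Tukey HSD p-values assume normal within-group errors; unit scores are
  bounded in [0, 1] and mildly discrete at 5 repetitions.
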