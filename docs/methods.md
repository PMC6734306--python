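# Methods

## The attack model

Migraine progression is modelled per subject as a two-state Markov chain
with daily time steps.  From the susceptible state an attack starts with
per-day probability μ; during an attack, each further day continues the
attack with probability δ, so attack durations are geometric with mean
1/(1−δ).  Menstrual modulation enters only through the onset probability:
μ = μ^M on days of the 5-day menstrual window (bleeding onset ± 2 days)
and μ = μ^NM elsewhere.  The continuation probability δ is deliberately
unmodulated.  Menstrually related migraine corresponds to
Δμ = μ^M − μ^NM > 0.

Assumptions worth stating explicitly:

* daily resolution — sub-day timing is ignored;
* a single δ per subject — no severity or duration modulation;
* window membership is deterministic given the bleeding record;
* parameters are constant over the observation period.

## Trimming and the exact test

Day counts are not exchangeable when attacks span several days, so the
test operates on *attack onsets*.  Day roles are assigned as follows:

* the first day of a migraine run whose preceding day is an observed
  non-migraine day is an **attack start**;
* later days of a run are **ongoing**;
* the two days after a run's end are **refractory**: by the relapse
  convention in trial guidelines, head pain recurring 2–48 h after pain
  freedom belongs to the same attack, so these days cannot carry an
  independent onset.  For the same reason a non-migraine day flanked by
  migraine days on both sides ("migraine-locked") is imputed as migraine
  before classification, iterated to a fixed point;
* runs starting on the first retained day have no observable onset and are
  **excluded** (they still generate trailing refractory days);
* everything else is **susceptible**.

If a migraine day were to fall on a refractory day (possible only on
non-imputed input), it is merged into the preceding attack and the
refractory period restarts after the merged run.

The susceptible plus attack-start days are the N classifiable days; K of
them lie in windows; they carry n onsets, k inside windows.  Conditioned
on the margins, k is Hypergeometric(N, K, n) under Δμ = 0, and the
criterion uses the one-sided upper-tail mid-p value (tail minus half the
point mass).  The mid-p correction is always applied on the diagnosis
path; the plain tail is exposed only as a diagnostic.  A table with N = 0,
K = 0 or K = N carries no contrast and is flagged non-evaluable rather
than given a p-value.  Evaluation is delegated to scipy's log-space
hypergeometric routines; the test suite verifies them against an
exact-rational oracle and an exhaustive enumeration of all C(N, n) event
placements for every table with N ≤ 12 (tolerance 1e-12).

sMM(α) is positive when p < α, with 0 < α < 0.5 (default 0.1, a
conventional compromise between sensitivity and specificity).  The
2/3-criterion is implemented as a fraction over *all* recorded windows —
positive when at least 2/3 of windows contain an attack-start day,
assessable from three windows up — rather than a sliding 2-of-3 rule;
onset-based membership ("an attack *started* in the window") is used, not
day overlap.

## Parameter estimation

From the trimmed classification: μ̂ = n/N, μ̂^M = k/K, μ̂^NM = (n−k)/(N−K),
with binomial standard errors; δ̂ = (migraine-days-in-identifiable-attacks
− attacks)/migraine-days, the plug-in continuation frequency.  Zero
denominators yield NaN with the condition flagged.

Two honest caveats, both verified in the test suite:

* per-diary ratio estimates are consistent but noisy; recovery checks and
  cohort comparisons pool counts across diaries before dividing;
* δ̂ measures *observed* run lengths.  Because an attack ending and a new
  onset one day later produces a migraine-locked gap that imputation
  merges, observed runs are slightly longer than chain episodes and δ̂ is
  biased upward by a term of order μ.  The bias is negligible in
  sparse-attack regimes (the δ-recovery test uses μ = 0.01) and does not
  affect the test's size, which depends only on onset placement among
  classifiable days.

## Data cleaning for observational diaries

Applied in fixed order; the pipeline is idempotent on its own output.

1. Cycle lengths are onset-to-onset day differences; an onset is a
   bleeding day preceded by a non-bleeding day.
2. Cycles longer than twice the subject's mean cycle length (mean over all
   her cycles, single pass, no re-iteration) are treated as missing data.
   The longest remaining run of ≥ 3 consecutive valid cycles is kept, ties
   broken toward the earliest; with no such run the diary is excluded.
   The retained range keeps head/tail days when the run touches the
   diary's ends and otherwise cuts at the bounding onsets (keeping the
   closing bleed and its window days).
3. Eligibility requires at least three consecutive valid cycles.
4. Truncation drops days more than 15 days before the first or after the
   last registered bleeding day, re-anchoring day 1 — distant migraine
   days cannot be classified against unrecorded cycles.
5. Locked-day imputation (above).

Simulated diaries skip steps 2–4: they contain no missing data, and the
simulation layouts (three windows plus a 10-day tail) would otherwise be
rejected by the three-cycle filter that exists to guard real diaries.

## The simulator

One diary is one realisation of the chain over a fixed layout: `n_cycles`
cycles of 28 days laid out as 23 non-window days followed by the 5 window
days, plus a 10-day windowless tail.  Bleeding is written on the window's
last three days so the onset sits at window centre and window detection
recovers the layout exactly.  The window phase within the cycle is a
layout knob (`window_offset`); results depend only on the number of window
vs. non-window susceptible days, not the phase.

Default parameters are the pooled clinical subgroup means, read as per-day
probabilities: true positives μ^NM = 0.045, μ^M = 0.244; true negatives
flat μ = 0.083; δ = 0.444 for both (mean attack duration 1.8 days).  They
are point masses by default so that study results are deterministic up to
Monte-Carlo error; `LogNormalSpread` adds multiplicative between-subject
heterogeneity when a population distribution is wanted (the empirical
distributions behind the original study are not published, so exact
replication of its figure-level AUC labels is out of reach by
construction).

Each diary consumes exactly one uniform per day from its own child stream
(spawned from the population seed), so populations are reproducible
independent of batch size or parallel order.  The simulator also returns
ground-truth episode counts, which is what the duration consistency check
uses (observed merged runs would over-estimate duration by the relapse
effect above).

## The ROC/AUC study

For each diary length (3–9 cycles) two labelled arms are simulated and
pushed through imputation → trimming → testing.  The sMM ROC is traced by
sweeping the threshold applied to the mid-p value over all observed
values; the intrinsically binary 2/3-criterion is given a ROC by sweeping
the required window fraction over [0, 1], with the canonical 2/3 point
reported separately (the headline comparisons are asserted at the
canonical points and as AUC orderings, not at figure-level AUC values).
AUC is the trapezoid over the empirical ROC path; vertical segments
contribute no area (verified exactly against scikit-learn on random
scores).  Sensitivities and specificities carry binomial Monte-Carlo
standard errors, and all stochastic assertions in the tests use 3-SE
tolerances.

Problem sizes: the package default is 10 000 diaries per arm (the study
scale); the test suite runs the full 3–9-cycle comparison at 2 000 per arm
and the null-size calibration at 2 000 diaries, sizes at which the
asserted orderings stand clear of Monte-Carlo noise.  The acceptance
script measures the null false-positive rate at 10 000 diaries.

## Known limitations

* The criterion tests association, not burden: a statistically clear but
  rare menstrual pattern is sMM-positive; trial eligibility may want the
  conjunction with the 2/3 rule.
* δ̂'s relapse-merging bias (above) means fitted δ from dense-attack
  diaries over-estimates the chain's continuation probability.
* Cycle-length variability within a subject is not simulated (fixed
  28-day cycles), and the cleaning pipeline's handling of diaries with two
  disjoint valid runs (keep the longest, earliest on ties) is one
  reasonable reading of an under-specified situation.
* Migraine-without-aura status is an input attribute; the package
  diagnoses the association, not the migraine type.
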