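# Methods

## The classifier and its conventions

The five-split avoidance model is evaluated with short-circuiting: the first
split whose predicate holds assigns the class, so an embryo that is both too
fast (t3 − tPNf < 11.48 h) and too slow by the t3 criterion (t3 ≥ 42.91 h) is
KID1, never KID2. Boundary directions follow the printed inequalities
verbatim: a start interval of exactly 11.48 h is *not* too fast; t3 exactly
42.91 h *is* too slow; an irregularity index of exactly 0.3408 is *not*
irregular-low; exactly 0.5781 *is* irregular-high; and an eight-cell time of
exactly 66.00 HPI fails the "before 66" requirement.

Two situations the published description never addresses are resolved as
follows and exposed through the `rule` tag on every result:

* **t5 absent when splits 3–4 are reached.** The index cannot be computed,
  but an embryo that never reached five cells cannot have reached eight cells
  before the deadline either, so it is routed to KID4 via the slow-t8 rule
  with no index.
* **t8 absent at split 5.** An unobserved eight-cell stage is treated as not
  reached before the deadline: KID4, slow-t8.

t4 is accepted in the data model but takes part in no split: the vendor lists
it among the model inputs without defining a rule for it, and we mirror that.
Degenerate spacing (t5 ≤ t2, or t3 outside [t2, t5]) raises an explicit
error rather than producing an index outside [0, 1]; with monotone
annotations this can only occur when t2 = t3 = t5 exactly.

Thresholds live in a frozen config object with the published constants as
defaults and YAML overrides for sensitivity analysis; nothing in the
classifier is hard-coded to the defaults.

## Morphology classing

The blastocyst quality classes overlap as defined in words (a 4AC grade has
both "an A" and "a C"), so classing applies worst-component-dominates
precedence: expansion ≤ 2 → Slow, else any C → PQE, else any A → TQE, else
B/B → GQE. This is the only precedence under which every clinically usable
(3BB-or-better) blastocyst lands in TQE or GQE, which the published
usable-blastocyst analysis presupposes. The enumerated 63-grade truth table
is a test fixture.

For day-3 embryos the printed PQE criterion ("and/or <50% fragmentation")
contradicts the GQE criterion (">20%"); it is read as ≥ 50%, the only
interpretation under which the three classes cover the space. Precedence is
TQE → PQE → GQE, so a 4-cell fragmented embryo is poor, not good. "TD" in
the source is read as trophectoderm (TE).

## Outcome statistics

The three endpoints are nested per transfer (live birth ⇒ clinical pregnancy
⇒ hCG rise), so LBR ≤ CPR ≤ PR for every group. Rates and contributions are
percentages rounded to one decimal, half away from zero; whole-percent
prose figures (62%, 71%, 83%) are integer roundings of the one-decimal
value. Event counts are reconstructed from printed (n, rate) pairs by
nearest-integer inversion, and the digest module asserts that these
reconstructions sum to the printed cohort totals for CPR (299) and LBR
(283); the per-group PR counts sum to 379 against a printed total of 380, a
misprint in the source that is stored and reported as informational rather
than silently corrected. The blastocyst columns of the morphology-by-stage
table are garbled in the source (rate columns duplicating contribution
columns, shares inconsistent with the printed n) and are not packaged.

Fisher's exact test uses the probability-mass two-sided convention: the sum
of hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed table, with 1e-7 relative slack
against floating-point ties. Tests verify it against exact-rational full
enumeration on every table with margins ≤ 12 and against an independent
library implementation. The ordinal trend is an ordinary least-squares fit
of rate on class rank (slope in percentage points per class); the degenerate
constant-rate case returns slope 0 with r² 0 by convention.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, not embryo
biology:

* **Group sizes** default to the study's 116/287/285/80 transfers
  (day-3 fresh, day-5 fresh, day-5 frozen, day-6 frozen).
* **Class distribution** defaults to 5/7/4/22/62% for KID1–5.
* **Outcomes** are drawn by nested Bernoulli construction — live birth
  first, then clinical pregnancy among non-live with probability
  (CPR−LBR)/(1−LBR), then hCG among non-clinical with (PR−CPR)/(1−CPR) — so
  the marginals match the configured class- and stage-conditional triples
  (defaults: the per-class day-3 and blastocyst table values) and nesting
  holds by construction.
* **Annotation times** are drawn by constructive inversion of the
  classifier: uniform sampling inside the threshold-carved region for the
  target class, with the five-cell time solved from a uniformly drawn index
  value, then monotone extension through tEB. Margins of 0.15 h on time cuts
  and 0.015 on index cuts (with t3 − t2 ≥ 2 h enforced where the index is
  constrained) guarantee that rounding times to 0.01 h never crosses a cut,
  so `classify(sample_times_for_class(k)) = k` holds for every draw. KID4
  mixes its two sub-types (~45% irregular-high, ~45% late eight-cell of
  which a third unobserved, ~10% never reaching five cells).
* **Morphology** is sampled independently of the kinetic class by default
  (day-3 shares 29/61/10% TQE/GQE/PQE; blastocyst 37/50/5/8%
  TQE/GQE/PQE/Slow), matching the source's emphasis that morphology and
  morphokinetics are separate axes; an optional `(class, morphology) → LBR`
  coupling map supports the interaction analysis.
* **Blastulation** flags are drawn per class (23/21/21/36/66% for KID1–5),
  emulating the separate blastulation-endpoint cohort.

What the generator does **not** model: realistic within-class kinetic
distributions (none were ever published — pronuclear fading ~ U(20, 28) h
and uniform gaps are labelled conveniences), correlation between division
times, patient effects, morphology–kinetics correlation (unless opted in),
or any image-level feature. Passing recovery tests therefore demonstrates
that the pipeline's arithmetic is correct under the configured
probabilities, not that the classifier would perform identically on real
annotation data. A transferred-blastocyst record's drawn blastulation flag
is likewise a simulation variable, not a logical consequence of its
transfer day.

## Problem sizes and tolerances

Classifier–oracle agreement is checked on 10,000 random valid time vectors;
generator round-trips on 5,000 draws per class; rate and blastulation
recovery on 10,000 embryos per class, asserted within three binomial
standard errors of the configured probabilities; outcome-marginal recovery
on 20,000 draws within ±0.01. The acceptance script's simulated quantities
use ten times the study's group sizes (7,680 transfers), which puts binomial
noise on a per-class rate below one percentage point. Digest arithmetic is
asserted exactly at the printed precision.

## Known limitations

* The packaged digest inherits the source's misprints (the PR count sum; one
  prose rate that disagrees with its own table by one reconstructed event);
  these are surfaced, not repaired.
* The generator's kinetics are uniform stand-ins; do not use them to study
  time-distribution-sensitive questions.
* No covariate modelling (age, treatment, stimulation protocol) and no
  survival analysis: the validation design compares raw per-class rates.
* The published p-values for specific subgroup comparisons are not
  reproduction targets: the exact 2×2 tables behind them are not recoverable
  from the printed counts. The test itself is implemented and verified
  against enumeration instead.
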