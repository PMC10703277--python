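# Methods

## The elicitation model

`meritrank` assumes each respondent carries an additive multi-attribute
value function over a criteria framework: one value `v(c, l)` per criterion
`c` and performance level `l`, non-decreasing in `l`, with `v(c, lowest) = 0`
and the highest-level values summing to 100. A proposal's worth is the sum
of its per-criterion values, so totals live on a 0–100 scale and the
highest-level value of a criterion is its weight.

Preferences are elicited with two-criterion trade-off questions ("partial
profiles"): option A is better on one criterion and worse on the other, all
remaining criteria implicitly equal, so under additivity an answer is
exactly a linear inequality between four level values. For K criteria with
m elicited levels each there are `C(K,2)·C(m,2)²` such questions (54 for
the default 4×3 setup). The engine is adaptive: after every answer, each
still-open question whose ordering is now logically forced is moved to the
*implied* set and never asked, so the session ends with all 54 pairs ranked
explicitly or implicitly.

### Implication testing

A question's ordering is implied when the opposite ordering is infeasible
under the accumulated linear constraints. Feasibility is probed with an LP
over the elicited level values (lowest level fixed at 0, monotone steps and
strict preferences separated by a margin of 1e-3 points, top-level sum
fixed at 100): "A implied" means no feasible value system puts B ahead.
This is strictly stronger than transitivity chaining — it also catches
cross-pair arithmetic consequences (e.g. a step of criterion 1 that beats
criterion 2's whole range, combined with a step of criterion 2 beating
criterion 3's range, forces the criterion-1-vs-criterion-3 comparison).

Two sound shortcuts avoid most LP solves without changing any verdict:

* a per-criteria-pair digraph over profiles (dominance edges plus recorded
  orderings) settles same-pair chains by reachability;
* feasible points returned by earlier solves are cached as witnesses — two
  witnesses with opposite-signed value differences prove "still undecided"
  with two dot products.

The test suite verifies that LP implication subsumes an independently
implemented transitivity closure on over 1000 randomly reached states.

### Question selection

`sequential` asks the first open question in a fixed canonical order
(criteria pair names, then option-A levels descending). `greedy` asks the
question with the best worst-case elimination count over its two strict
answers. Counting eliminations with the LP itself costs ~100 probes per
candidate and answer, so greedy scores candidates with the same-pair
closure count — a sound lower bound that is exact on a fresh state, where
a single answer can only have same-pair consequences. The exact LP count is
retained as a brute-force oracle in the tests. Greedy's mean question
burden does not exceed sequential's over seeded cohorts (tested at 30
respondents), and simulated cohorts answer a median of ~21–23 questions,
within the 7–24 range observed for this framework in practice.

### Quality control

Mirroring fielded DCE practice: the first and the (lower) median-index
answered questions are re-asked at the session end (a session with a single
answered question re-asks it twice, keeping exactly two repeats);
consistency is the number of exact matches (0–2). A session is a "speeder"
if any response took under 1 s or the median response time (all responses,
repeats included, lower median on even counts — the conservative choice)
is under 3 s; both thresholds are CLI flags. Only completed, non-speeder
sessions enter estimation. Completeness of a session read from CSV is
re-derived by replaying its answers and checking that no enumerated task
remains undecided (the CSV schema deliberately carries no derived columns).

## Weight derivation

The answers of one respondent form the constraint set of a two-stage LP:

1. **Max-margin**: maximise the common slack ε by which every strict
   preference and every within-criterion level step holds. ε* > 0
   certifies consistency; engine-produced sessions are consistent by
   construction because only questions with both answers feasible are
   asked (an externally supplied contradictory file raises an error that
   names a preference cycle when one exists on a single criteria pair).
2. **Regularisation**: fix ε = ε* and minimise the L1 distance to a
   neutral reference grid (equal criterion importance, equally spaced
   levels). This selects a deterministic, reproducible representative from
   the max-margin face; the same answers always give a bit-identical
   point system.

Only ordinal properties of the output are meaningful: the derived system
reproduces every elicited and implied ordering with strict margin, but its
cardinal values are one admissible choice among many, so tests assert
ordinal recovery (exact, 100 seeded error-free respondents) and the scale
invariants, never cardinal agreement with any external tool.

EQUAL answers are hard equality constraints. The engine guarantees they are
admissible: when both strict orderings of a question are feasible,
convexity makes the tie feasible too.

### Interpolation and aggregation

Non-elicited levels (medium-low, medium-high in the default framework) are
filled per respondent by the Fritsch–Carlson monotone piecewise-cubic
interpolant through the elicited (rank, value) points, leaving elicited
values untouched; collinear anchors interpolate linearly. Group statistics
(mean, sample SD, t-based 95% CI with n−1 df; a single respondent reports
SD 0 and a degenerate CI by convention) are computed after per-respondent
interpolation, matching how mean weights are conventionally reported for
such surveys. R's `splinefun(method="monoH.FC")` serves as an independent
interpolation oracle in the tests; its boundary-slope rule differs slightly
from SciPy's PCHIP variant, so the oracle comparison uses a ±1.0-point
tolerance while monotonicity and bracketing are asserted exactly.

The packaged reference point system (published mean weights for the default
framework, from a survey of 220 stakeholders) is stored exactly as printed:
its rounded top-level values sum to 100.1, so it is validated with an
as-printed tolerance of ±0.5 rather than renormalised — traceability beats
internal consistency for published numbers.

## Scoring and comparisons

Scores add across criteria with a zero floor, so the minimum over ratings
is 0 and the maximum exactly 100 for any derived normalised system; ranks
use competition ("1224") ordering with ties broken stably by proposal id;
merit–cost is a plain ratio requiring positive cost. Group comparisons use
a hand-rolled fixed-effects one-way ANOVA (between/within decomposition) on
each criterion's highest-level weight; it matches `scipy.stats.f_oneway` to
1e-10 on random data, with documented conventions for degenerate inputs
(all values identical: F = 0, p = 1; zero within-group variance with
unequal means: F = ∞, p = 0). Committee-mode scoring uses the group-mean
point system by default; per-respondent systems remain available.

## Synthetic respondents

The generator emulates the kind of stakeholder survey the pipeline is built
for, with known ground truth:

* **True values**: top-level weights are Dirichlet draws centred on the
  group mean vector (equal shares by default), scaled to 100. The default
  concentration of 40 gives a between-respondent top-weight SD of ≈6.8
  points, representing true preference heterogeneity consistent with the
  ~7–9-point SDs reported for such surveys once elicitation noise is
  added on top. Interior elicited levels sit at sorted uniform fractions
  of the top value (default band 0.4–0.8); non-elicited levels are filled
  with the pipeline's own monotone interpolant.
* **Answers**: the sign of the true value difference; differences within
  an indifference threshold (default 0) give EQUAL; strict answers flip
  with probability `error_rate` (cohort default 0.05, a convention — no
  empirical noise level is available; error-free studies set it to 0).
  Errors never fabricate EQUAL, so they remain observable through the
  consistency repeats.
* **Response times**: lognormal (median 6 s, σ = 0.5 by default). The
  speeder persona uses median 0.5 s and caps every response at 0.9 s, so
  injected speeders fall entirely below the 1 s threshold and are flagged
  with sensitivity 1.0.
* **Non-completers** abort after 1–6 answers.

What the simulator does **not** model: learning or fatigue across the
question sequence, intransitive or non-additive true preferences, criterion
interactions, or demographic structure beyond the group label. Passing
recovery tests therefore show that the pipeline faithfully inverts its own
assumed response model — not that real respondents satisfy that model.

## Problem sizes and numerical choices

* Feasibility probes use a 1e-3-point separation margin with 1e-6 solver
  slack; all LPs use the HiGHS solver via SciPy, which is deterministic.
* Stage 2 re-imposes ε at ε*·(1−1e-9) to keep the stage-1 optimum feasible
  under floating-point round-off.
* The burden study (acceptance script and test) simulates 200 respondents
  with flat-Dirichlet top weights — the least-informative prior over weight
  vectors — and reports the cohort median (~21–23 explicitly answered
  questions). Ordinal recovery runs 100 respondents; the implication-
  completeness check covers 1000+ reachable states; the group-difference
  power study runs 100 replicates of 100-per-group cohorts on sampled true
  systems (elicitation fidelity being established separately and exactly
  by the ordinal-recovery test).

## Known limitations

* The LP margin makes "strict" preference a modelling choice; genuinely
  indifferent respondents should use the EQUAL answer rather than tiny
  margins.
* The stage-2 reference grid is one defensible tie-break among many;
  cardinal point values should not be over-interpreted (only orderings,
  and aggregate means across many respondents, carry information).
* With many EQUAL answers the max-margin ε* can be small and the derived
  system close to degenerate; the scale invariants still hold.
* Greedy question selection is a heuristic stand-in for the (unpublished)
  selection rule of hosted DCE software; only the resulting burden range
  is comparable, not per-respondent question sequences.
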