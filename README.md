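# meritrank

Adaptive pairwise-ranking preference elicitation and multi-criteria scoring
of research proposals.

Research funders and clinical trial networks must decide which proposals to
pursue, and ad-hoc scoring sheets bake in arbitrary weights. `meritrank`
implements the full pipeline of a PAPRIKA-style adaptive discrete choice
experiment (DCE) so that the weights come from stakeholders' revealed
trade-offs instead:

1. **Framework** — criteria (default: *Appropriateness*, *Significance*,
   *Relevance*, *Feasibility*) with five ordered performance levels each, of
   which low / medium / high are shown in choice tasks.
2. **Elicitation** — respondents choose between *partial profiles*:
   hypothetical proposals described on just two criteria at a time with a
   strict trade-off. After each answer, every task whose ordering is now
   logically forced is eliminated (by linear-programming feasibility, which
   subsumes transitivity chaining), so each respondent answers only a small
   subset of the 54 enumerated tasks. Two tasks are repeated at the end as a
   consistency check, and "speeders" (any answer < 1 s, or median < 3 s) are
   excluded.
3. **Valuation** — each respondent's answers become a *point system*
   `v(criterion, level)` with `v(·, lowest) = 0` and
   `Σ_c v(c, highest) = 100`, found by a two-stage LP (maximise the
   separation margin, then regularise toward a neutral grid for
   determinism). Non-elicited levels are filled by monotone (Fritsch–Carlson)
   interpolation; group means with SDs and t-based 95% CIs are reported.
4. **Scoring** — a proposal rated with one level per criterion scores
   `S = Σ_c v(c, level_c) ∈ [0, 100]`; proposals are ranked (ties share the
   minimum rank) and optionally divided by cost for a merit–cost ratio.
   Group differences are compared by one-way ANOVA on each criterion's
   highest-level weight.

A synthetic-respondent module generates cohorts with known additive value
systems, response errors, indifference thresholds, lognormal response times
and speeder/non-completer personas, so every stage is testable end to end.

## Worked example

```python
import meritrank as mr

fw = mr.load_default_framework()

# simulate a small two-group stakeholder cohort through the full DCE
cfg = mr.CohortConfig(groups=[
    mr.GroupConfig(name="consumer", n=3, error_rate=0.0),
    mr.GroupConfig(name="researcher", n=3, error_rate=0.0),
])
sessions, truth = mr.generate_cohort(fw, cfg, seed=21)

res = mr.PaprikaModel(sessions, fw).fit()
print(res.summary())
```

```
Stakeholder mean point values (0-100 scale)
==========================================================
respondents: 6  (excluded: 0 speeders, 0 non-completers)
      criterion level_label mean  sd ci_low ci_high  n
Appropriateness         Low  0.0 0.0    0.0     0.0  6
Appropriateness  Medium-low  9.9 3.4    6.4    13.5  6
Appropriateness      Medium 17.7 4.9   12.6    22.8  6
Appropriateness Medium-high 23.6 5.1   18.2    28.9  6
Appropriateness        High 28.1 5.2   22.6    33.5  6
...  (Significance, Relevance, Feasibility rows follow)
==========================================================
```

Each row is the group-mean value (percentage points) of one performance
level; the `High` rows are the criterion weights proper, and they sum to
100 across criteria for every respondent.

Scoring a proposal under the packaged published mean weights (a survey of
220 consumers, researchers and funders on the default framework):

```python
ref = mr.load_reference_weights()
rating = mr.ProposalRating("demo", {
    "Appropriateness": 3,  # Medium        -> 18.7
    "Significance": 5,     # High          -> 26.6
    "Relevance": 2,        # Medium-low    ->  8.8
    "Feasibility": 4,      # Medium-high   -> 16.9
}, cost=2.0)
print(mr.score_proposal(ref, rating))        # 71.0
print(mr.merit_cost_ratio(71.0, 2.0))        # 35.5 points per unit cost
```

The same pipeline is available from the shell:

```sh
meritrank simulate-cohort --config cohort.yaml --seed 3 --out sessions.csv --truth truth.json
meritrank qc sessions.csv --min-rt 1.0 --median-rt 3.0 --out qc.json
meritrank derive sessions.csv --out weights/
meritrank aggregate weights/ --by --out mean_weights.csv
meritrank score proposals.csv --weights reference --out scored.csv
meritrank summarize weights/
```

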