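# Methods

This note documents the models, parameter choices and numerical decisions
behind `cabanet`, and what the synthetic experiments do and do not show.

## The synthetic cohort generator

The generator emulates a one-year post-marketing-surveillance cohort of 660
metastatic, docetaxel-refractory CRPC patients treated with cabazitaxel.
One row per patient; 91 explanatory variables; three response variables
(OS, TTF, PSA response) with censor bookkeeping.

### Variables

Thirty-three *structural* explanatory variables carry the clinical content:
age, Gleason 8–10, ECOG PS (ordinal 0/1/2, where 2 stands for "≥2"), four
prior-therapy flags, nine metastatic-site flags, baseline PSA, prophylactic
G-CSF, dose per cycle (mg/m²), relative dose intensity (RDI, %), cycle
count, three discontinuation-reason flags, and nine adverse-event flags.
The remaining 58 columns are independent noise (alternating binary at
prevalences 0.05–0.5 and standard-normal continuous), padding the
dimensionality to 91: the full variable list of the emulated study is not
public, and inventing 58 more named clinical variables would add no
information, while the dimensionality matters for the network stages.

Binary prevalences, the age distribution (normal, median 70 y, sd 9.5,
clipped to 43–91), the dose distribution (normal 20.8 ± 3.4 mg/m², clipped
10–26.3), and the ECOG distribution (62.5/29.5/8.0%, renormalized over the
0.2% unknown) are set to the published cohort's values.

### Generative chain

1. **Exposure.** RDI = dose/25 × f × 100 with an intensity factor
   f ~ N(0.81, 0.15) clipped to [0.30, 1.01] (delays and reductions), so the
   median RDI lands at the published 67.2%.
2. **TTF** follows a Weibull proportional-hazards model (shape 1.05, scale
   169 d) with log-HR +0.65 per SD of RDI: a higher delivered intensity
   shortens the time on treatment, giving the weak *negative* RDI–TTF
   correlation the emulated analysis reported.  Marginal KM median ≈ 116 d.
3. **Observation window** = 365 d, except for a 5% early-dropout fraction
   censored uniformly in (30, 365) — the second censored population a
   one-year registry carries.  TTF and OS are both truncated at the window.
4. **Cycles** = round(TTF/21 × c) with c ~ N(0.75, 0.30) clipped to
   [0.3, 1.2], capped at 18 — a noisy derivation of treatment duration,
   median 4 cycles.
5. **Neutropenia cascade**: any-grade neutropenia is logistic in
   standardized dose and cycles (intercept 0.58, coefficients 1.10 and
   1.30 → incidence ≈ 57.9%); Grade ≥3 is an 85% subset of any-grade
   (≈ 49.2%); febrile neutropenia a 36.6% subset of Grade ≥3 (≈ 18.0%);
   bone-marrow suppression is neutropenia plus an independent 28.3%.
   The nesting mirrors clinical grading and induces the strong
   within-cascade correlations a real safety dataset shows.
6. **OS** is Weibull (shape 1.25, scale 468 d) with log-HRs: liver
   metastasis +1.25, lung metastasis +1.20, ECOG +0.90 per level,
   neutropenia −1.05, and −0.70 per SD of (recorded) TTF — treatment
   duration and neutropenia are protective, visceral metastases and poor PS
   adverse.  Marginal KM median ≈ 319 d with ≈ 52% events by day 365.
7. **PSA response** (≥30% decline; baseline ≥ 5 ng/mL eligibility from a
   log-normal baseline PSA) is logistic in standardized TTF, with 15%
   assessment missingness on top of ineligibility (~18% missing overall).

All draws come from one `numpy` generator seeded per cohort; identical
(config, seed) pairs are bit-for-bit reproducible.  Covariates are
standardized inside linear predictors against *fixed* reference moments, so
the generative law does not depend on the realized sample.

### Effect-size choices

The emulated cohort reports only qualitative subgroup-ordering
directions, so the absolute effect sizes are free design parameters.  They were fixed once by a Monte-Carlo pilot of the full
pipeline: large enough that each planted dependency has a conditional
partial correlation ≳ 0.15 in every conditioning context the PC search can
visit at n = 660 — the level needed for a supermajority of bootstrap
skeletons to retain the edge under 365-day administrative censoring — and
small enough that the implied univariate hazard ratios (≈ 2–3.5 for the
adverse factors, ≈ 0.3–0.5 for the protective ones) stay within the range
real CRPC registries report.  The printed-marginal calibration (medians,
incidences) was re-verified after fixing them.

### What the generator does not emulate

No per-center effects (316 centers), no CTCAE grading logic, no
longitudinal PSA kinetics, no informative censoring beyond the uniform
dropout, no correlation among baseline covariates (metastatic sites are
drawn independently), and the 58 padding variables are pure noise.  Passing
recovery tests therefore show that the pipeline finds planted conditional
dependencies at realistic n, censoring and dimensionality — not that it
would be well-calibrated under correlated baselines or informative dropout.

## Graphical-Markov stage

*Partial correlation* r(i,j·S) is computed from the inverse of the
(cached) correlation submatrix; |S| = 1 uses the closed-form recursion.  A
submatrix with condition number above 1e8 gets a ridge of 1e-4 on its
diagonal; an irrecoverably degenerate computation (zero-variance column,
singular after ridge) yields an *incomputable* signal instead of an
exception.  The Fisher-z test uses √(n−|S|−3)·|atanh r| with a two-sided
normal tail; n−|S|−3 ≤ 0 is incomputable.

*PC skeleton*: edges start complete and are removed at the first
conditioning set (sizes 0..3, enumerated in increasing size, lexicographic
within size, drawn from the current neighbourhoods of either endpoint) with
p > α.  Incomputable tests are skipped with the edge retained for that set:
the estimation must never abort mid-run on a degenerate resample.  Constant
columns are isolated up front.  Each surviving
edge carries the partial correlation of its last surviving test, the sign
source.  The conditioning cap of 3 keeps the per-iteration cost bounded;
the search is exact under that cap, with level-1 tests vectorized and
higher levels computed through stacked submatrix inversions (the scalar
ridge path is the semantic reference and handles all degenerate entries).

*Stability selection*: B patient-level nonparametric bootstrap resamples
(same n, with replacement; the resampling unit is the patient because no
strata are defined), one skeleton per resample, per-pair selection and
positive-sign counts.  A pair is *stable* iff count > min_count (strictly;
default B/2, i.e. ">500 of 1000").  Sign: positive iff the positive
fraction > 0.5 strictly, negative iff < 0.5, indeterminate at an exact tie.
A failed iteration is logged and contributes no edges.

A consequence of bootstrapping one fixed dataset: per-iteration false
selections run at roughly twice the nominal α (the bootstrap doubles the
variance of a correlation statistic around its sample value), so the *mean*
per-pair null frequency is ≈ 0.13 at α = 0.05 — but the strict
supermajority rule is calibrated, selecting a null pair at ≈ α (only pairs
whose full-sample p-value already beats α can be stable).  Stability
selection controls stable false edges, not per-iteration ones.

## Consensus clustering

Stable edges (frequency > 0.5) form the weighted association graph.  The
descriptive model names map to the canonical igraph algorithms: edge
betweenness; leading eigenvector; fast-greedy modularity; Louvain (fast
unfolding); label propagation (near-linear-time); walktrap (random walks);
infomap (maps of random walks).  Frequencies act as tie strengths; edge
betweenness, which interprets weights as distances, receives 1/weight, and
its dendrogram is cut at maximum *weighted* modularity evaluated explicitly
(igraph would otherwise score cuts with the distance weights).  Every model
runs per connected component — partitioning a disconnected graph is
well-defined and guarantees cross-component co-cluster counts of zero —
with node order canonicalized and stochastic models seeded, so a rerun is
identical and input order is irrelevant.

The consensus rule is ≥ 4 of 7 co-clusterings.  The descriptive form of the rule reads as strictly more than four, but
count-4 factors are reported as findings in the emulated results, so the
inclusive reading is taken as normative (both behaviours are a
`min_models` flag away).  The 80% positive-causality rule is inclusive at
the boundary (0.80 → positive).

## Survival confirmation

Kaplan–Meier estimation, the k-group log-rank test and the univariate Cox
model are delegated to lifelines; the module owns subgroup definitions,
degenerate-input handling and reporting.  Medians are the smallest t with
S(t) ≤ 0.5 (flagged undefined when the curve never reaches 0.5, as happens
under administrative censoring); median CIs use the log–log
(Brookmeyer–Crowley) construction, matching how registry reports print
median CIs without naming a method.  Cox ties use Efron's correction
(discrete-day data produce heavy ties); monotone likelihoods are flagged
with an unbounded CI.  The cycle dichotomy is ≥ 4 vs < 4 (the cohort median
and the cut used in the retrospective literature); ECOG compares 0 / 1 / ≥2
with the hazard ratio reported for ≥2 vs 0.  All subgroup HRs are
univariate by design.

## Recovery scoring

Precision, recall and sign accuracy compare unordered pairs.  Two
normalizations make the comparison meaningful:

* **Outcome-view folding.**  With ~50% administrative censoring the
  conditional-independence structure splits an outcome association between
  the recorded-time column and the censoring indicator: conditioning on
  `os_censoring` absorbs the event-probability channel, so the skeleton may
  legitimately attach a covariate to either column (rarely both).  Both
  views fold onto the outcome process before scoring.  Observation-window
  edges carry a "+-" truth sign because their direction is genuinely
  view-dependent (time view positive, dropout view negative).
* **Truth-node restriction.**  Precision is computed over pairs whose
  endpoints lie in the planted graph's node space.  Pairs among the noise
  padding have no declared ground truth and are expected to appear at the
  test size (≈ α of all null pairs); they are a property of the α-level
  testing, not of the generator, and are exercised by the dedicated null
  calibration test instead.

## Problem sizes

The default analysis configuration is B = 1000 iterations at α ∈ {0.05,
0.01}.  The test suite and pilots use B = 200 (recovery), B = 100 (null
calibration), 20 seeds (calibration pooling), n = 5000 (skeleton toys) and
1000 replicates (type-I calibration) — sizes at which every Monte-Carlo
margin in the assertions is several standard errors wide while a full run
stays in the minutes range on one core.

## Known limitations

* Pearson-based partial correlation treats binary and ordinal columns
  numerically; polychoric/rank options are out of scope.
* No edge orientation: the output is an undirected skeleton with signs.
* The PC search is the sequential (non-stable) variant; edge-removal order
  follows the canonical lexicographic enumeration, so results are
  deterministic but can differ from order-independent PC variants.
* Bootstrap stability selection on a single dataset cannot remove
  full-sample chance correlations (see above); interpretation of any one
  stable edge should account for the ≈ α stable-false rate.
* The immortal-time concern for exposure-derived factors (cycles,
  neutropenia accrue with time on treatment) is inherited from the emulated
  design: the subgroup HRs for those factors are confirmatory
  visualizations, not causal estimates.
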