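# cabanet

Network-based machine-learning analysis of clinical outcomes in
castration-resistant prostate cancer (CRPC), packaged as a tested, fully
reproducible pipeline on synthetic registry-style cohorts.

Real-world registries of cabazitaxel-treated, docetaxel-refractory CRPC
patients suggest that the adverse events and treatment-exposure variables a
patient accrues (neutropenia, number of treatment cycles, relative dose
intensity) carry prognostic information about overall survival, alongside
classic baseline factors (visceral metastases, ECOG performance status).
`cabanet` re-implements the analysis chain used to mine such registries —
graphical-Markov network estimation with bootstrap stability selection, a
seven-algorithm community-detection consensus, and Kaplan–Meier subgroup
confirmation — and pairs it with a synthetic cohort generator whose
dependency structure is *known*, so every stage can be scored against ground
truth.  It is aimed at biostatisticians and methods researchers who want to
study or extend this class of registry analyses without access to closed
patient-level data.

## The methods

**Synthetic cohort.** `generate_cohort` simulates n = 660 patients with 91
explanatory variables: baseline characteristics and metastatic sites drawn at
published prevalences, treatment exposure (dose, relative dose intensity,
cycle count), a neutropenia → Grade ≥3 → febrile-neutropenia cascade that is
logistic in exposure, and Weibull proportional-hazards outcomes

> S(t | x) = exp( −(t/λ)^k · e^{βᵀx} )

for overall survival (OS) and time-to-treatment-failure (TTF), with
administrative censoring at 365 days plus a small early-dropout process.
Defaults are calibrated so the cohort reproduces the published marginals
(median age 70 y, KM median OS ≈ 319 d, TTF ≈ 116 d, any-grade neutropenia
≈ 57.9%, …).  The generator returns the planted dependency graph with signed
effect sizes.

**Graphical-Markov stage.** Conditional independence of variables i, j given
a set S is tested through the partial correlation r(i,j·S) (inverse of the
correlation submatrix, ridge-stabilized when near-singular) with the
Fisher-z statistic √(n−|S|−3)·|atanh r| against a standard normal.  A
PC-algorithm skeleton search removes an edge as soon as some conditioning
set of size ≤ 3 among current neighbours yields p > α.  Incomputable tests
(singular submatrices, degenerate resamples) are skipped with the edge
retained, so a run can never abort.  The skeleton is re-estimated on B
patient-level bootstrap resamples; a pair is reported only when present in
strictly more than B/2 iterations (the ">500 of 1000" rule at α = 0.05 or
0.01), and its sign is voted from the surviving partial correlations.

**Consensus clustering.** Stable edges (frequency > 0.5) form a weighted
association graph, partitioned by seven classical community-detection
algorithms (edge betweenness, leading eigenvector, fast greedy, Louvain,
label propagation, walktrap, infomap — via igraph).  A factor is declared
associated with a response when they co-cluster in ≥ 4 of the 7 models; a
direction is called positive when the bootstrap positive-sign frequency is
≥ 80%.

**Survival confirmation.** Kaplan–Meier curves with Greenwood variance and
Brookmeyer–Crowley (log–log) median CIs, log-rank tests, and univariate Cox
hazard ratios (Efron ties, via lifelines) for six subgroups: liver
metastasis, lung metastasis, ECOG PS, neutropenia, febrile neutropenia, and
≥ 4 vs < 4 cabazitaxel cycles.

**Recovery scoring.** Selected edges are compared with the planted graph as
unordered pairs (precision, recall, sign accuracy).  Because ~50% of OS
times are administratively censored, an outcome association may surface on
the recorded-time column or on the censoring indicator; both views fold onto
the same outcome process before scoring.

## Worked example

```bash
cabanet run-all --iterations 200 --seed 0 --out out/
# alpha 0.05: 57 stable edge(s)
# alpha 0.01: 25 stable edge(s)
```

`out/edges_alpha005.tsv` is the stable-edge table (the machine twin of a
graphical-modeling results table); its top rows at seed 0:

```
source                   target                     frequency  sign
bone_marrow_suppression  neutropenia                1.0        positive
disc_adverse_event       ttf_censoring              1.0        negative
dose_per_cycle           relative_dose_intensity    1.0        positive
febrile_neutropenia      grade3plus_neutropenia     1.0        positive
```

`out/consensus_alpha005.tsv` counts, for every factor, in how many of the
seven clustering models it shares a community with OS and with TTF; at seed 0
liver and lung metastasis co-cluster with OS in 7/7 models.  The subgroup
table (`out/subgroups.tsv`) shows the confirmatory pattern, e.g. liver
metastasis HR = 2.25 (95% CI 1.70–2.98, present vs absent) and a log-rank
p ≈ 6×10⁻⁹ — visceral metastases are adverse, while neutropenia and ≥ 4
cycles come out protective.  Against the planted truth this run recovers the
dependency graph with precision 1.00, recall 0.79, sign accuracy 1.00
(`report.json`, key `recovery`).

Every number above is deterministic given `--seed`.

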