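# morbnet

Multimorbidity network analysis for binary chronic-disease survey data:
estimate the conditional-dependence network among diseases, partition it
into multimorbidity patterns, nominate **bridging diseases** by centrality,
and quantify their association with complex (multisystem) multimorbidity.

## The problem

Multimorbidity — two or more chronic conditions in one person — is usually
summarized by clustering diseases into patterns (cardiovascular,
musculoskeletal, mental, ...). Pattern lists alone hide the *structure*
between patterns: some diseases sit between otherwise separate clusters and
may act as gateways through which a patient's profile grows from one
pattern into a complex multisystem phenotype. `morbnet` is built for
epidemiologists and health-services researchers who want to go from a
person × disease 0/1 table to (1) a sparse disease network, (2) pattern
communities, (3) centrality-ranked bridging candidates, and (4) adjusted
odds ratios for the complex phenotype — with gender stratification as a
first-class axis.

## The model

All disease indicators are binary, so the underlying graphical model is an
Ising-type pairwise Markov random field over x ∈ {0,1}^p:

    P(x) ∝ exp( hᵀx + ½ xᵀ W x )

Estimation is **nodewise L1-penalized logistic regression**: each disease
is regressed on all the others with lasso penalty λ_s chosen per node by
cross-validation (one-standard-error rule by default) or extended BIC; an
edge (s,t) is kept under the AND rule iff both β̂_{s←t} ≠ 0 and
β̂_{t←s} ≠ 0, with weight = their mean. Because of the {0,1} coding the
aggregated weights estimate the couplings W directly (an optional
unpenalized refit on the selected support removes shrinkage bias).

Downstream: communities by fast-greedy (CNM) modularity maximization;
six centrality metrics (degree, closeness, betweenness, PageRank,
eigenvector, HITS hub score); person-level pattern assignment (≥ 2
diseases of a community ⇒ the pattern is held; ≥ 2 patterns ⇒ *complex*
phenotype); and a gender-stratified logistic regression of the complex
flag on nominated bridging diseases with age/income/education controls,
reported as odds ratios with 95% Wald intervals.

Because survey microdata of this kind are rarely shareable, the package
includes a planted-structure synthetic cohort generator (Gibbs sampling
from a block-community Ising model with designated bridge nodes and
isolated conditions) so the entire chain is testable against known truth.

## Worked example

```python
from morbnet import (DiseaseNetworkModel, MGMConfig, ModelSpec,
                     assign_patterns, default_design, fit_logistic,
                     rank_bridges, simulate_cohort)

cohort = simulate_cohort(default_design(), n=1592, seed=42)
res = DiseaseNetworkModel(cohort, MGMConfig(seed=42, lambda_selection="ebic")).fit()
part = res.communities()
ranked = rank_bridges(res.centralities(), metric="betweenness", top_k=3)
assignment = assign_patterns(cohort, part, min_count=2)
fits = fit_logistic(cohort, assignment.complex_flags.astype(float),
                    ModelSpec(predictors=tuple(ranked.index)))
```

With the default planted design (five disease blocks, bridges at D1
hypertension and D20 depression, four isolates) this prints:

```
edges: 67
communities: 9 Q = 0.683
         degree  betweenness  pagerank
disease
D1            8        176.0     0.030
D20           6        152.0     0.034
D8            6        130.0     0.045
complex prevalence: 25.4%
stratum term    OR  ci_low  ci_high stars
      M   D1 2.603   1.806    3.750   ***
      M  D20 3.013   1.900    4.778   ***
accuracy range: 0.65-0.98
```

Reading it: the estimated network has 67 edges organized into 9
communities (the five planted blocks, plus the isolates as singletons) at
modularity Q = 0.683; the two planted bridge diseases top the betweenness
ranking, as they should; about a quarter of simulated respondents hold two
or more patterns (the complex phenotype); and carrying a bridging disease
multiplies the odds of the complex phenotype by ~2.4–4.6 after demographic
adjustment. Per-node classification accuracies of the nodewise fits span
0.65–0.98.

The same pipeline runs from the shell:

```bash
morbnet run-all --outdir out --seed 42          # simulate + full analysis
morbnet run-all --input cohort.csv --outdir out # your own cohort CSV
```

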