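# Methods

This note documents the statistical machinery behind `morbnet`: the models,
the defaults and why they are set where they are, what the synthetic
cohorts do and do not emulate, and the numerical choices that matter for
reproducibility.

## 1. Data model

A cohort is a person × disease table of 0/1 indicators (default catalog:
32 chronic conditions, codes `D1`–`D32`) plus categorical demographics:
gender (M/F), age group (50-64 / 65-74 / 75plus), income quartile (Q1–Q4)
and education (Primary/Secondary/Tertiary). Disease entries must be
complete and binary — they are the modelling substrate. Demographic values
may be missing; they only enter the regression stage, where listwise
deletion is applied and the dropped count logged. The multimorbidity
filter (keep persons with ≥ 2 diseases) is an explicit operation, never an
implicit side effect.

## 2. Network estimation

### Model

With all variables binary, the pairwise Markov random field is the Ising
model P(x) ∝ exp(hᵀx + ½xᵀWx), x ∈ {0,1}^p. Its full conditionals are
logistic regressions whose coefficients are exactly the couplings
W<sub>st</sub> — the basis for nodewise estimation and for the package's
recovery tests.

### Solver

Each nodewise problem minimizes −(1/n)·loglik + λ‖β‖₁ (intercept
unpenalized) by proximal-Newton coordinate descent: an outer IRLS
quadratic approximation, an inner cyclic coordinate descent with
active-set iteration, warm starts down a log-spaced penalty grid from
λ_max = max_j |⟨x_j, y−ȳ⟩|/n to 10⁻³λ_max (30 points by default).
Convergence is declared when no coefficient moves by more than 10⁻⁷.
Binary design matrices dispatch to a sparse-column kernel with identical
arithmetic (bit-for-bit) at a fraction of the cost. The solver is verified
in the test suite against unpenalized IRLS at λ=0 and against an
independent L1 solver (sklearn saga) at λ>0, both to ≤10⁻⁶.

### Penalty selection

Two selectors are provided per node:

- **Cross-validation** (default, 10 folds): fold splits are a seeded
  permutation cut into contiguous blocks; the score is held-out binomial
  deviance. The default rule is the **one-standard-error** convention —
  the largest λ whose mean deviance is within one SE (over folds) of the
  minimum. The plain minimizer (`cv_rule="min"`, ties broken toward the
  sparser λ) is available but deliberately not the default for structure
  recovery: sample-level spurious correlations persist across folds, so
  CV-min systematically admits false edges (measured ≈12% false-edge rate
  on independent data, versus ≈0% under 1SE). Fold fits use a relaxed
  tolerance (10⁻⁵); the reported coefficients always come from a
  full-tolerance fit on all data.
- **Extended BIC** (γ = 0.25): −2·loglik + df·(log n + 2γ log p). One path
  fit per node, no folds — roughly 10× faster, slightly more liberal than
  CV-1SE on strong-signal designs and the recommended choice for large
  simulation studies.

Per-node CV seeds are derived from the configured seed *and the disease
label* (CRC32), so permuting catalog columns permutes the fitted network
exactly.

### Aggregation

AND rule by default: edge (s,t) exists iff both directed coefficients are
nonzero; weight = their mean. OR keeps an edge when either is nonzero,
treating the absent coefficient as 0 in the mean. Sign-conflicting pairs
are kept with weight = mean absolute magnitude and flagged
`sign_consistent=False` — conflicts are diagnostics, not silent choices.
Aggregated weights below 10⁻⁶ are dropped as numerical noise. An optional
**debiased refit** (unpenalized logistic on each node's selected support)
removes lasso shrinkage before aggregation; with it, estimated edge
weights track the true couplings with RMSE ≈ 0.08 on two 5-cliques
(w = 1.0, n = 5000). Near-separated refits (|β| > 20 or non-convergence)
fall back to the penalized estimate.

Degenerate nodes (constant columns) are retained as isolated vertices with
an intercept-only fit and a warning. Node classification accuracy —
the share of persons with 1{p̂ > 0.5} equal to the observed indicator — is
reported within-sample or on held-out CV folds (both offered because
either convention is common in applied reports).

## 3. Communities and centralities

Community detection is agglomerative CNM modularity maximization on
absolute edge weights: merge the community pair with the largest gain
ΔQ = e_ab/m − d_a·d_b/(2m²) until no positive gain remains. Determinism is
guaranteed by identifying communities with their smallest member's catalog
index and breaking gain ties toward the lexicographically smallest id
pair. Isolates end as singletons; Q is reported for the final partition
and never falls below the singleton baseline.

Centralities (per disease): degree (incident edge count); closeness
(component-restricted (reachable−1)/Σd, isolates 0; a harmonic variant is
available); betweenness (Brandes, unnormalized); PageRank (damping 0.85,
sums to 1); eigenvector centrality (per-component power iteration with a
spectral shift — without the shift the iteration oscillates on bipartite
components — scored on the component with the largest principal
eigenvalue, max-normalized, ties flagged); HITS hub score (max-normalized;
equals the authority score on undirected graphs). Signed weights enter all
metrics as |w|; shortest-path metrics use lengths 1/|w| in the default
weighted mode (strong association = short distance) and 1 otherwise.

One caveat: on *bipartite* graphs the HITS iteration (effectively A²) has
a degenerate top eigenvalue and its fixed point is start-dependent, so the
textbook identity "hub = eigenvector centrality on undirected graphs"
holds only on non-bipartite components; the test suite checks the identity
on connected non-bipartite ensembles. The `nx.hits` start vector is pinned
to the uniform vector — its default random start leaks run-to-run noise at
machine precision, which would break byte-level reproducibility.

Bridging diseases are nominated by ranking on one metric (betweenness by
default), ties broken by degree then catalog order, with all six metrics
reported alongside; the cutoff for how many to carry into the regression
is explicit user input.

## 4. Patterns and the complex phenotype

A person holds pattern P iff they carry ≥ `min_count` (default 2) diseases
of community P; holding two or more patterns defines the complex
(multisystem) phenotype. Published pattern prevalences in this literature
come without a stated person-level rule, so this rule is a declared
package convention — configurable, logged, and chosen to echo the standard
two-or-more-diseases multimorbidity criterion. Assignment is
non-exclusive; pattern prevalences may jointly exceed 100%. Gender
comparisons use the pooled two-proportion z-test, two-sided at α = 0.05
(|z| ≥ 1.959964); zero-pooled-variance cells are reported as undefined
rather than significant.

## 5. Bridging regression

Logistic regression of the complex flag on the nominated diseases with
dummy-coded controls (reference levels: age 50-64, income Q1, education
Primary), fitted per gender stratum by plain maximum likelihood (IRLS,
|Δloglik| < 10⁻¹⁰, ≤ 100 iterations, SEs from the inverse observed
information). Firth-style penalization is deliberately *not* the default:
extreme odds ratios with very wide intervals are a recognizable signature
of plain ML under near-separation, and the package flags that condition
(|β| > 15 or SE > 10³) instead of silently changing the estimator.
Reporting: OR, 95% Wald CI, and stars at 0.05/0.01/0.001. Constant
predictor columns are rejected (pooled) or dropped with a warning
(within a stratum, e.g. a gender-specific condition). Planted-truth
simulations in the test suite verify ≤ 15% bias on an OR of 4 at n = 2000
and near-nominal CI coverage.

## 6. Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not the epidemiology of any real population. A `PlantedDesign` partitions
the catalog into block communities (couplings w_in on all within-block
pairs), bridge nodes attached to several blocks (w_bridge), and isolates.
The default 32-node design has five blocks (sizes 6,6,5,5,4) grouped along
familiar clinical lines, bridges at D1 (hypertension) and D20 (depression)
with w_in = 1.0 and w_bridge = 0.8, four isolated conditions, and target
marginals spanning 0.03–0.42. The two bridges attach disjoint member sets
(offset attachments where they share a block) so that betweenness
concentrates on the true bridges rather than on shared attachment points,
and the planted backbone is connected — a disconnected truth makes bridge
ranking fragile to any single spurious edge.

Thresholds h are calibrated to the target marginals: closed-form
mean-field initialization (h = logit(m) − Wm), then a damped
stochastic-approximation refinement against short seeded Gibbs runs
(12 rounds; fixed damping 0.6 on n = 2000 early, decreasing Robbins-Monro
steps on n = 6000 late). Mean-field alone overshoots by up to ~0.1
prevalence inside w = 1.0 cliques; after refinement realized marginals
match targets within ±0.02 at n = 5000. Calibration is deterministic given
the design, so a parameter set is built once and reused across sampling
seeds.

Sampling is Gibbs with one independent chain per row (200 burn-in sweeps
from a Bernoulli(logistic(h)) start), making rows exchangeable like survey
respondents; a single thinned chain is available. Sweeps visit nodes in
sorted-label order and consume randomness in that order, which makes
sampling exactly label-equivariant. Demographics are drawn independently
of the disease matrix (category probabilities: gender 0.5/0.5, age
0.45/0.30/0.25, income uniform quartiles, education 0.5/0.3/0.2 — chosen
as plausible for a 50+ general population). A separate harness draws a
binary outcome from logistic(β₀ + βᵀx) over disease columns and
demographic dummies to validate odds-ratio recovery.

What passing tests therefore show: the chain recovers *planted Ising
structure* under clean conditions (binary data, no missingness,
independent respondents, pairwise interactions only). They do not show
robustness to self-report measurement error, informative non-response,
survey weighting, higher-order interactions, or temporal disease ordering
— all outside the generator's scope.

## 7. Pipeline conventions

`run_pipeline` executes load/simulate → multimorbidity filter → per-stratum
network fit → communities/centralities/bridge ranking → pattern assignment
→ gender comparison → bridging regression. Stratified runs fit M and F
networks separately *and* a pooled network: pattern identities are not
comparable across independently fitted networks, so the pooled partition
defines the shared patterns used for the gender prevalence comparison and
for the regression outcome. Every output directory carries a manifest with
the seed, a config hash, package version and per-stage log. With a fixed
seed all numeric outputs are byte-identical across runs (the manifest's
wall-clock timings are the only exception).

Default problem sizes in the shipped tests and acceptance script (chains
of p = 8 at n = 4000, the 32-node design at n = 5000, 5–50 seeded
replicates per study, study-scale runs at n = 1592) were chosen so each
simulation study resolves its target property with comfortable margin
while the whole suite stays fast on a single CPU.

## 8. Known limitations

- Pairwise (k = 2) interactions only; no Gaussian or categorical nodes.
- The person-to-pattern rule and the bridging-predictor cutoff are
  package conventions, configurable but not canonical.
- CNM is the only community algorithm (by design); no bootstrap
  edge-stability intervals.
- Plain-ML odds ratios under near-separation are flagged, not corrected;
  Firth-type bias reduction is not implemented.
- The generator's clinical realism is limited to block/bridge/isolate
  topology and marginal prevalence ranges.
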