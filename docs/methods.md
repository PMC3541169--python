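# Methods

This note documents the models, the numerical choices, and what the synthetic
data do and do not establish.

## The classifier and its evaluation

A genome's presence profile is derived from CAZy-style gene counts by
thresholding at one gene (`present ⇔ count ≥ 1`).  Counts are copy numbers;
the screening question is existential, so the threshold is not configurable —
but the rule itself is: `GeneSetRule(required_all, required_any, min_any)`
defaults to GT28 ∧ GT51 ∧ (≥1 of GH23/GH73/GH102/GH103/GH104).  GH25 also acts
on PG but is not part of the default five-family disjunction (lysozymes of
GH25 occur widely outside PG-producing lineages); the six-family variant is a
one-line configuration.

Ground truth is three-valued.  Unknown-status genomes are excluded from every
confusion table and counted explicitly (`excluded_unknown`); they are never
imputed, because the missingness is literature coverage, not biology.  A
metric whose denominator is empty is `None`, an explicit undefined marker —
downstream reports must distinguish "no data" from a perfect score.  The
prediction's orientation (`positive_means`) is a parameter because both
orientations are scientifically useful: the 3-gene set predicts PG presence,
while GT51 absence predicts PG absence.

The bundled `fixture_cohort()` is a synthetic per-genome reconstruction of the
reported confusion structure (1,260 set-positive all PG-present; 138
set-negative split 84/24/30 absent/present/unknown; 114 GT51-negative with 5
PG-present).  It is exact for every cross-tabulation those constants pin down,
but the per-genome supplementary data behind them are not deposited, so any
quantity requiring the real per-genome covariates (the full-cohort φ of 0.963,
the reported odds ratios) is *not* desk-reproducible; the package computes the
analogous quantities on its own fixtures instead and labels them as such.  One
known internal discrepancy of the source constants: no combination of them
yields the reported 99.53 % GT51 specificity (the fixture gives
1279/1284 = 99.61 %); the package reports what it computes.

## Association statistics

* χ² on 2×2 tables is Pearson's without continuity correction (Yates optional
  by flag); a zero margin returns undefined markers, not an exception.
* The φ coefficient is computed in closed form and is tested to equal
  brute-force Pearson correlation of the expanded 0/1 vectors — this removes
  any ambiguity about what "Pearson correlation on indicators" means.
* PCA operates on the centered (optionally scaled) absence-indicator matrix of
  the eight families plus PG over known-status genomes; constant columns are
  dropped with a warning.  Returned loadings are the principal axes
  (orthonormal), suitable for a factor-loading plot.
* Logistic regression of PG absence enters the three binarized covariates
  jointly by default (GC < 50 %, size < 1.5 Mb, obligate intracellular —
  cut-offs are arguments); univariate mode exists because reported effect
  sizes in this literature are sometimes univariable.  Complete separation is
  detected (|β| > 15 or non-finite/huge standard error) and flagged with an
  infinite-OR marker.  Goodness of fit uses Hosmer–Lemeshow on deciles of
  fitted risk with g − 2 df.
* No multiple-testing correction is applied anywhere; the statistics are
  reported per test.

## Gain-penalizing parsimony

Ancestral states minimize total transition cost with `gain_cost = 2`,
`loss_cost = 1` by default — the smallest integer asymmetry that penalizes
gains, which suffices to prefer "one loss at a clade stem plus one regain"
over scattered independent losses, and with equal costs reduces exactly to
Fitch/Sankoff parsimony (cross-checked against dendropy's Fitch pass).  The
dynamic programme handles polytomies natively and ignores branch lengths
(parsimony is topology-only).  Tie-breaks are deterministic: at the root a tie
goes to state 1 (ancestral presence — the natural reading for a trait carried
by > 90 % of extant taxa); below the root a tie keeps the parent's state,
delaying changes toward the tips.  Nodes where a tie occurred carry an
ambiguity flag.  A branch is identified by its child node id ("date"); the
root hosts no event.

`fixture_gt51_tree()` is a synthetic 39-tip bacteria-only cladogram assembled
from the lineages known to have lost GT51 (and the one known regain); it is a
stand-in for the undeposited 1,114-taxon 16S tree.  Parsimony on it yields 8
losses + 1 gain, which demonstrates the method's behaviour on the published
qualitative history, not an independent re-estimate from the original data.

## Correlated evolution (Pagel)

Two binary traits evolve jointly over states {00, 01, 10, 11}; the independent
model has 4 free rates (each trait's gain/loss), the dependent model 8 (each
single-trait transition rate conditioned on the other trait's state);
simultaneous double transitions have rate 0.  Likelihoods use Felsenstein
pruning with per-node rescaling; per-branch transition matrices come from an
eigendecomposition of the generator (one decomposition per likelihood
evaluation, reused across branches), with a scaling-and-squaring fallback for
near-defective generators, all JIT-compiled with numba (a pure
numpy/scipy path exists when the JIT is unavailable).  The root prior is flat
over the four joint states — implementations differ here, so it is stated;
a useful corollary is that the independent model's likelihood factorizes into
two 2-state problems, which both speeds fitting and structurally seeds the
dependent fit.  Trees without branch lengths get unit lengths (configurable):
the 16S input trees for this analysis are cladogram-like.

Fitting maximizes over log-rates bounded in [1e−6, 1e3] with multi-start
L-BFGS-B; `fit()` uses 5 starts by default, the first deterministic and the
dependent model always seeded from the independent optimum (its exact nested
equivalent), which guarantees `lnL_dep ≥ lnL_indep` up to optimizer
monotonicity.  The *score* is `max(0, 2ΔlnL)`.  The *error percentage* is a
parametric bootstrap: traits are re-simulated under the fitted independent
model on the same tree and both models refitted; with the `(1 + k)/(n + 1)`
correction it is never exactly zero.  Inside `pagel_test` the observed data
and every bootstrap replicate use identical reduced optimizer settings
(2 starts, capped iterations): the p-value's validity rests on the observed
and simulated scores being exchangeable under the null, not on each fit being
globally exhaustive, and this keeps a 200-tip test with 19–99 replicates in
seconds rather than minutes.  `n_sim ≥ 19` is enforced (resolution 5 %);
monomorphic bootstrap replicates score 0 (no evidence of dependence).

## Event clustering

A cluster is a set of (character, event-type) pairs that co-occur on shared
branches.  Co-occurrence is at exact branch granularity — the strictest
reading of a "date" framed by two speciation events.  Candidate member sets
are the closed intersections of per-branch event pools; sets of ≥ 2 members
recurring on ≥ 2 branches become clusters, keeping maximal sets.  Feature
clustering groups characters by Jaccard similarity of their event-branch
profiles (default threshold 1.0 = identical profiles).  Events joining no
cluster are returned as an explicit remainder — nothing is silently dropped.
Verification attaches a Pagel test to every character pair of a cluster
(pruning tips of unknown PG status when PG is involved); a cluster is
"supported" when all pairwise error percentages are ≤ 5 %.

## Synthetic data: what it emulates, what it does not

* `simulate_tree` is pure-birth (Yule) with exponential waiting times and one
  final interval, so trees are ultrametric with positive pendant edges and
  mean root-to-tip depth `Σ_{k=2..n} 1/(kλ)`.  A death rate is deliberately
  out of scope — extinction does not change any tested property.
* `simulate_characters` samples exact CTMC paths branch by branch, recording
  every transition, so the *true* history (including multiple hits on one
  branch) is available.  Parsimony undercounts multiple hits by construction;
  the event-recovery test therefore conditions on histories with ≤ 10 changes,
  where the loss-dominated regime (gain 0.002, loss 0.02 per unit length on
  200-tip trees, root in state 1) mirrors a widespread trait eroding in
  scattered lineages.
* `generate_cohort` draws each arm of the confusion structure independently;
  arms with probability 0 or 1 are deterministic, so PPV = 1 is exact while
  NPV and prevalence carry binomial noise.  PG-less set-negative genomes
  always lack GT51, mirroring the observed coupling.  Unknown status can be
  injected into either arm.
* `generate_covariate_cohort` plants a known logistic model (default odds
  ratios 7.7 / 80 / 19.5) behind binary covariates rendered as consistent
  numeric values; it exists for parameter-recovery testing, not realism.

Passing tests on these generators show the *methods* are correct and
calibrated (type-I error of the bootstrap p-value 5 % ± 3 points at 200 tips;
power ≥ 95 % for perfectly coupled traits; parsimony equal to the exhaustive
optimum on every tried instance).  They do not validate the biological claims
on real annotation data, which would require the undeposited cohort and tree.

## Problem sizes and determinism

Monte-Carlo tests use 200-tip trees, 19 bootstrap replicates per test and
200 (null) / 40 (power) outer replicates; oracle-equivalence tests use 500
random instances (≤ 8 tips for parsimony enumeration, ≤ 6 tips for the
likelihood sum).  These sizes give the calibration bands quoted above while
keeping the default suite in the tens of minutes.  Every stochastic component
takes an explicit integer seed (numpy `SeedSequence` spawning); pipeline
reruns with the same config and seed are byte-identical, and the manifest
records the seed and a config hash.

## Known limitations

* Ancestral reconstruction of the focal characters is parsimony-only;
  likelihood/Bayesian reconstruction is out of scope by design.
* The Pagel score's null is χ²₄-like only asymptotically; inference relies on
  the bootstrap, not the asymptotic distribution.
* The bootstrap refits are truncated optimizations; scores are comparable
  across replicates but individual rate estimates from `pagel_test` internals
  should not be over-interpreted — use `fit()` with full starts for rates.
* Branch-granular co-occurrence is conservative: events one node apart never
  cluster (a radius-1 option was considered and left out to keep "date"
  semantics exact).
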