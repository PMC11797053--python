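# Methods

This note records the models the package implements, the numerical and
design choices behind them, and what the synthetic data can and cannot
establish.

## Trees and the Brownian covariance

All comparative machinery consumes the Brownian-motion among-species
covariance C of a rooted tree with branch lengths: C[i,j] is the shared
root-to-MRCA path length, the diagonal the root-to-tip distance. Pagel's
λ-scaling multiplies off-diagonals by λ and keeps the diagonal; the
admissible upper bound λ_max is found by bisection on the smallest
eigenvalue of the scaled matrix and routinely lies slightly above 1 for
nested topologies, so fitted λ a little above 1 is representable.

Ultrametricization deliberately avoids re-dating. `extend` lengthens each
terminal branch to the maximum root-to-tip depth; `mean_path_length`
adjusts terminal branches toward the mean depth and refuses when a branch
would go negative. Downstream, the phylogenetic discriminant needs only
*an* ultrametric covariance, not calibrated dates, which is why a
penalized-likelihood dating step is out of scope.

Pruning preserves all pairwise patristic distances among kept tips
(collapsed unary nodes have their branch lengths summed); a unary root is
kept so original depths survive when the retained tips fall inside one
subtree.

## The synthetic study system

The generator mirrors the analysis model exactly:

* **Tree** — pure-birth (Yule) process, default rate 1, until n species;
  ultrametric by construction.
* **Trophic categories** — a continuous-time Markov chain on
  {herbivore, carnivore, omnivore} along branches; default symmetric rate
  0.3 per off-diagonal, root state omnivore (the intermediate state).
* **Copy numbers** — y_s ~ Poisson(exp(μ + β·1[focal] + u_s + e_s)),
  u ~ MVN(0, σ²ₚ·C̃), e_s ~ N(0, σ²ₑ) i.i.d. C̃ is C scaled to unit
  root-to-tip depth, so σ²ₚ is the marginal phylogenetic variance at the
  tips regardless of the tree's time units — without this convention a
  nominal σ²ₚ would be silently multiplied by tree depth (≈ 4 for a
  32-tip Yule tree at rate 1).
* **Locus tables** — multi-copy families are clustered within the 5-Mb
  window on one chromosome with probability `tandem_fraction`, otherwise
  scattered across distinct chromosomes; coordinates are only as realistic
  as the co-location rule requires.
* **Diet compositions** — herbivores eat primary producers exclusively;
  carnivores and omnivores receive Dirichlet proportions over prey
  classes, weighted toward herbivorous prey.

### Fixture conditions for the pipeline

The bundled pipeline fixture uses 32 species, 100 families, 10 planted
herbivore-high families with effect β = ln 4, baseline μ = ln 1.2,
σ²ₚ = 0.05, σ²ₑ = 0.02, and resamples trophic histories until each
category holds at least 30% of species. These conditions encode what the
screen is designed to detect, and two of them deserve explanation:

* the screen's background criterion (≥ 70% of out-group species with ≤ 2
  copies) presumes a *stable* background — most gene families sit at
  roughly one copy with little phylogenetic volatility, with copy-number
  variance concentrated in the focal families. A baseline near one copy
  with small log-scale variances is that regime; with a volatile
  background the screen's absolute thresholds stop being meaningful.
* the presence criterion (≥ 90% of in-group species with ≥ 1 copy) is
  zero-tolerance whenever the in-group holds fewer than ten species, so
  the fixture keeps categories near balance — comparable to real
  comparative panels, where the smallest trophic class still covers
  roughly a fifth to a third of species.

What passing tests on this fixture do **not** show: robustness to
annotation error, to orthology mis-assignment, to pseudogene inflation, or
to model misspecification — real copy numbers are not exactly Poisson
log-normal (an optional negative-binomial generator is the hook for such
robustness checks).

## The phylogenetic mixed model

The Poisson family is sampled by Metropolis-within-Gibbs (numba kernel):

* componentwise Gaussian random-walk updates for the phylogenetic effects
  u (using the maintained vector C⁻¹u so each site update is O(n)) and the
  observation-level residuals e;
* random-walk updates for intercept and slope with flat priors;
* conjugate inverse-gamma draws for both variance components; the
  univariate inverse-Wishart(V = 1, ν = 0.002) prior is the inverse-gamma
  (ν/2, νV/2), applied to σ²ₚ and σ²ₑ alike;
* four likelihood-invariant *translation* moves that shift a fixed effect
  and absorb the shift in u or e, leaving η unchanged and accepted on the
  prior ratio alone. These decorrelate (β, u) and are what makes the
  slope mix: without them the effective sample size for β on 64-tip
  problems drops by a factor of ~50.

Proposal steps adapt toward 20–40% acceptance during burn-in only, then
freeze, preserving detailed balance for the retained draws. The Gaussian
family is a pure Gibbs sampler (the latent field, fixed effects and
variances are all conjugate) and folds e into the residual variance.

Defaults follow the conventional long-chain settings for this model class
(1,050,000 iterations, 50,000 burn-in, thinning 200 → 5,000 retained
draws). Simulation studies in the tests use the reduced chain
55,000/5,000/10, which recovers a β of 1.2 within ±0.35 in ≥ 8/10 seeds
on 64-tip data and holds the null rejection rate of pMCMC < 0.05 near
0.05 across 200 null families on 32-tip trees; these problem sizes are
the package's chosen simulation scale. pMCMC is 2·min(P(β>0), P(β<0));
when all retained draws share a sign the chain's resolution bound 2/N is
reported and flagged (printed `<0.0004` for 5,000 draws). Bonferroni
adjustment is a reporting-layer multiplication by the test count.

Chosen where the model class leaves options open: fixed effects get
improper flat priors; the Poisson model includes an observation-level
residual (overdispersion) term; the category predictor is coded 1 for the
focal category and 0 for all others.

## Phylogenetic signal

**Pagel's λ** maximizes the Gaussian profile likelihood with analytically
profiled mean and scale, λ searched on [0, λ_max]. The profile is often
multimodal and can spike in a narrow window just inside the
positive-definiteness boundary, so the search uses a uniform 41-point scan
densified geometrically toward λ_max before local refinement. The LR test
against λ = 0 uses a χ²(1) reference despite the boundary, hence is
conservative.

**Blomberg's K** is the observed MSE₀/MSE ratio (GLS mean, C-weighted
error) over its Brownian expectation; K = 1 exactly on a star tree and
E[K] ≈ 1 under Brownian motion on any tree. Significance comes from
tip-label permutations, default 999, so the smallest attainable p is
0.001.

## Discriminant analysis

Two-class Fisher LDA from the closed form w ∝ S⁻¹(m_h − m_c) with the
pooled within-class covariance S; priors enter only the decision
threshold. DF scores are wᵀ(x − grand centroid), oriented so herbivores
score high (the orientation is a convention and is documented rather than
inferred). A singular pooled covariance — constant count columns happen —
gets a logged ridge of 1e-8·tr(S)/p.

Stepwise selection greedily adds the feature minimizing overall Wilks' λ
(det W / det(W+B)); a candidate enters only if its partial-F p-value,
F = (Λ_old/Λ_new − 1)(n − g − p)/(g − 1), is ≤ α_enter (default 0.2, the
customary default of stepwise discriminant routines). LOOCV refits
naively per fold and keeps the full-data priors in every fold, matching
the fixed-prior convention of the phylogenetic variant. Clade holdout
drops a named clade, refits, and predicts the held-out members.

**pFDA** follows the whiten-then-discriminate construction: rows of X and
the intercept are whitened by the inverse lower Cholesky factor of the
λ-scaled covariance of the ultrametric tree; the whitened intercept is
projected out of each feature (phylogenetic GLS centring); ordinary LDA
with *fixed* priors is fitted to the result. At λ = 0 on a unit-depth
tree the whitening is the identity and pFDA reproduces plain LDA exactly
— the regression test for the construction. The optimal λ minimizes
training misclassification over the grid 0–0.1 (step 0.01), ties to the
smallest λ. Training misclassification is a noisy selector when the
classes overlap appreciably; the λ* = 0 preference for phylogeny-free
labels is therefore only a stable property near the discriminant's error
floor, which is where the method is used in practice.

## Duplication modes

Two placed copies are a tandem pair when on the same chromosome with
start-to-start distance ≤ 5 Mb (inclusive; a gap-based distance is
available as an option). A family in a species is `tandem` when every
placed copy has only tandem relations, `interchromosomal` when no tandem
pair exists, `both` when a tandem pair coexists with a copy whose
relations are all non-tandem, and `ND` below two placed copies (copies on
unanchored contigs don't count). The aggregation from pairwise relations
to the single per-family label is a documented choice — the underlying
rule set is pairwise and the `both` semantics is isolated so it can be
swapped.

## Trophic levels

TL_i = 1 + Σⱼ DC_ij·TL_j / Σⱼ DC_ij with conventional prey levels
(primary producers 1, herbivorous 2, omnivorous 2.5, carnivorous 3);
proportions are used as weights and need not be normalized. A pure
primary-producer diet gives TL = 2 (the herbivore level) exactly.

## Pipeline

Stages chain as screen → comparative → discriminant → pFDA → duplication
→ trophic regression. The discriminant consumes the families significant
for herbivory/carnivory from the comparative table when present,
otherwise the screen's pass set. All stage seeds derive deterministically
from the master seed; every output carries a header with a hash of the
analysis settings (file paths excluded, so relocated runs hash alike),
and two runs with one config are byte-identical.

## Known limitations

* Only the two model shapes the pipeline needs (univariate Poisson and
  Gaussian response with one random effect) are implemented — this is not
  a general mixed-model engine.
* The χ²(1) reference for the λ test ignores the boundary at zero.
* Species matching is exact string equality; reconciliation of tip names
  against metadata is the caller's rename map.
* pFDA's internal construction is one defensible reading of
  whiten-then-discriminate; it is isolated behind `fit_pfda` precisely
  because other formulations exist.
* Two- and three-way discriminants beyond the herbivore/carnivore
  contrast, ROC analysis, and GO-style functional enrichment are out of
  scope.
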