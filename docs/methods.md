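# Methods

This note documents the models, the numerical choices, and the synthetic
data behind `songevo`, and what the test suite does and does not
establish about real data.

## Models

**Mk models.** A discrete learning-window state (binary stable/plastic
or ternary early/delayed/plastic) evolves by a continuous-time Markov
chain with generator Q (off-diagonals ≥ 0, zero row sums). ER constrains
all off-diagonal rates equal; SYM one rate per unordered pair; ARD one
per ordered pair. Likelihoods use Felsenstein pruning with per-node
rescaling; transition matrices exp(Qt) come from one eigendecomposition
of Q applied to all branch lengths (fallback to `scipy.linalg.expm` when
the eigenbasis is ill-conditioned). The root prior is uniform by default
and can be set to the fitted stationary distribution; this matters
little on trees whose depth is large relative to 1/rate. ER vs ARD is a
likelihood-ratio test with df = (#ARD rates − 1); for the binary state
that is df = 1.

**Stochastic character maps.** Node states are drawn from their joint
conditional distribution (root from prior-weighted conditionals, then
children given parents), and each branch path is sampled conditional on
its endpoints by uniformization: the number of candidate jumps is drawn
from the endpoint-conditioned Poisson mixture, jump times are uniform
order statistics, and the jump chain is bridged with cached powers of
R = I + Q/μ; self-jumps are merged. The jump-count series is truncated
at 200 terms, far beyond anything reachable at the rates involved.
Transition counts are segment-boundary counts; the minimum over an
ensemble is reported as the most parsimonious history, with the argmin
map's directed counts.

**Brownian rate models.** A continuous trait (always ln-transformed) has
tip covariance σ²C under one rate, where C holds shared root-to-tip path
lengths, or V = Σ_r σ²_r C_r under regime-painted rates, where C_r is
the shared path length spent in regime r according to one stochastic
map. The root state is profiled by GLS and σ² by its closed form
(1/n denominator), so only rate *ratios* are optimized numerically.
The ensemble ("Brownie") test fits the multi-rate model on every map in
the ensemble and refers 2·(mean LL_multi − LL_single) to chi-square with
df = regimes − 1; the single-rate likelihood does not depend on the
painting and is computed once. Nested groupings (three-rate vs two-rate)
are compared the same way with df = 1.

**Phylogenetic ANOVA.** The observed statistic is the classical one-way
F (it does not depend on the tree). The null distribution is F computed
on datasets simulated under single-rate BM on the tree, with σ² fitted
from the data; p uses the add-one estimator (1 + #{F_sim ≥ F_obs}) /
(n_sim + 1), so it is never exactly 0. Post-hoc pairwise comparisons use
Welch t statistics referred to the same simulated null (two-sided on
|t|) and are Holm-adjusted within the pairwise family.

**PGLS with Pagel's λ.** Residual correlation = phylogenetic correlation
with off-diagonals multiplied by λ. λ is profiled by ML on a 64-point
grid over [0, λ_max] refined by golden-section search, where
λ_max = 1/(1 − e_min) is the positive-definiteness bound (e_min the
smallest eigenvalue of the correlation matrix); λ is deliberately not
clamped at 1, and boundary optima are flagged. Slope standard errors use
the n−2-denominator variance; p is two-sided t with n − 2 df.

**Pagel's discrete test.** The joint chain on {(0,0),(0,1),(1,0),(1,1)}
has eight single-change rates; double transitions are structural zeros.
The independent model ties the four rate pairs; its maximum likelihood
is computed separably as two 2-state fits (exactly equivalent by the
product-chain identity, asserted in tests). The dependent model is
fitted by L-BFGS-B on log rates with a repair restart seeded from the
independent optimum whenever the nesting inequality is violated by the
optimizer. LR df = 4. A "run" is one random-restart fit from log-uniform
starting rates over [1e-3, 1e2] per unit mean tree depth — run-to-run
variability emulates repeated optimizer launches of the original
workflow. The threshold sweep binarizes the continuous trait at every
observed value with a strictly-greater "high" rule (so an observed
threshold never empties the low class); degenerate thresholds are
skipped. Bins are contiguous groups of the sorted unique thresholds;
remainders go to the lower bins (10 thresholds into 3 bins → 4/3/3).
Binned rate means carry a 1,000-resample percentile-bootstrap 95% CI;
the significance profile is the mean per-threshold percent of runs with
p < 0.05.

**Multiple testing.** Holm–Bonferroni: the i-th smallest of m p-values
is tested at α/(m − i + 1), stopping at the first failure. The
seven-trait family gives the ladder 0.0071, 0.0083, 0.01, 0.0125,
0.0167, 0.025, 0.05.

**Sister-pair rate scan.** For every cherry, the local rate proxy is the
squared standardized contrast (x₁ − x₂)²/(t₁ + t₂) and the size proxy
the pair mean; association is Spearman's ρ with a permutation p. The
choice of statistic is this package's design; other reasonable proxies
(absolute contrasts, BM-rescaled contrasts) differ only in power.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_maps` | 10,000 | maps for transition counting (ASR) |
| `n_maps_brownie` | 1,300 | maps per Brownie ensemble |
| `n_sim_anova` | 1,000 | BM simulations per phylANOVA |
| `runs_per_threshold` | 100 | Pagel runs per sweep threshold |
| `runs_binary` | 1,000 | Pagel runs for mating/EPP |
| `restarts` | 10 | multi-start count for Mk fits |
| `n_bins` | 3 | sweep summary bins (2–5) |

`--fast` switches to 100 / 100 / 200 / 10 / 50 / 5 — the profile used by
the test suite. Jackknife re-runs reduce sweep repetitions to 20.
Stage-level seeds derive from the master seed by stable hashing of stage
names, so adding a stage never perturbs another stage's draws and every
output is bit-reproducible.

## Synthetic data

The generator emulates the shape of the study data: 67 species in 24
families (families are clades cut at the shallowest depth with ≥ 24
crossing lineages) on a Yule tree rescaled to unit root-to-tip depth.
The binary learning state evolves under ER with rate 0.7 per unit depth,
which yields on the order of a dozen state changes per tree. Ternary
codings subdivide stable species at random (35% early, the rest
delayed; 8 species left uncoded), with continuous years uniform [0.5, 1]
for early, 1.33 for delayed, 2.0 for plastic. The seven song traits are
regime-BM on the true learning history with equal σ² = 0.5 in both
states and state offsets equal to the observed group means of each
ln trait (e.g. 1.8807 stable vs 3.946 plastic for ln syllable
repertoire), so group-mean structure is planted without any rate
difference. Per-study raw values jitter the true value lognormally
(sd 0.15, 1–3 studies per trait) so median/min/max aggregation modes
genuinely differ. Duration and interval are emitted raw, so the derived
rate and continuity identities hold exactly by construction. The mating
trait switches with gain/loss rates 0.3 in stable and 3.0 in plastic
lineages (planting elevated mating-system turnover under plasticity, as
a dependent chain in which the learning state is unaffected by mating);
EPP switches state-independently at 0.5. Missingness mirrors the
study's per-trait coverage (10 species without mating data, 26 without
EPP, 22 without duration/interval, etc.), removed at random.

What the generator does **not** emulate: real family taxonomy or
topology; phylogenetic clustering of the early/delayed subdivision
(available as a configurable mode only in the sense that the proportions
are configurable); observation error structure beyond lognormal
study-to-study spread; and — importantly — group-mean differences that
are *phylogenetically clustered* rather than tied deterministically to
the tip state. The last point has a concrete consequence: because a
state offset moves a lineage's value whenever its state changes, the
offset contributes variance concentrated on state-transition branches,
and the two-rate Brownie test correctly detects it. A dataset built this
way therefore cannot simultaneously show a large group difference and a
null two-rate test, whereas real data can (there, the group difference
accumulates within a few deep clades). Passing planted-structure tests
on this generator shows the pipeline detects what was planted; it does
not certify behavior under every covariance structure real data can
have.

## Calibration behavior

Measured at the scaled designs used in the tests (one CPU):

* phylANOVA type-I error is nominal (≈ 0.04–0.05 at 50 tips, 200 null
  simulations).
* The Brownie ensemble test is *conservative*: averaging per-map
  two-rate log-likelihoods shrinks the statistic's upper tail relative
  to chi-square(1) (null mean statistic ≈ 0.7 instead of 1), giving
  type-I ≈ 0.02–0.05 at 100 tips with 100 maps. This is a property of
  the mean-log-likelihood comparison itself, not of the optimizer.
* The Pagel LR test is slightly *liberal* at 100 tips (type-I ≈ 0.08;
  the chi-square(4) reference is an asymptotic approximation) and is
  nominal (≈ 0.05) by 300 tips.

## Degenerate inputs and tie-breaks

Polytomies are resolved deterministically (children ordered by smallest
descendant tip label) into zero-length binary nodes; all likelihoods are
invariant to this. Zero-likelihood tip configurations return −inf rather
than raising. Constant traits push σ̂² (or the Mk rate) to the boundary
and are flagged. Regimes with zero mapped branch length are dropped with
a warning. Degenerate sweep thresholds are skipped, not errors. Missing
values are explicit markers; every analysis subsets complete rows rather
than imputing (the one documented exception: a species whose song
repertoire is exactly 1 inherits its syllables-per-song as syllable
repertoire, flagged as imputed).

## Problem sizes in the test suite

Oracle tests enumerate ≤ 6-tip trees exactly. Calibration studies use
500 replicates at 50 tips (phylANOVA) and 200 replicates at 100 tips
(Brownie with 100-map ensembles; Pagel). Recovery studies use 50
replicates at 200 tips. The planted-structure end-to-end tests run the
67-species default generator with 100-map ensembles and a 2-run-per-
threshold sweep. These sizes are the package's chosen test profile; the
library defaults above are the full-scale settings.
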