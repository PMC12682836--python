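# Methods

This note documents the statistical machinery in `mnminer`: the models, the
defaults and why they are what they are, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Reference framework and relative leaf [Mn]

Leaf [Mn] is a usable proxy for root carboxylate exudation only relative to
co-occurring reference species, because absolute leaf [Mn] tracks soil and
climate as much as root physiology. Each site therefore needs a positive
reference (a known exuder) and a negative reference (a known non-exuder, or
young leaves, which have not yet accumulated Mn).

Resolution rules, in order:

1. Observed references at the site are used directly. Several reference
   species of the same polarity are pooled (provenance `grouped`).
2. An all-young-leaf negative reference is flagged `young_leaf`.
3. A site with no observed reference of one polarity receives the
   cross-site fallback (`site_average`, the APR/ANR convention): the
   *site-level mean* of every other site's references of that polarity, one
   pseudo-replicate per contributing site. Using site means rather than all
   other-site individuals is a deliberate choice — the replicate set stays
   comparable in size to a real reference sample, and a Welch test against
   it remains defined — and every downstream row carries the provenance
   flag so users can exclude such sites.

Resolution is deterministic in the input set: rows are sorted internally so
row order never changes the result.

The relative score is linear normalisation between the reference means:
`relative [Mn] = 100·(target − neg)/(pos − neg)` percent. It is 0 at the
negative reference, 100 at the positive, unbounded on both sides (strong
exuders routinely exceed 100 %), invariant to common rescaling of all three
inputs, and computed from *species-mean* Mn (replicate-level relative
scores are not produced — the classifier works on replicates, the score on
means). Reference means closer than `1e-9·max(|pos|, |neg|, 1)` raise a
degenerate-reference error rather than silently dropping the site; the
tolerance is a numerical guard, not a biological threshold.

## Exudation calls

`welch_t` implements Welch's unequal-variance t-test from first principles:
`t = (x̄ − ȳ)/√(s²x/nx + s²y/ny)` with Welch–Satterthwaite degrees of
freedom and a two-sided Student-t p-value. Degenerate corners have fixed
conventions: both variances zero with equal means gives t = 0, p = 1;
with unequal means, an infinite t and p = 0, flagged and logged.

The call rubric, per target species × site:

- **exudes** — significantly higher leaf [Mn] than the negative reference:
  two-sided test at `alpha` (default 0.05) *and* a positive mean
  difference. A one-sided option is exposed; two-sided-plus-direction is
  the default because it is the more conservative reading of
  "significantly higher".
- **strong capacity** — leaf [Mn] similar to or significantly higher than
  the positive reference, operationalised as target mean ≥ positive mean
  OR a significant positive difference. "Similar" has no test attached in
  the field convention; the mean-threshold reading is explicit here and
  recorded in output metadata.

No multiple-testing correction is applied by default (per-site screening
calls are the point of the design); a Holm option over the vs-negative
p-values is available. The genus summary counts each species once, as an
exuder if any site-level call is positive — the per-site table remains the
primary output.

Calibration, checked by simulation in the acceptance suite: with target and
negative reference drawn from the same lognormal (n = 5 each), the exudes
rate is one tail of the two-sided test, ≈ 0.02–0.03 at alpha = 0.05
(slightly below alpha/2 because the t-test is conservative in the upper
tail under lognormal skew); with a e² ≈ 7.4-fold Mn effect the sensitivity
is ≈ 1.

## Group-means GLS with AICc selection

Site/species comparisons of leaf nutrients use a one-way group-means model
fitted by maximum likelihood under three candidate variance structures:

- `constant` — one σ² (k = g + 1 parameters);
- `per_group` — σ²_g per group (k = 2g);
- `power_of_mean` — Var = σ²·|μ_g|^(2δ) (k = g + 2), the standard
  variance-increases-with-mean family for concentration data.

Because the model is saturated (one mean per group), the GLS fitted means
equal the group sample means under any within-group-constant weighting, so
the likelihood profiles analytically over everything except δ, which is
optimised on [−10, 10] by bounded scalar minimisation.

Model selection is by AICc, `−2ℓ + 2k + 2k(k+1)/(n−k−1)`, with the
conventional parsimony band: among candidates within 2 AICc units of the
minimum — differences the AICc scale treats as effectively equivalent —
the fewest parameters win. The band matters: strict lowest-AICc lets an
extra identifiable variance parameter beat the true constant-variance model
with asymptotic probability P(χ²₁ > ~2.2) ≈ 0.13, capping recovery of the
homoscedastic truth near 80–85 %; with the band, recovery is ≥ 90 % in both
directions (verified by simulation at n = 30 per group). `parsimony_margin=0`
restores strict lowest-AICc.

Post-hoc pairwise comparisons use the studentized-range criterion. Under
constant variance this is exactly Tukey HSD (checked against an independent
implementation and the tabulated critical value q₀.₀₅;₃,₂₇ = 3.506); under
the heteroscedastic structures, standard errors come from the fitted group
variances with Welch–Satterthwaite df (Games–Howell). The compact letter
display uses insert-and-absorb: groups sharing a letter are not
significantly different at alpha.

## PCA diagnostics and correlations

PCA is a spectral decomposition of the correlation matrix (listwise
deletion, dropped rows counted and logged). Sampling adequacy follows the
usual gates, reported not enforced: KMO = Σr²ᵢⱼ/(Σr²ᵢⱼ + Σq²ᵢⱼ) over i≠j,
with q the anti-image partial correlations from the inverted correlation
matrix (≈ 0.5 for uncorrelated data, > 0.6 conventionally adequate), and
Bartlett's sphericity χ² = −(n−1−(2v+5)/6)·ln det R on v(v−1)/2 df. A
numerically singular R leaves KMO as NaN with a warning; the PCA itself is
still returned.

Pearson correlation matrices are computed after a natural-log transform
(concentrations are positive and right-skewed; r is invariant to the log
base), with two-sided t-based p-values and hard errors on non-positive
values naming the offending rows.

Leaf N:P uses the mass-basis ratio with the strict ratio > 20 flag for
phosphorus limitation.

## Comparative methods

All tree methods run on the Brownian covariance matrix **V**, with
V[i,j] the shared root-to-MRCA path length of tips i and j, built in a
single postorder pass and verified exactly against a brute-force
root-path-intersection oracle. Inversion is by Cholesky factorisation; a
singular V (zero-length branches) receives a jitter of 1e-12 × tree depth
on the diagonal, with a logged warning. Trees are used as given —
ultrametricity is reported, never enforced, and there is no re-dating.

**Blomberg's K.** With â the phylogenetic (GLS root) mean,
MSE0 = (y−â)ᵀ(y−â)/(n−1), MSE = (y−â)ᵀV⁻¹(y−â)/(n−1), and
K = (MSE0/MSE) / {[tr V − n/(1ᵀV⁻¹1)]/(n−1)}. K = 1 is the Brownian
expectation; K < 1, weaker-than-Brownian signal. Significance comes from a
randomisation test: trait values are shuffled across tips (default
n_perm = 10 000, fully vectorised) and the upper-tail frequency of
variance ratios ≥ observed is reported with the +1 correction, so
p ∈ [1/(n_perm+1), 1] and is exactly reproducible given the seed. The
implementation matches an exact symbolic evaluation on a 4-tip tree to
1e-10 and an independent R implementation (phytools `phylosig`) to 1e-13;
under Brownian simulation on 50-tip trees the mean K is ≈ 0.96–1.01 and
the test's size under the shuffle null is ≈ 0.04–0.06 at alpha 0.05.

**Ancestral states.** ML states under Brownian motion are the GLS
conditional expectations given the tips: the root equals â, and node i
gets â + Cov(nodeᵢ, tips)V⁻¹(y − â). Along a branch the conditional
expectation is linear between endpoint states, which is what the exported
interpolation provides. Verified against a brute-force multivariate-normal
conditioning oracle built from an independently enumerated joint
tips-plus-nodes covariance.

**PGLS.** β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with an intercept column, σ̂² from the
V-weighted residual sum of squares on n − 2 df, and two-sided t tests.
On a star tree V = I and the fit reproduces OLS to 1e-10. Brownian motion
is the only correlation model; Pagel's λ and OU transformations are out of
scope.

**Tip-rate tests.** Speciation tip rates are consumed as a per-tip table
(their estimation — e.g. reversible-jump MCMC over diversification
regimes — is an external analysis, deliberately not reimplemented; the
simulator provides trait-linked rates for testing). Rates are natural-log
transformed; Spearman's rho is rank-based (so the transform is cosmetic
there) with an exact permutation p for n ≤ 9 and the t-approximation
otherwise, and the PGLS arm regresses log rate on the trait. Traits for
signal analyses require complete data — a missing tip raises rather than
imputes; prune the tree first.

## Synthetic data

`gen_survey` emulates the survey design the pipeline targets: 18 sites by
default, one positive and one negative reference species per site, 1–6
target species per site at 5 replicates, all element concentrations
lognormal (sdlog 0.25, a ~25 % within-species CV typical of leaf trace
elements), a shared multiplicative site-fertility effect (sdlog 0.15), and
Mn levels at field magnitudes — negative references ~40, positive ~300,
exuders ~1000 mg kg⁻¹. Two sites lose their positive and two their
negative reference to exercise the APR/ANR fallback. Leaf N and P are
bivariate lognormal with log-scale correlation 0.8 around means of
10.6 mg g⁻¹ and 0.4 mg g⁻¹, so N:P ratios and correlation analyses have
realistic structure; soil records are acidic (pH CaCl₂ 3.4–4.9) with
gamma-distributed low P. What it does **not** emulate: spatial structure
within sites, soil–plant feedbacks, covariance between Mn and the other
elements, species shared across sites with correlated means, or
measurement censoring — so passing tests demonstrate the statistics are
correct and calibrated at the stated design, not that field data will be
this clean.

`gen_tree_traits_rates` grows a pure-birth (Yule) tree by exponential
waiting times, simulates a Brownian trait by root-to-tip accumulation
(σ² = 1 per unit length by default), and sets
log rate = a + slope·trait + N(0, sd), defaults slope −1, sd 0.1 —
a recoverable negative rate–trait link. Every artifact draws from its own
RNG stream spawned from the master seed, so adding a stage never perturbs
earlier outputs and a fixed seed reproduces files byte for byte.

## Problem sizes and determinism

Simulation-based checks use: 10 000 replicates for the classifier type-I
rate; 200 six-site surveys for power; 500 trees of 50 tips for the mean-K
calibration and 500 shuffles × 999 permutations for the randomisation-test
size; 200 replicates per direction at n = 30/group for variance-structure
recovery. These sizes put the Monte-Carlo error well inside each check's
tolerance band. All stochastic code takes explicit seeds
(`numpy.random.default_rng`); permutation p-values with equal seeds agree
exactly.

## Known limitations

- The exudation call is a proxy inference: elevated leaf [Mn] can also
  reflect facilitation by exuding neighbours, redox microsites or
  transporter variation. The rubric is honest about this — it claims
  evidence of exudation, not measurement of it.
- APR/ANR fallback sites inherit cross-site reference variance; their
  calls are flagged and best treated as lower confidence.
- The power-of-mean variance structure is undefined for a zero group mean
  (that candidate is skipped with a warning).
- Blomberg's K assumes complete trait data on the pruned tree and a rooted
  tree with branch lengths; polytomies are handled naturally by the
  covariance construction.
- The exact Spearman permutation p enumerates n! pairings and is limited
  to n ≤ 9 by default.
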