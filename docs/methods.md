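# Methods

## Scope and model

The package implements a five-stage analysis linking soil microbiome
divergence to field overyielding, plus a theoretical screen:

1. **Dissimilarity.**  Feature-count (ASV × sample) tables are rarefied to
   the minimum library size (single seeded draw without replacement, a
   multivariate hypergeometric sample per library), restricted to the
   putative plant-pathogen guild (union of primary and secondary lifestyle
   labels), and collapsed to species × species Bray–Curtis matrices
   (Σ|a−b|/Σ(a+b)); the species-pair value is the arithmetic mean over all
   cross pairs of replicate samples.  This aggregation is order-free and
   unbiased; geometric or median alternatives change little and are not
   exposed.
2. **Greenhouse feedback.**  Log total (shoot + root) dry biomass is fitted
   with cell-means coding — one indicator per observed plant × inoculum
   cell — plus one centered seedling-height slope per plant species, so each
   cell coefficient is the adjusted mean at that species' own mean height
   (shifting all heights by a constant provably leaves every feedback
   unchanged).  Sterile controls are excluded from the feedback cells.
   The pairwise statistic is the four-cell log contrast; its variance sums
   Var/(N·mean²) over the four *distinct* cells (α_A, β_B, α_B, β_A) with
   the conspecific N replaced by 1 (nine conspecific replicates shared by
   nine feedback estimates).  Performance defaults to total biomass and is
   configurable to shoot-only.
3. **Pooling.**  Group and overall summaries use closed-form
   DerSimonian–Laird random effects with normal-quantile 95% intervals (no
   small-k t correction).  This is a deliberate approximation to a
   multivariate REML fit with a pair random effect; a unit test
   cross-checks the estimate and τ² against an independent implementation.
4. **Predictor.**  Exhaustive main-effects subsets (no interactions) over
   the 11 candidate dissimilarity groups, Gaussian-likelihood
   AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with the additive constant
   dropped (common to all models, so Δ values are exact); Akaike weights,
   importance = summed weight, importance cutoff 0.7.  The final predictor
   takes slopes from the best model restricted to the configured predictor
   set (default: the three pathogen groups; lower-ranked predictors are
   never forced in even when their importance clears 0.7) and the
   weight-averaged intercept.  A perfect fit (RSS = 0) is floored at
   numerical zero so AICc stays finite and ordered.
5. **Field effects.**  ΔRY_i = B_i,mix/M_i − 1/N with the expected relative
   yield 1/N (equal planting proportions; the design does not vary them).
   SE uses the population covariance, which makes CE + SE equal the net
   effect identically — the definitional property of the partition.
   Species harvested at zero stay in with RY = 0.  M_i is the global mean
   over that species' monoculture plots (four in the design).  Plot scores
   use realized biomass proportions; the plot PSF sums unordered pairs
   (i < j) without a factor 2 — an `ordered_pairs` switch doubles it for
   sensitivity, changing regressions only by a constant factor.

**Feedback model.**  Replicator dynamics on the simplex with fitness
w = σP.  σ_ij = σ_ji = w_mono − PSF_ij/2 with w_mono = PSF(d = 1)/2: the
feedback recovered from σ equals the predicted pairwise PSF exactly, the
heterospecific baseline for a fully dissimilar pair is zero, and conspecific
effects are equal across species.  Dissimilarities are symmetric, so no
information supports an asymmetric split; the constructor accepts arbitrary
σ for sensitivity work.  Because adding a constant to σ leaves the
dynamics' equilibria, stability and complementarity invariant (verified
numerically and by test), the zero baseline is purely a reproducibility
convention.

Equilibria come from Cramer's rule (column i of σ replaced by ones; column
replacement is forced by the derivation σP = ŵ1) and are cross-checked
against the direct linear solve; feasibility requires every frequency in
(ε, 1−ε) with ε = 1e−9.  Stability is the dominant eigenvalue of the
analytic Jacobian of the reduced (N−1)-dimensional system (threshold
−1e−9); a finite-difference Jacobian is retained as a test oracle only.
Community-level feedback I_c is the dominant eigenvalue of the symmetrized
σ restricted to the zero-sum tangent space (orthonormal Helmert basis).
This definition is pinned by its N = 2 reduction — sign(I_c) equals the
sign of the pairwise feedback — and, for symmetric σ, coincides with the
stability criterion, so feasible communities with I_c < 0 are stable and
overyield (mean fitness is maximized at the interior equilibrium).  Model
complementarity is N·(ŵ − w_mono).  The ODE integrator works in reduced
coordinates (last frequency substituted), so trajectories stay on the
simplex exactly; the full-coordinate replicator flow is only neutrally
stable to off-simplex drift when ŵ < 0, which an earlier full-coordinate
implementation exposed.

The screen enumerates all 2^18 − 19 = 262,125 subsets of size ≥ 2
(deterministic order, guard at pool size 22) and is vectorized per richness
with batched solves and eigendecompositions; the full enumeration runs in a
few seconds on one CPU.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study designs at the combinatorial level and
the statistical structure the analysis assumes; its defaults are the
study conditions used by every test.

- **Pool and pairing.**  3 families × 6 species.  Partner graphs are fixed
  circulant constructions (within-family offsets {1,3,5}; between families
  species k meets k, k+1, k+2), not random: the printed counts (81 pairs,
  9 within / 18 between per combination) are then deterministic.  Which
  particular partners were used in the original assays is not derivable
  from counts alone; any symmetric 3-regular choice reproduces them.
- **Dissimilarities.**  Family-block means with Gaussian jitter
  (sd 0.08), clipped to [0,1].  The base pattern is solved through the
  linear predictor from the published group-level feedback ranges:
  legume-like pairs (F2|F2, mean 0.20) least dissimilar — limited pathogen
  specialization among legumes — composite-like pairs most (F3|F3 0.51,
  F1|F3 0.54).  Each pathogen group gets a distinct ±0.08/∓0.04 offset
  pattern so the three predictors are statistically separable; the eight
  nuisance groups are flat at 0.5.
- **True feedback** is the three-group linear predictor evaluated on the
  simulated dissimilarities plus Gaussian noise (sd 0.4, the scatter scale
  of the pair-level regression).
- **Greenhouse.**  Cell mean for plant i in soil j is b_i − PSF_ij/2
  (species baseline b_i ~ logNormal), which makes the feedback statistic on
  noiseless cell means return the truth to machine precision — a
  construction identity the tests exploit.  Heights ~ N(5 cm, 1), covariate
  slope 0.05 log-units/cm, pot noise sd 0.3 on the log scale, sterile
  bonus +0.25.
- **Field.**  Monoculture means rise linearly from 225 to 375 g m⁻²
  across species (base 300).  Mixture yield per species is
  (M_i/N)(1 + g·dilution) with dilution computed from the true feedbacks at
  equal planted proportions and gain g = 1 — so overyielding is pathogen
  dilution by construction, and with the gain at zero every ΔRY, CE and SE
  vanish and RYT = 1 exactly.  Biomass noise is lognormal (cv 0.15),
  matching the log-transform used downstream; cover is an affine
  species-specific function of biomass plus noise (sd 1.5) to exercise the
  cover→biomass calibration.  Precipitation is generated as a label and
  never used.
- **Reads.**  Two monoculture samples per species (paired plots of matched
  composition pooled).  Compositions are hierarchical mixtures of a global
  block, a family block and a steep species-private block, with the
  within-family shared mass set to one minus the target dissimilarity —
  within-family Bray–Curtis is exact in the noise-free limit; cross-family
  values are monotone in the configured overlap but only approximate
  (the global-mass construction can only realize the pairwise minimum),
  which is why the pipeline's predictor stage consumes the directly
  simulated matrices and the sequencing route serves as a validated
  parallel path.  Mixture samples average the member compositions, so each
  species' dominant private pathogen is diluted by exactly 1/N, and the
  dilution signature (change in its relative abundance, ties broken by
  smallest feature id) decreases with richness by construction.

Passing tests on these data therefore demonstrate correctness of the
estimators and the internal consistency of the causal chain — not that real
communities satisfy the generator's assumptions (no spatial structure, no
block or precipitation effects, no compositional overdispersion beyond
multinomial sampling, equal conspecific effects).

## Problem sizes and determinism

Simulation-based checks use the design sizes of the study (81 pairs, 168
mixtures, 262,125 communities) and 20-seed replicate batteries for the
recovery properties; the complete pipeline runs in well under a minute, and
the acceptance battery enumerates the full 18-species pool.  Every
stochastic step draws from a generator seeded by (seed, purpose-tag), so
runs are byte-identical under a fixed seed and stages are reproducible in
isolation.

## Known limitations

- DerSimonian–Laird ignores the sharing of conspecific cells across pairs
  beyond the variance down-weighting; a multivariate model with an explicit
  covariance would be more faithful at extra complexity.
- The community-feedback eigenvalue definition for N > 2 is one natural
  generalization of the pairwise sign criterion; published counts of
  passing communities depend on the exact form chosen, so the screen's
  absolute counts are not comparable across definitions (the qualitative
  richness–complementarity shape is).
- The best-model slope convention for the final predictor can fail when a
  configured predictor drops out of the AICc-best model under weak signal;
  the pipeline then falls back to the exact-subset fit and logs it.
- Field plot scores assume realized biomass proportions measure density;
  cover-based biomass is a calibrated proxy with species-specific error.
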