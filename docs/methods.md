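# Methods

## The model

The package analyses binary site-by-species incidence matrices from
depth-gradient surveys. The core question is which idealized
metacommunity geometry best describes the arrangement of species ranges
along the dominant latent gradient, and — with two survey periods —
whether individual species have moved their depth limits between them.

### Ordination

Sites and species are scored on the first non-trivial correspondence
analysis axis (reciprocal averaging, RA). The axis is extracted by SVD of
the chi-square standardized residual matrix
S = D_r^{-1/2} (P − r c^T) D_c^{-1/2}; row/column standard coordinates are
u/√r and v/√c. The classical alternating-averaging iteration is retained
as an independent cross-check and must agree with the SVD route to 1e−8
after sign/scale alignment (iteration tolerance 1e−13, max 10,000 sweeps;
the successive-change criterion under-estimates the distance to the fixed
point when the first two eigenvalues are close, hence the conservative
tolerance). Verified numerically against vegan's `cca` on a fixed matrix.

CA scores are defined only up to sign. Two conventions make output
deterministic: when depths are available the axis is oriented so the
score–depth correlation is non-negative (the reported r is therefore
|r| with its unchanged two-sided p); otherwise the first non-empty site
scores no higher than the last. Empty sites (possible in null matrices)
score 0 — the weighted mean of the centered axis — and sort stably.
Matrices of rank < 2 (e.g. all cells 1) have no non-trivial axis and are
signaled as degenerate.

### The three elements

On the RA-ordered matrix:

- **Coherence** counts *embedded absences*: zeros strictly between the
  first and last presence of each species down the site order, plus the
  same count within each site across the species order. Counting both
  directions matches the behavior of the widely used reference
  implementation of this analysis; a column-only variant is available
  via `embedded_absences(m, rows=False)`.
- **Turnover** first fills each species' range (every cell between first
  and last presence set to 1), then sums over unordered species pairs the
  product of the two exclusive-site counts ("replacements").
- **Boundary clumping** tallies each species' two range endpoints
  (a single-site range counts its site twice) per site and computes
  Morisita's index I = Q Σ f_i(f_i−1) / (F(F−1)). The test statistic is
  χ² = I(F−1) + Q − F, referred to a chi-square with df = Q − 3 by
  default — the convention used in the survey-analysis tradition this
  package serves — with the conventional Q − 1 available via
  `df_offset=1`. I > 1 is
  tested in the right tail (clumping), I < 1 in the left
  (hyperdispersion).

### The r1 null model

Coherence and turnover are tested against a fixed-proportional null:
every null matrix keeps each site's observed richness exactly, and within
a site the occupied species are a weighted sample without replacement
with weights proportional to observed species prevalence. Sampling uses
exponential-key (Efraimidis–Spirakis) top-k selection, which is
distributionally identical to sequential proportional draws; tests check
it against exact enumeration of inclusion probabilities. Empty sites stay
empty ("zero rows allowed"). Each null matrix is **re-ordinated by RA
before its metrics are evaluated** — the observed ordering is itself an
optimization, so scoring nulls in the observed order would bias the null
distribution. Defaults: 1,000 nulls, one root seed, every run
reproducible bit-for-bit.

Significance uses the normal approximation z = (obs − mean)/SD with
two-tailed p. A parametric p permits values below 1/n_sim and is the
convention this analysis tradition reports; empirical-rank p-values are
deliberately not used. Zero null variance is flagged degenerate (p = 1 if
obs equals the mean, else 0).

**A calibration caveat**: the r1 null amplifies column-marginal
heterogeneity relative to an i.i.d. Bernoulli process with the same
expected fill (we verified the same behavior in vegan's r1 sampler).
I.i.d. 30 × 60 matrices at fill 0.3 sit ≈ 1.3 SD above the coherence null
on average and are rejected toward Checkerboard in roughly a quarter of
cases at α = 0.05. Even data generated from the r1 null itself retain a
mild positive bias (mean z ≈ +0.9, ≈ 12% two-sided rejections) because
the null weights must be re-estimated from the data's own over-dispersed
realized marginals. The z-test against this null is therefore somewhat
anti-conservative by construction; users should read "Random" as
"indistinguishable from the r1 null", not "i.i.d.", and treat marginal
coherence p-values with care.

### Classification

The decision tree: significantly *more* embedded absences than null →
Checkerboard; non-significant coherence → Random; significantly *fewer* →
branch on turnover. Significant turnover: fewer replacements → Nested,
more → Clementsian / Gleasonian / EvenlySpaced as boundaries are clumped
(I > 1, significant) / indistinguishable from random / hyperdispersed
(I < 1, significant). Non-significant turnover yields the Quasi- variants
by the sign of the replacement deviation; Nested and Quasi-Nested labels
carry the clumping subtype. α = 0.05, two-tailed, no multiplicity
correction. The tree is total and deterministic (property-tested over the
full significance/direction space).

One documented edge: a matrix with significant coherence, replacements
*above* the null mean but non-significant, and significant clumping falls
in the tree's Quasi-Clementsian cell, although analysts have sometimes
read such outcomes as "Quasi-nested/Random" when the biological context
suggests broad overlapping ranges. The classifier follows the tree; the
per-metric results are always reported alongside the label so such cases
can be judged directly.

## Subsampling robustness and rarefaction

`permutation_study` draws n_perm uniform k-site subsets (default k = 19,
n_perm = 600), reruns the full EMS classification and the axis–depth
correlation on each, and tallies labels, correlations significant at
p < 0.001, correlations with |r| > 0.80, and distinct-species richness
overall and per group. Subsampling is uniform over sites, not
depth-stratified: the point of the study is precisely to let the depth
profile of the subsample vary. Degenerate subsamples are recorded under a
"degenerate" label, never silently redrawn, so frequencies are over
exactly n_perm draws. Inner EMS runs default to 1,000 nulls and are
configurable downward. Rarefied richness from the same machinery is
checked against the hypergeometric closed form
E[S_k] = Σ_j [1 − C(n−n_j, k)/C(n, k)].

## Depth-shift accounting

A species' *maximal depth of occurrence* is the depth of its deepest
occupied site (optionally capped at a reporting floor, default 79 m —
reporting only; zone logic always uses uncapped values). For species
present in both periods, Δ = max_recent − max_old defines the category
(decrease / increase / unchanged; "unchanged" means exactly Δ = 0 on
recorded site depths — no tolerance). The within-category test is a
paired Student's t on the per-species (old, recent) depth pairs with
df = n − 1, computed on old − recent so a decreasing category gives
positive t; a two-sample Welch variant is available via `paired=False`.

Fishing-pressure zones split the gradient at 30 m (LFP shallow, HFP
deep). The boundary depth itself is assigned to HFP by default — the
zones are conventionally labelled 19–30 m and 30–80 m with the boundary
shared — with an open-boundary option. Transitions (HFP→LFP, stay-HFP,
LFP→HFP, stay-LFP) partition the shared species; percentages sum to 100.

## Synthetic generators

`gen_structure` builds noise-free idealized matrices: nested (species
occupy prefixes of a richness-ordered site list — a perfect subset
chain), clementsian (contiguous non-overlapping site blocks), gleasonian
(contiguous ranges, independent midpoints/widths), evenly spaced
(contiguous ranges with maximally spread starts), checkerboard
(complementary random site sets within species pairs), random (i.i.d.
Bernoulli). Noise is a symmetric per-cell bit flip — the simplest
one-knob perturbation.

`gen_survey` emulates a two-period soft-bottom survey on a 19–80 m
gradient: uniform site depths (an optional deep-biased profile mimics
dense historical surveys), contiguous per-species depth niches (uniform
midpoint; width uniform on 20–61 m, reflecting surveys where many ranges
span much of the gradient), Bernoulli occupancy within range
(default 0.95 — site records that pool several grab replicates detect a
resident species with high probability), and a trait-weighted draw
without replacement of round(shift_fraction × S) species (default
fraction 0.33) whose deep range limit contracts by a truncated-normal
draw (mean 20 m, SD 5 m, floored at 1 m and at the range's shallow
limit). Large or (semi)emergent species carry `trait_effect` (default 4)
times the odds of being drawn. The emitted truth is the *realized*
shifted set and contractions — truncation at range bounds makes the
realized mean contraction ≈ 19 m for the nominal 20 — and recovery tests
compare estimates to that truth.

What the generator does **not** emulate: abundance, spatial
autocorrelation beyond the shared gradient, gear differences between
periods, taxonomic drift (harmonization is exercised with synthetic
synonym tables instead), and the very sparse occupancy of real historical
matrices. Passing recovery tests therefore demonstrates correctness of
the estimators under a clean niche model, not robustness to every
field-data pathology.

## Problem sizes and numerical choices

Recovery experiments run 20 generator seeds at 30 sites × 60 species with
300 nulls per EMS run; the subsampling study in the acceptance script
uses 120 draws of 19 sites with 199 inner nulls on a 40-site survey.
These sizes keep Monte-Carlo error small relative to the quantities
reported (recovery percentages in steps of 5, null means estimated to a
few percent) while the full acceptance run stays around a minute.
Tie-breaks are stable sorts on input order everywhere; all RNG flows from
one root seed through derived substreams.

## Known limitations

- Only the first RA axis is used; no detrended or constrained ordination.
- Only the r1 null ships (the interface admits other fill rules).
- Classification inherits the r1/i.i.d. calibration caveat above.
- Site-level records are assumed pre-pooled (one binary vector per site
  per period); replicate-level pooling is out of scope.
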