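# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mitodiv`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Diversity estimation (`seq_diversity`)

Per-species alignments of mitochondrial protein-coding sequence are
analysed codon-by-codon under NCBI translation table 2 (vertebrate
mitochondrial: AGA/AGG are stops, ATA is Met, TGA is Trp). Site and
difference counting follows Nei & Gojobori (1986):

- each codon contributes fractional synonymous sites equal to the
  fraction of its nine single-nucleotide neighbours that preserve the
  amino acid, summed per position; changes to stop codons count as
  nonsynonymous, so `syn + nonsyn = 3` exactly for every coding codon;
- codon pairs differing at k > 1 positions are resolved by averaging the
  per-step classification over all k! orderings whose intermediate
  codons avoid stops. For the rare pairs in which every ordering passes
  through a stop, all orderings are used with the stop treated as a 21st
  amino-acid state (steps into or out of it are nonsynonymous);
- codons containing gaps, ambiguity codes or stops in either sequence of
  a pair are excluded pairwise, from both the difference and the site
  totals — not listwise, which would discard usable data;
- `piS` is the mean over all n(n-1)/2 sequence pairs of synonymous
  differences per synonymous site; `piN` analogously. No multiple-hit
  correction is applied within species: diversities are far below
  saturation, and corrections are reserved for between-species
  divergence.

`piN/piS` is undefined when `piS = 0`; such species are excluded from
ratio analyses and logged. Species with fewer than four sequenced
individuals are excluded up front (the inclusion rule of the emulated
study design). Pairwise comparisons run through a precomputed 60x60
codon-pair lookup table; tests validate the table against brute-force
pathway enumeration.

## Phylogenetic machinery (`comparative`)

Newick input goes through dendropy with underscores preserved.
Polytomies are resolved arbitrarily into zero-length binary branches
(contrasts require a binary tree; zero-length internal branches are the
standard representation of soft polytomies). Missing branch lengths are
an error — the contrast variances are meaningless without them.

Independent contrasts follow Felsenstein's pruning: at each internal
node the contrast is `(x1 - x2)/sqrt(v1 + v2)`, the ancestral value is
the precision-weighted mean, and the parent branch is extended by
`v1*v2/(v1 + v2)`; a tree with n tips yields exactly n - 1 contrasts.
Tips lacking a trait are pruned per analysis, so the n of each pairwise
analysis follows the missing-data pattern. Under log transformation,
non-positive values are dropped with a warning. Both sister branches of
zero length is an error (the expected variance vanishes).

Pagel's lambda multiplies the off-diagonal entries of the
Brownian-motion covariance. The ancestral mean and BM rate are profiled
out analytically; the profile likelihood is maximized over lambda in
[0, 1] with a bounded scalar optimizer, and both boundary values are
evaluated explicitly so boundary maxima are exact. Estimates reported as
1.0 are genuine boundary solutions — lambda is not allowed above 1. The
likelihood-ratio statistic against lambda = 0 is referred to chi-square
with 1 df, the standard (boundary-anticonservative) convention.
Logarithms are natural throughout; log–log slopes are base-invariant,
and doubling effects are computed as `2^slope`.

## Contrast association (`association`)

All contrast regressions and correlations pass through the origin: the
sign of each contrast is an arbitrary choice of sister order, so any
statistic must be invariant to row-wise sign flips, which forbids an
intercept. The through-origin Pearson coefficient is
`r = S_xy/sqrt(S_xx*S_yy)` with a two-sided t test on n - 1 df (only
the association consumes a degree of freedom; no mean is estimated).
Least squares is delegated to statsmodels OLS without a constant; t
tests use n - p df and the adjusted R^2 is the uncentred, no-intercept
version. VIFs come from through-origin auxiliary regressions, reporting
infinity (not an exception) for exact collinearity. Model comparison
uses the standard nested F test.

The model-selection path is a scripted recipe, not an automatic
selector: longevity is dropped for its strong collinearity with age at
maturity; mass and mass-specific metabolic rate (MSMR) are never entered
together (their log contrasts are strongly negatively correlated);
candidate additions are judged by nested F tests. Raw p values are
reported with no multiple-testing correction, and the report says so.

## The gamma-DFE consistency model (`dfe_consistency`)

With neutral synonymous mutations and deleterious nonsynonymous
mutations drawn from a gamma DFE of shape `beta`,
`piS = 2*Ne*u` and `piN/piS = k*Ne^(-beta)`. Between two species,
`(piN1/piS1)/(piN2/piS2) = (Ne1/Ne2)^(-beta)`; with `Ne ∝ x^gamma` for a
census proxy `x`, the log piN/piS vs log x slope is `-gamma*beta`.
`beta` defaults to 0.45, a site-frequency-spectrum estimate for
mammalian mtDNA; this package does not estimate the DFE itself, and
`beta` is a configuration parameter everywhere it appears. The constant
`k` cancels from every between-species ratio and is carried only so the
generative model is fully specified. Doubling effects are reported as
whole percentages.

## Sister-pair divergence (`sister_pairs`)

Triplets are cherries of the dataset tree plus the nearest taxon sharing
a sequenced gene with both sisters. Sister-pair membership is exclusive
(cherries are disjoint); a species may serve as outgroup for another
pair, since the outgroup only anchors the branch decomposition
`ds_i = (d12 + d_io - d_jo)/2` (negative decompositions clamp to 0).

dS between two sequences is the Nei–Gojobori proportion of synonymous
differences per synonymous site with the Jukes–Cantor correction
`-(3/4)ln(1 - 4p/3)`, undefined (flagged unreliable) at `p >= 3/4`. This
is a deliberate re-implementation choice over maximum-likelihood codon
models: it is self-contained and testable at desk scale, at the cost of
a few percent of systematic deviation at deep divergence where the
four-state assumption bends around codon structure (twofold-degenerate
sites saturate earlier than JC assumes). The retention window
`0.00005 < dS < 1` uses strict inequalities; retention requires *both*
sisters in range (the stricter of the two readings of "either"), with a
switch for the permissive reading. A transversion-only mode restricts
differences and site counts to transversions and uses the two-class
correction `-(1/2)ln(1 - 2q)`.

The log dS contrast between sisters cancels the shared divergence time:
`dS_i = u_i*T`, so `log dS1 - log dS2 = log(u1/u2)`. On synthetic
triplets with equal rates the contrasts centre on zero; with
`u1/u2 = 2` they centre on `ln 2`, independent of `T`.

## Synthetic worlds (`synthetic_data`)

The generator emulates the statistical structure the analysis assumes,
with full ground truth recorded.

**Tree.** A pure-birth clade simulated to `n_species/sampling_fraction`
tips (default fraction 0.12 — roughly the share of a mammal-sized clade
with population sequence data), thinned to the sampled species, rescaled
to unit depth, and with internal-node ages floored at `min_split_frac`
(default 0.01) of the depth. The floor emulates the dating resolution of
literature-assembled chronograms, which do not place dataset sister
species at vanishing split times; it matters because contrasts divide by
the square root of the split depth, so any non-Brownian trait component
(tip noise, estimation error) is amplified without bound as splits
approach zero and a single recent cherry can dominate a through-origin
regression.

**Traits.** Log-scale traits evolve as Brownian motion blended with
independent tip noise to achieve a target Pagel's lambda per trait
(sampling directly from `lambda*C + (1-lambda)*diag(C)`). Defaults give
mass lambda 1.0, MSMR 0.99, maturity 0.95, longevity 0.92, latitude
0.84, range 0.64 — strong inertia for life history, weaker for range —
with realistic cross-trait correlations (mass–MSMR -0.85,
maturity–longevity 0.82). Latitude is signed degrees via a tanh squash
rather than log-normal.

**Population sizes and targets.** `log Ne` is `gamma_true` times
centred log range plus `delta_dens` times the centred log density proxy
(1/BMR, so that with `delta_dens = gamma_true` the composite measure
range/BMR is the generative census size) plus Gaussian noise
(sd 0.3). Baselines `Ne = 1e5`, `u = 5e-8` and `theta_scale = 2` give a
median target `piS` of 0.01 — a realistic mammal mtDNA value that keeps
the whole distribution below the 0.1 cap where the correction-free
within-species regime would fail. Configurations whose +3 sigma target
exceeds the cap are rejected; individual tail draws above it (a
~1-in-10^5 event at the defaults) are resampled and logged.
`piN/piS = k*Ne^(-beta_true)` with the constant set so the baseline
ratio is 0.2. The mutation-rate law `u ∝ Ne^c` defaults to `c = 0`
(independent); `c = -1` reproduces the mutation-rate-limit scenario in
which the piS–range slope flattens while the piN/piS slope persists.

**Alignments.** Sample sizes are `2 + Poisson(mean - 2)` individuals
(default mean 15) and `Poisson(mean_codons)` codons (default 433, i.e.
~1,300 bp). A random coding background is drawn; synonymous and
nonsynonymous segregating sites are placed at distinct codons with
Poisson counts `pi_target * sites * a_n` (`a_n` the harmonic number of
n-1), derived-allele counts from the neutral 1/i spectrum, and mutations
chosen among single-nucleotide changes of the required class that avoid
stops. Each 1/i-spectrum mutation contributes `1/a_n` expected pairwise
differences, so the estimator is unbiased for the targets by
construction — which the closure tests verify.

**What the generator does not emulate.** Allele frequencies are drawn
independently per site (infinite-sites, no shared genealogy), so
between-site linkage — total in non-recombining mtDNA — is absent and
real estimator variance is understated; there is no demographic history,
selection at synonymous sites, hitch-hiking, cryptic species structure,
alignment error or base-composition bias. Passing recovery tests
therefore demonstrate that the estimators and the analysis chain are
correct for data satisfying the model's assumptions, not that real-data
inferences are unbiased.

## Known statistical behaviour of the full chain

Log-transforming noisy diversity estimates introduces a negative bias of
roughly half the squared coefficient of variation, which shrinks with
`Ne`; the fitted `gamma_hat` is therefore slightly steeper than the
generative slope at the default problem sizes, while the log piN/piS
slope is nearly immune because the numerator and denominator biases
cancel to first order. Exclusion of zero-diversity species truncates the
low-`Ne` tail and adds a small additional steepening. Across 100 worlds
of 500 species the mean ratio slope is statistically consistent with the
generative `-gamma*beta` (the acceptance experiment computes this); the
residual few-percent steepening echoes, at much smaller magnitude, the
usual empirical pattern of observed ratio slopes exceeding the DFE
prediction. Similarly, the mean of per-species `piN/piS` ratios carries
a Jensen bias relative to the target ratio, so estimator closure for the
ratio is asserted on pooled diversities (ratio of sums), not on the mean
of ratios.

## Problem sizes

Default analyses use the emulated-study scale (639 species); the
replicated consistency experiment uses 100 worlds of 500 species, and
recovery tests use 100–200 replicates at 200 tips — sizes chosen so the
full suite completes on a single CPU in minutes while keeping
Monte-Carlo standard errors a small fraction of the effects under test.
All randomness flows from explicit seeds; analysis itself is
deterministic.
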