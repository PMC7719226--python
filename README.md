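# mitodiv

Why do some species harbour more mitochondrial DNA diversity than others?
Neutral theory says synonymous diversity should track the product of the
effective population size and the mutation rate, `piS = 2*Ne*u` for
maternally inherited haploid mtDNA — yet correlations between mtDNA
diversity and census population size have been notoriously hard to
demonstrate. `mitodiv` implements, as a tested and reusable pipeline, a
comparative analysis of this question for a mammal-like clade: codon-level
diversity estimation, phylogenetically corrected correlation and
regression, and an analytic consistency model linking the strength of
purifying selection to population size. Because the original
species-level sequence databases are not redistributable, the pipeline
ships with a first-class synthetic-data generator that produces clades
with known ground truth, so every step can be validated by parameter
recovery.

It is aimed at molecular evolution and comparative-methods researchers
who want the individual components (Nei–Gojobori counting, independent
contrasts, Pagel's lambda, through-origin contrast regression, sister-pair
dS contrasts) as a coherent, scriptable library.

## The model

For each species, synonymous (`piS`) and nonsynonymous (`piN`) pairwise
diversity per site are estimated from in-frame codon alignments under the
vertebrate mitochondrial genetic code (NCBI table 2), with Nei–Gojobori
equal-pathway counting. If nonsynonymous mutations are deleterious with
gamma-distributed selection coefficients (shape `beta`), then

    piS     = 2 * Ne * u
    piN/piS = k * Ne^(-beta)        (independent of u)

If `Ne` scales with a census-size proxy `x` (geographic range, or
range/BMR) as `Ne ∝ x^gamma`, the slope of log `piN/piS` contrasts on
log `x` contrasts is predicted to be `-gamma*beta`, where `gamma` is
estimated as the log `piS` vs log `x` slope. A log–log slope `b` means
the response changes by `100*(2^b - 1)` percent per doubling of `x`.

Species are not independent data points; all correlations and
regressions run through the origin on Felsenstein independent contrasts,
and phylogenetic signal per trait is quantified with Pagel's lambda
(profile ML on [0,1], likelihood-ratio test against lambda = 0).
Mutation-rate variation is probed separately with sister-species
triplets: per-branch synonymous divergence `dS` (Jukes–Cantor corrected,
retention window `0.00005 < dS < 1`), whose between-sister log contrast
cancels the shared divergence time.

## Worked example

```python
from mitodiv import (WorldConfig, simulate_world, diversity_table,
                     contrast_frame, origin_regression, predicted_slope,
                     doubling_effect)

world = simulate_world(WorldConfig(n_species=500, gamma_true=0.16,
                                   beta_true=0.45, seed=1))
table, _ = diversity_table(world.alignments.values())
merged = world.traits.join(table.set_index("species")[["pi_s", "pi_n_over_pi_s"]])

cf = contrast_frame(world.phylogeny, merged, ["range_km2", "pi_s"])
gamma_hat = origin_regression(cf["pi_s"], cf[["range_km2"]]).slopes["range_km2"]
print(f"gamma_hat = {gamma_hat:+.3f}")
print(f"predicted piN/piS slope = {predicted_slope(gamma_hat, 0.45).predicted_slope:+.3f}")
print(f"piS change per range doubling = {doubling_effect(gamma_hat):+.0f}%")
```

prints (seed 1):

```
gamma_hat = +0.197
predicted piN/piS slope = -0.088
piS change per range doubling = +15%
```

i.e. this world's fitted diversity–range slope lands near the generative
0.16 (single-world sampling error of a few hundredths is expected),
diversity rises by about 15% per doubling of range, and the gamma-DFE
model predicts a log piN/piS vs log range slope near -0.09 — which the
ratio-contrast regression then tests directly. Averaged over 100 such
worlds the ratio slope centres on the generative -0.072.

The numbered drivers under `analysis/` run the full narrative on the
default 639-species world (diversity table, lambda table, contrast
correlations, regression recipe, consistency section, sister-pair dS)
and write their tables under `results/`. There is also a CLI:
`mitodiv simulate|diversity|analyze|triplets --help`.

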