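"""Synthetic worlds with known ground truth for the diversity analysis.

Generates a time-calibrated pure-birth phylogeny, life-history traits
with tunable phylogenetic signal (Pagel's lambda per trait), per-species
effective population sizes tied to geographic range and population
density, and codon alignments whose expected synonymous and
nonsynonymous diversities equal the generative targets

    piS = theta_scale * Ne * u
    piN / piS = k * Ne**(-beta_true)

Segregating sites are placed under an infinite-sites approximation with
a neutral (1/i) allele-frequency spectrum, so the expected pairwise
diversity per mutation is 1/a_n (a_n the harmonic number of n-1);
expectations, not genealogical variance structure, are what downstream
recovery tests consume.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .comparative import Phylogeny
from .seq_diversity import (
    ALL_CODONS,
    CODING_CODONS,
    CodonAlignment,
    _codon_index,
    _tables,
    is_stop,
    translate,
)


class ConfigError(ValueError):
    pass


#: Traits carried by every synthetic world, with Brownian-motion tip
#: variance (on the natural-log scale, tree depth 1), phylogenetic
#: signal lambda, and the mean of the log value.  Defaults mimic a
#: mammal-wide table: masses spanning many orders of magnitude with
#: strong signal, range and the diversity statistics with weaker signal.
DEFAULT_TRAITS: dict[str, dict[str, float]] = {
    "range_km2": {"bm_var": 5.3, "lambda": 0.64, "log_mean": math.log(3e5)},
    "mass_g": {"bm_var": 7.8, "lambda": 1.0, "log_mean": math.log(150.0)},
    "msmr": {"bm_var": 0.64, "lambda": 0.99, "log_mean": math.log(1.2)},
    "latitude": {"bm_var": 1.0, "lambda": 0.84, "log_mean": 0.0},
    "maturity_days": {"bm_var": 1.7, "lambda": 0.95, "log_mean": math.log(300.0)},
    "longevity_months": {"bm_var": 0.9, "lambda": 0.92, "log_mean": math.log(200.0)},
}

_TRAIT_ORDER = list(DEFAULT_TRAITS)

# Cross-trait correlations of the underlying (log-scale) deviations:
# mass and mass-specific metabolic rate strongly negatively correlated,
# longevity and age at maturity strongly positively, both life-history
# timescales increase with mass.  Range and latitude are independent of
# the rest.
_TRAIT_CORR = pd.DataFrame(
    np.eye(len(_TRAIT_ORDER)), index=_TRAIT_ORDER, columns=_TRAIT_ORDER
)
for _a, _b, _r in [
    ("mass_g", "msmr", -0.85),
    ("maturity_days", "longevity_months", 0.82),
    ("mass_g", "maturity_days", 0.55),
    ("mass_g", "longevity_months", 0.55),
    ("msmr", "maturity_days", -0.45),
    ("msmr", "longevity_months", -0.45),
]:
    _TRAIT_CORR.loc[_a, _b] = _TRAIT_CORR.loc[_b, _a] = _r


@dataclass(frozen=True)
class WorldConfig:
    """Generative parameters of a synthetic clade.

    The defaults describe the emulated data set: 639 species, on
    average 15 sequenced individuals and ~1,300 bp (433 codons) of
    mitochondrial coding sequence per species.  ``gamma_true`` is the
    slope of log Ne on log range; ``delta_dens`` the slope on the log
    density proxy 1/BMR (when equal to ``gamma_true`` the composite
    measure range/BMR is the generative census size); ``u_exponent``
    sets u proportional to Ne**c (0 = mutation rate independent of Ne).
    """

    n_species: int = 639
    tree_depth: float = 1.0
    #: fraction of the clade with sequence data; the tree is a pure-birth
    #: tree of n_species/sampling_fraction tips thinned to the sampled
    #: species, so dataset sister pairs sit at realistic depths rather
    #: than at the vanishing splits of a completely sampled clade
    sampling_fraction: float = 0.12
    #: dating resolution of the chronogram as a fraction of tree depth:
    #: no split is placed closer to the present than this (time-calibrated
    #: trees assembled from the literature do not resolve very recent
    #: splits, and contrasts on near-zero branches are pathological for
    #: any trait with a non-Brownian component)
    min_split_frac: float = 0.01
    gamma_true: float = 0.16
    beta_true: float = 0.45
    delta_dens: float = 0.16
    ne_noise_sd: float = 0.3
    ne_baseline: float = 1e5
    u_baseline: float = 5e-8
    u_exponent: float = 0.0
    theta_scale: float = 2.0
    ratio_at_baseline: float = 0.2
    mean_individuals: float = 15.0
    mean_codons: float = 433.0
    traits: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in DEFAULT_TRAITS.items()
    })
    seed: int = 0

    #: ceiling on per-species target piS; beyond it the correction-free
    #: within-species regime no longer holds
    pi_s_cap: float = 0.1

    @property
    def k(self) -> float:
        """Constant of piN/piS = k * Ne**(-beta)."""
        return self.ratio_at_baseline * self.ne_baseline**self.beta_true

    def validate(self) -> None:
        if self.n_species < 4:
            raise ConfigError("need at least 4 species")
        if min(self.tree_depth, self.ne_baseline, self.u_baseline,
               self.theta_scale, self.ratio_at_baseline) <= 0:
            raise ConfigError("rates and scales must be positive")
        if self.beta_true <= 0:
            raise ConfigError("beta_true must be positive")
        if self.mean_individuals < 2:
            raise ConfigError("mean_individuals must be at least 2")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ConfigError("sampling_fraction must be in (0, 1]")
        for name, spec in self.traits.items():
            lam = spec.get("lambda", 1.0)
            if not 0.0 <= lam <= 1.0:
                raise ConfigError(f"lambda for {name} outside [0, 1]")
            if spec.get("bm_var", 1.0) <= 0:
                raise ConfigError(f"non-positive bm_var for {name}")
        # infeasibility: if the configured scale pushes the bulk of the
        # target-piS distribution above the cap, no amount of resampling
        # makes the world generable
        sd = self._log_ne_sd()
        pi_s_hi = (
            self.theta_scale * self.ne_baseline * self.u_baseline
            * math.exp((1.0 + self.u_exponent) * 3.0 * sd)
        )
        if self.theta_scale * self.ne_baseline * self.u_baseline >= self.pi_s_cap:
            raise ConfigError(
                "baseline target piS exceeds the within-species regime cap"
            )
        if pi_s_hi >= self.pi_s_cap * 2.0:
            raise ConfigError(
                f"target piS at +3 sigma ({pi_s_hi:.3g}) far exceeds the cap "
                f"{self.pi_s_cap}; lower theta_scale, u or Ne spread"
            )

    def _log_ne_sd(self) -> float:
        var_range = self.traits["range_km2"]["bm_var"]
        vm = self.traits["mass_g"]["bm_var"]
        vr = self.traits["msmr"]["bm_var"]
        rho = _TRAIT_CORR.loc["mass_g", "msmr"]
        var_dens = vm + vr + 2.0 * rho * math.sqrt(vm * vr)
        return math.sqrt(
            self.gamma_true**2 * var_range
            + self.delta_dens**2 * var_dens
            + self.ne_noise_sd**2
        )


@dataclass
class SyntheticWorld:
    """A generated clade: tree, trait table, alignments, and the truth."""

    config: WorldConfig
    phylogeny: Phylogeny
    traits: pd.DataFrame
    alignments: dict[str, CodonAlignment]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def _yule_tree(n_tips: int, rng: random.Random) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` extant tips (unit birth rate).

    Lineages split after Exp(k) waits with k the current lineage count;
    after the n-th birth the tree is extended by the waiting time to the
    next (unrealized) event so terminal branches stay strictly positive.
    """
    tree = dendropy.Tree()
    birth_time = {id(tree.seed_node): 0.0}
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.expovariate(float(k))
        parent = active.pop(rng.randrange(k))
        parent.edge.length = t - birth_time.pop(id(parent))
        for _ in range(2):
            child = parent.new_child()
            birth_time[id(child)] = t
            active.append(child)
    t += rng.expovariate(float(n_tips))
    taxa = tree.taxon_namespace
    for i, leaf in enumerate(active, start=1):
        leaf.edge.length = t - birth_time.pop(id(leaf))
        leaf.taxon = taxa.new_taxon(f"tip{i:05d}")
    tree.seed_node.edge.length = 0.0
    return tree


def _simulate_tree(
    n_species: int,
    depth: float,
    sampling_fraction: float,
    min_split_frac: float,
    rng: random.Random,
) -> Phylogeny:
    """Pure-birth clade thinned to the sampled species, rescaled to ``depth``.

    Internal-node ages are floored at ``min_split_frac * depth``, the
    dating resolution of the emulated chronogram.
    """
    n_clade = max(n_species, int(round(n_species / sampling_fraction)))
    tree = _yule_tree(n_clade, rng)
    if n_clade > n_species:
        labels = sorted(t.label for t in tree.taxon_namespace)
        keep = rng.sample(labels, n_species)
        tree.retain_taxa_with_labels(keep)
        tree.suppress_unifurcations()
        tree.seed_node.edge.length = 0.0
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label), start=1
    ):
        leaf.taxon.label = f"sp{i:04d}"
    max_depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    # node ages (time before present), clamped to the dating resolution
    age: dict[int, float] = {}
    dist: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        dist[id(node)] = (
            0.0 if parent is None
            else dist[id(parent)] + (node.edge.length or 0.0)
        )
    floor = min_split_frac * max_depth
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            age[id(node)] = 0.0
        else:
            raw = max_depth - dist[id(node)]
            kids = max(age[id(c)] for c in node.child_nodes())
            age[id(node)] = max(raw, floor, kids)
    scale = depth / max_depth
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is not None:
            node.edge.length = (age[id(parent)] - age[id(node)]) * scale
    return Phylogeny(tree)


def _simulate_traits(
    phylo: Phylogeny, config: WorldConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Log-scale traits: lambda-blended Brownian motion, correlated across traits."""
    labels, C = phylo.vcv()
    n = len(labels)
    C = C / config.tree_depth  # unit tip variance before per-trait scaling
    trait_names = list(config.traits)
    corr = _TRAIT_CORR.reindex(index=trait_names, columns=trait_names).fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    chol_corr = np.linalg.cholesky(corr.to_numpy())
    Z = rng.standard_normal((n, len(trait_names))) @ chol_corr.T
    cols = {}
    for t_idx, name in enumerate(trait_names):
        spec = config.traits[name]
        lam = spec.get("lambda", 1.0)
        V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        x = spec.get("log_mean", 0.0) + math.sqrt(spec["bm_var"]) * (L @ Z[:, t_idx])
        cols["log_" + name] = x
    frame = pd.DataFrame(cols, index=labels)
    # natural-scale traits; latitude is signed degrees, not log-normal
    for name in trait_names:
        if name == "latitude":
            frame[name] = 35.0 * np.tanh(frame["log_" + name] / 2.0)
        else:
            frame[name] = np.exp(frame["log_" + name])
    frame = frame[[c for c in frame.columns if not c.startswith("log_")]]
    frame.index.name = "species"
    return frame


def _assign_ne_u(
    traits: pd.DataFrame, config: WorldConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Ne from range and density, u per the mutation-rate law, piS/piN targets."""
    log_range = np.log(traits["range_km2"].to_numpy())
    log_dens = -np.log(traits["msmr"].to_numpy() * traits["mass_g"].to_numpy())
    base = (
        config.gamma_true * (log_range - log_range.mean())
        + config.delta_dens * (log_dens - log_dens.mean())
    )
    n = len(traits)
    pi_base = config.theta_scale * config.ne_baseline * config.u_baseline
    eps = rng.normal(0.0, config.ne_noise_sd, size=n)
    log_ne = np.log(config.ne_baseline) + base + eps
    # rare tail draws above the cap are resampled (noise only); the
    # config-level feasibility check keeps this a tail event
    for _ in range(200):
        pi_s = pi_base * np.exp(
            (1.0 + config.u_exponent) * (log_ne - math.log(config.ne_baseline))
        )
        bad = pi_s >= config.pi_s_cap
        if not bad.any():
            break
        eps[bad] = rng.normal(0.0, config.ne_noise_sd, size=int(bad.sum()))
        log_ne[bad] = math.log(config.ne_baseline) + base[bad] + eps[bad]
    else:
        raise ConfigError("could not keep target piS below the cap")
    ne = np.exp(log_ne)
    u = config.u_baseline * (ne / config.ne_baseline) ** config.u_exponent
    pi_s = config.theta_scale * ne * u
    ratio = config.k * ne ** (-config.beta_true)
    truth = pd.DataFrame(
        {
            "ne": ne,
            "u": u,
            "pi_s_target": pi_s,
            "ratio_target": ratio,
            "pi_n_target": pi_s * ratio,
        },
        index=traits.index,
    )
    return truth


# ---------------------------------------------------------------------------
# Alignment construction
# ---------------------------------------------------------------------------

_CODON_STRS = np.array(ALL_CODONS)
_CODING_IDX = np.array([_codon_index(c) for c in CODING_CODONS])

def _mutation_menu() -> tuple[dict[int, list[int]], dict[int, list[int]]]:
    """For each coding codon index, the synonymous / nonsynonymous
    single-nucleotide neighbour codon indices (stops excluded)."""
    syn: dict[int, list[int]] = {}
    nonsyn: dict[int, list[int]] = {}
    for codon in CODING_CODONS:
        idx = _codon_index(codon)
        s_list, n_list = [], []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if is_stop(alt):
                    continue
                (s_list if translate(alt) == translate(codon) else n_list).append(
                    _codon_index(alt)
                )
        syn[idx] = s_list
        nonsyn[idx] = n_list
    return syn, nonsyn


_SYN_MENU, _NONSYN_MENU = _mutation_menu()
_HAS_SYN = np.array(sorted(i for i, v in _SYN_MENU.items() if v))


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _neutral_count(n: int, rng: np.random.Generator) -> int:
    """Derived-allele count from the neutral 1/i spectrum on 1..n-1."""
    i = np.arange(1, n)
    p = (1.0 / i) / np.sum(1.0 / i)
    return int(rng.choice(i, p=p))


def build_alignment(
    species_id: str,
    n_individuals: int,
    n_codons: int,
    pi_s_target: float,
    pi_n_target: float,
    rng: np.random.Generator,
) -> CodonAlignment:
    """Codon alignment whose expected piS/piN estimates hit the targets.

    A random coding background is drawn; synonymous and nonsynonymous
    segregating sites are placed at distinct codons with Poisson counts
    calibrated so that mean pairwise differences per site equal the
    targets (each 1/i-spectrum mutation contributes 1/a_n expected
    pairwise differences).
    """
    if n_individuals < 2:
        raise ConfigError("need at least 2 individuals")
    tab = _tables(False)
    background = rng.choice(_HAS_SYN, size=n_codons)
    syn_sites = float(tab.syn_sites[background].sum())
    nonsyn_sites = float(tab.nonsyn_sites[background].sum())
    a_n = _harmonic(n_individuals)
    m_syn = rng.poisson(pi_s_target * syn_sites * a_n)
    m_nonsyn = rng.poisson(pi_n_target * nonsyn_sites * a_n)
    total = m_syn + m_nonsyn
    if total > n_codons:  # pathological; keep proportions
        m_syn = int(round(m_syn * n_codons / total))
        m_nonsyn = n_codons - m_syn
        total = n_codons
    seqs = np.tile(background, (n_individuals, 1))
    if total:
        sites = rng.choice(n_codons, size=total, replace=False)
        for j, codon_pos in enumerate(sites):
            menu = _SYN_MENU if j < m_syn else _NONSYN_MENU
            options = menu[int(background[codon_pos])]
            if not options:
                continue
            derived = options[int(rng.integers(len(options)))]
            count = _neutral_count(n_individuals, rng)
            carriers = rng.choice(n_individuals, size=count, replace=False)
            seqs[carriers, codon_pos] = derived
    sequences = ["".join(_CODON_STRS[row]) for row in seqs]
    return CodonAlignment(
        species_id=species_id,
        sequences=sequences,
        sequence_ids=[f"{species_id}_ind{i + 1}" for i in range(n_individuals)],
        genes=[("synthetic_mt", (0, n_codons))],
    )


# ---------------------------------------------------------------------------
# Worlds
# ---------------------------------------------------------------------------

def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate one complete synthetic clade from ``config`` (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree_rng = random.Random(int(rng.integers(2**31)))
    phylo = _simulate_tree(
        config.n_species,
        config.tree_depth,
        config.sampling_fraction,
        config.min_split_frac,
        tree_rng,
    )
    traits = _simulate_traits(phylo, config, rng)
    truth = _assign_ne_u(traits, config, rng)
    alignments: dict[str, CodonAlignment] = {}
    n_ind_draws = 2 + rng.poisson(config.mean_individuals - 2.0, size=len(traits))
    n_codon_draws = np.maximum(
        30, rng.poisson(config.mean_codons, size=len(traits))
    )
    for i, sp in enumerate(traits.index):
        alignments[sp] = build_alignment(
            sp,
            int(n_ind_draws[i]),
            int(n_codon_draws[i]),
            float(truth.loc[sp, "pi_s_target"]),
            float(truth.loc[sp, "pi_n_target"]),
            rng,
        )
    return SyntheticWorld(
        config=config,
        phylogeny=phylo,
        traits=traits,
        alignments=alignments,
        truth=truth,
    )


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Emit the file formats the pipeline consumes, plus the truth table.

    FASTA per species (with a manifest TSV mapping species to files and
    genes), the Newick tree, the trait TSV, and a truth TSV.
    """
    outdir = Path(outdir)
    fasta_dir = outdir / "alignments"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sp, aln in sorted(world.alignments.items()):
        path = fasta_dir / f"{sp}.fasta"
        with open(path, "w") as fh:
            for sid, seq in zip(aln.sequence_ids, aln.sequences):
                fh.write(f">{sid}\n{seq}\n")
        manifest_rows.append(
            {"species": sp, "file": str(path.relative_to(outdir)),
             "gene": aln.genes[0][0]}
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.tsv", sep="\t",
                                       index=False)
    world.phylogeny.tree.write(
        path=str(outdir / "tree.nwk"), schema="newick",
        suppress_rooting=True, unquoted_underscores=True,
    )
    bmr = world.traits["msmr"] * world.traits["mass_g"]
    traits_out = world.traits.copy()
    traits_out["bmr_ml_o2_h"] = bmr
    traits_out.to_csv(outdir / "traits.tsv", sep="\t")
    world.truth.to_csv(outdir / "truth.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Triplets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripletSimConfig:
    """Sister-pair simulation: shared split time, per-sister rates.

    ``divergence`` is the expected per-site substitution load u*T on
    each sister branch at ``rate_ratio`` 1; the outgroup sits
    ``outgroup_factor`` times deeper.  ``rate_sd_log`` adds lognormal
    rate variation across triplets.
    """

    n_triplets: int = 50
    n_codons: int = 433
    divergence: float = 0.05
    rate_ratio: float = 1.0
    rate_sd_log: float = 0.0
    outgroup_factor: float = 3.0
    seed: int = 0


def _evolve(seq: np.ndarray, expected_subs_per_site: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply Poisson-count random substitutions, rejecting stop codons."""
    seq = seq.copy()
    n_events = rng.poisson(expected_subs_per_site * 3 * len(seq))
    for _ in range(n_events):
        codon_pos = int(rng.integers(len(seq)))
        codon = ALL_CODONS[int(seq[codon_pos])]
        pos = int(rng.integers(3))
        alt_base = "ACGT".replace(codon[pos], "")[int(rng.integers(3))]
        alt = codon[:pos] + alt_base + codon[pos + 1 :]
        if is_stop(alt):
            continue  # mutations to stops are unobservable; event discarded
        seq[codon_pos] = _codon_index(alt)
    return seq


def simulate_triplets(
    config: TripletSimConfig,
) -> tuple[list[CodonAlignment], pd.DataFrame]:
    """Triplet alignments with known per-sister rates and a shared split time.

    Sister 1 evolves at ``rate_ratio`` times the rate of sister 2 over
    the same time T, so the expected dS log-contrast is
    log(rate_ratio), independent of T.  Returns the alignments (ordered
    sp1, sp2, outgroup) and a truth table with u1/u2 and T per triplet.
    """
    rng = np.random.default_rng(config.seed)
    alignments = []
    rows = []
    for t in range(config.n_triplets):
        scale = math.exp(rng.normal(0.0, config.rate_sd_log)) if \
            config.rate_sd_log > 0 else 1.0
        d2 = config.divergence * scale
        d1 = d2 * config.rate_ratio
        ancestor = rng.choice(_CODING_IDX, size=config.n_codons)
        root = _evolve(
            ancestor,
            (config.outgroup_factor - 1.0) * 0.5 * (d1 + d2), rng
        )
        sp1 = _evolve(root, d1, rng)
        sp2 = _evolve(root, d2, rng)
        out = _evolve(
            ancestor, config.outgroup_factor * 0.5 * (d1 + d2), rng
        )
        name = f"triplet{t + 1:03d}"
        alignments.append(
            CodonAlignment(
                species_id=name,
                sequences=["".join(_CODON_STRS[s]) for s in (sp1, sp2, out)],
                sequence_ids=[f"{name}_sp1", f"{name}_sp2", f"{name}_out"],
                genes=[("synthetic_mt", (0, config.n_codons))],
            )
        )
        rows.append({"triplet": name, "u1_t": d1, "u2_t": d2,
                     "rate_ratio": config.rate_ratio})
    return alignments, pd.DataFrame(rows)
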