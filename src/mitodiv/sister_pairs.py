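"""Sister-triplet divergence analysis.

Groups species into triplets — two sister species (a cherry of the
dataset tree) plus an outgroup sharing a sequenced gene — estimates
synonymous divergence dS per sister branch, filters unreliable
estimates, and forms divergence-time-free log-ratio contrasts:
dS = u * T with shared split time T, so log dS1 - log dS2 = log(u1/u2).

dS between two sequences is the Nei–Gojobori proportion of synonymous
differences per synonymous site with a Jukes–Cantor multiple-hit
correction; a transversion-only variant is provided for saturation
checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparative import Phylogeny
from .seq_diversity import AlignmentError, CodonAlignment, pairwise_counts

logger = logging.getLogger(__name__)

#: Retention window for dS estimates (strict inequalities): below the
#: lower bound an estimate is mostly sampling noise, above the upper
#: bound multiple hits dominate.
DS_LOWER = 0.00005
DS_UPPER = 1.0


@dataclass(frozen=True)
class Triplet:
    sp1: str
    sp2: str
    outgroup: str
    shared_gene: str


@dataclass(frozen=True)
class DivergenceEstimate:
    """Synonymous divergence per synonymous site between two sequences."""

    ds: float
    ds_tv: float
    n_syn_sites: float
    reliable: bool = True

    def in_window(self, lower: float = DS_LOWER, upper: float = DS_UPPER) -> bool:
        return self.reliable and lower < self.ds < upper


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor correction -(3/4)ln(1 - 4p/3); undefined at p >= 3/4."""
    if p >= 0.75:
        return float("nan"), False
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), True


def _tv_correct(q: float) -> tuple[float, bool]:
    """Transversion-distance correction -(1/2)ln(1 - 2q); undefined at q >= 1/2."""
    if q >= 0.5:
        return float("nan"), False
    return -0.5 * math.log(1.0 - 2.0 * q), True


def estimate_ds(pair_alignment: CodonAlignment,
                transversions_only: bool = False) -> DivergenceEstimate:
    """dS between the two sequences of ``pair_alignment``.

    In transversion-only mode both the differences and the sites are
    restricted to transversion changes and the two-class correction
    -(1/2)ln(1-2q) replaces the four-state Jukes–Cantor formula.
    """
    if pair_alignment.n_sequences != 2:
        raise AlignmentError("estimate_ds expects exactly 2 sequences")
    a, b = pair_alignment.sequences
    sd, _, ss, _ = pairwise_counts(a, b)
    sd_tv, _, ss_tv, _ = pairwise_counts(a, b, transversions_only=True)
    if ss <= 0:
        raise AlignmentError("no comparable synonymous sites")
    p = sd / ss
    ds, ok = _jc_correct(p)
    q = sd_tv / ss_tv if ss_tv > 0 else float("nan")
    ds_tv, ok_tv = _tv_correct(q) if not math.isnan(q) else (float("nan"), False)
    reliable = ok_tv if transversions_only else ok
    primary_sites = ss_tv if transversions_only else ss
    return DivergenceEstimate(
        ds=ds_tv if transversions_only else ds,
        ds_tv=ds_tv,
        n_syn_sites=primary_sites,
        reliable=reliable,
    )


def triplet_branch_ds(
    alignment: CodonAlignment, transversions_only: bool = False
) -> tuple[DivergenceEstimate, DivergenceEstimate]:
    """Per-sister-branch dS from a 3-sequence alignment (sp1, sp2, outgroup).

    Uses the additive decomposition d(i) = (d12 + d_i,out - d_j,out)/2,
    which apportions the sister-to-sister divergence onto the two
    branches since their split; negative decompositions are clamped to 0.
    """
    if alignment.n_sequences != 3:
        raise AlignmentError("triplet alignment must have exactly 3 sequences")

    def pair(i: int, j: int) -> DivergenceEstimate:
        sub = CodonAlignment(
            species_id=alignment.species_id,
            sequences=[alignment.sequences[i], alignment.sequences[j]],
            sequence_ids=[alignment.sequence_ids[i], alignment.sequence_ids[j]],
            genes=list(alignment.genes),
        )
        return estimate_ds(sub, transversions_only=transversions_only)

    d12, d1o, d2o = pair(0, 1), pair(0, 2), pair(1, 2)
    reliable = d12.reliable and d1o.reliable and d2o.reliable
    ds1 = max(0.0, (d12.ds + d1o.ds - d2o.ds) / 2.0) if reliable else float("nan")
    ds2 = max(0.0, (d12.ds + d2o.ds - d1o.ds) / 2.0) if reliable else float("nan")
    sites = d12.n_syn_sites
    return (
        DivergenceEstimate(ds=ds1, ds_tv=float("nan"), n_syn_sites=sites,
                           reliable=reliable),
        DivergenceEstimate(ds=ds2, ds_tv=float("nan"), n_syn_sites=sites,
                           reliable=reliable),
    )


# ---------------------------------------------------------------------------
# Triplet selection
# ---------------------------------------------------------------------------

def select_triplets(
    phylo: Phylogeny,
    gene_availability: Mapping[str, Sequence[str]],
) -> list[Triplet]:
    """Cherries of the tree paired with the nearest gene-sharing outgroup.

    A cherry (two tips that are mutual closest relatives) becomes a
    triplet when some other taxon shares a sequenced gene with both
    sisters; the nearest such taxon (smallest patristic distance to the
    pair, ties broken alphabetically) is the outgroup.  Each species
    belongs to at most one sister pair (cherries are disjoint by
    construction); a species may serve as the outgroup of another
    pair, since the outgroup only anchors the branch decomposition.
    Candidates without a usable outgroup or shared gene are dropped
    with a logged reason.
    """
    tree = phylo.tree
    genes = {sp: set(gs) for sp, gs in gene_availability.items()}
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}

    cherries: list[tuple[str, str]] = []
    for node in tree.postorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            pair = sorted(c.taxon.label for c in children)
            cherries.append((pair[0], pair[1]))
    cherries.sort()

    paired: set[str] = set()
    triplets: list[Triplet] = []
    for sp1, sp2 in cherries:
        if sp1 in paired or sp2 in paired:
            continue
        shared = genes.get(sp1, set()) & genes.get(sp2, set())
        if not shared:
            logger.info("cherry (%s, %s) dropped: no shared gene", sp1, sp2)
            continue
        candidates = []
        for other in sorted(taxa):
            if other in (sp1, sp2):
                continue
            shared3 = shared & genes.get(other, set())
            if not shared3:
                continue
            dist = min(
                pdm.patristic_distance(taxa[sp1], taxa[other]),
                pdm.patristic_distance(taxa[sp2], taxa[other]),
            )
            candidates.append((dist, other, shared3))
        if not candidates:
            logger.info(
                "cherry (%s, %s) dropped: no outgroup shares a gene", sp1, sp2
            )
            continue
        dist, outgroup, shared3 = min(candidates, key=lambda c: (c[0], c[1]))
        triplets.append(
            Triplet(sp1=sp1, sp2=sp2, outgroup=outgroup,
                    shared_gene=sorted(shared3)[0])
        )
        paired.update((sp1, sp2))
    return triplets


# ---------------------------------------------------------------------------
# Filtering and contrasts
# ---------------------------------------------------------------------------

@dataclass
class TripletRecord:
    """A triplet with its per-sister dS estimates and retention status."""

    triplet: Triplet
    ds1: DivergenceEstimate
    ds2: DivergenceEstimate
    retained: bool = True
    exclusion_reason: str = ""
    traits1: dict = field(default_factory=dict)
    traits2: dict = field(default_factory=dict)


def filter_ds(
    records: Sequence[TripletRecord],
    lower: float = DS_LOWER,
    upper: float = DS_UPPER,
    require_both: bool = True,
) -> list[TripletRecord]:
    """Apply the strict dS retention window to every triplet.

    ``require_both=True`` (default, the stricter reading) demands both
    sisters inside the window; the permissive reading keeps a triplet if
    either sister passes.  Exclusion reasons are recorded in place and
    counted in the log.
    """
    n_excluded = 0
    for rec in records:
        ok1 = rec.ds1.in_window(lower, upper)
        ok2 = rec.ds2.in_window(lower, upper)
        keep = (ok1 and ok2) if require_both else (ok1 or ok2)
        rec.retained = keep
        if not keep:
            n_excluded += 1
            rec.exclusion_reason = (
                f"ds out of ({lower}, {upper}): ds1={rec.ds1.ds:.6g}, "
                f"ds2={rec.ds2.ds:.6g}"
            )
    logger.info("dS filter excluded %d of %d triplets", n_excluded, len(records))
    return [rec for rec in records if rec.retained]


def pair_contrasts(record: TripletRecord) -> dict[str, float]:
    """Per-trait log(trait1/trait2) contrasts for one sister pair.

    Includes ``ds`` from the divergence estimates plus every trait
    present and positive for both sisters; anything else is omitted for
    that pair.  Contrasts are antisymmetric under swapping the sisters.
    """
    out: dict[str, float] = {}
    if (
        record.ds1.reliable and record.ds2.reliable
        and record.ds1.ds > 0 and record.ds2.ds > 0
    ):
        out["ds"] = math.log(record.ds1.ds / record.ds2.ds)
    for name in set(record.traits1) & set(record.traits2):
        v1, v2 = record.traits1[name], record.traits2[name]
        if v1 is None or v2 is None:
            continue
        if not (np.isfinite(v1) and np.isfinite(v2)) or v1 <= 0 or v2 <= 0:
            continue
        out[name] = math.log(v1 / v2)
    return out


def contrast_table(records: Sequence[TripletRecord]) -> pd.DataFrame:
    """Stack pair contrasts for all retained triplets into a DataFrame."""
    rows = []
    for rec in records:
        if not rec.retained:
            continue
        row = {"sp1": rec.triplet.sp1, "sp2": rec.triplet.sp2}
        row.update(pair_contrasts(rec))
        rows.append(row)
    return pd.DataFrame(rows)


def triplet_table(records: Sequence[TripletRecord]) -> pd.DataFrame:
    """TSV-ready triplet summary (ids, gene, dS per sister, retention)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "sp1": rec.triplet.sp1,
                "sp2": rec.triplet.sp2,
                "outgroup": rec.triplet.outgroup,
                "gene": rec.triplet.shared_gene,
                "ds1": rec.ds1.ds,
                "ds2": rec.ds2.ds,
                "retained": rec.retained,
                "exclusion_reason": rec.exclusion_reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sp1", "sp2", "outgroup", "gene", "ds1", "ds2", "retained",
                 "exclusion_reason"],
    )
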