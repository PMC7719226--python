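"""Phylogenetic comparative machinery.

Newick trees (time-calibrated, TimeTree-style), Felsenstein (1985)
independent contrasts, and Pagel's lambda phylogenetic-signal estimation
with a likelihood-ratio test against lambda = 0.

Species trait data are not statistically independent because of shared
ancestry; contrasts between sister lineages, standardized by their
expected Brownian-motion variance, remove that dependence.  A tree with
n tips yields exactly n - 1 contrasts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted binary tree with non-negative branch lengths in time units."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def pruned_to(self, labels: Sequence[str]) -> "Phylogeny":
        """Copy of the tree retaining only the given tip labels."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        sub = self.tree.clone(depth=1)
        sub.retain_taxa_with_labels(sorted(keep))
        sub.suppress_unifurcations()
        return Phylogeny(sub)

    def vcv(self, labels: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Brownian-motion covariance: shared root-to-MRCA path lengths."""
        tree = self.tree
        leaves = list(tree.leaf_node_iter())
        if labels is not None:
            by_label = {lf.taxon.label: lf for lf in leaves}
            leaves = [by_label[lb] for lb in labels]
        # depth of every node from the root
        depth: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + (
                edge if parent is not None else 0.0
            )
        n = len(leaves)
        C = np.zeros((n, n))
        mrca_depth = _pairwise_mrca_depths(tree, leaves, depth)
        for i in range(n):
            C[i, i] = depth[id(leaves[i])]
            for j in range(i + 1, n):
                C[i, j] = C[j, i] = mrca_depth[i, j]
        return [lf.taxon.label for lf in leaves], C


def _pairwise_mrca_depths(
    tree: dendropy.Tree, leaves: list, depth: dict[int, float]
) -> np.ndarray:
    """Depth of the MRCA for every leaf pair, via one postorder sweep."""
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    out = np.zeros((n, n))
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            own = index.get(id(node))
            below[id(node)] = np.array([own] if own is not None else [], dtype=int)
            continue
        child_sets = [below.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                if len(child_sets[a]) and len(child_sets[b]):
                    out[np.ix_(child_sets[a], child_sets[b])] = d
                    out[np.ix_(child_sets[b], child_sets[a])] = d
        below[id(node)] = np.concatenate(child_sets) if child_sets else \
            np.array([], dtype=int)
    return out


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick tree; resolve polytomies into zero-length binary nodes.

    Branch lengths are required on every non-root edge (they carry the
    divergence times the contrast variances depend on).
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate tip labels")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise TreeError(
                f"missing branch length above {_describe_node(node)}"
            )
        if node.edge.length < 0:
            raise TreeError(f"negative branch length above {_describe_node(node)}")
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    return Phylogeny(tree)


def _describe_node(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    tips = [lf.taxon.label for lf in node.leaf_iter()]
    return f"clade({','.join(sorted(tips)[:3])}...)" if len(tips) > 3 else \
        f"clade({','.join(sorted(tips))})"


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """n-1 standardized contrasts for one trait on a pruned tree."""

    node_ids: list[str]
    contrasts: np.ndarray
    variances: np.ndarray
    tip_count: int
    dropped: list[str]

    def __post_init__(self) -> None:
        if len(self.contrasts) != self.tip_count - 1:
            raise TreeError(
                f"{len(self.contrasts)} contrasts for {self.tip_count} tips"
            )


def _usable_trait(
    trait: Mapping[str, float] | pd.Series, log_transform: bool
) -> tuple[dict[str, float], list[str]]:
    values = dict(pd.Series(trait).dropna())
    dropped = []
    if log_transform:
        for sp, v in list(values.items()):
            if v <= 0:
                dropped.append(sp)
                del values[sp]
        if dropped:
            logger.warning(
                "dropping %d species with non-positive trait under log", len(dropped)
            )
        values = {sp: math.log(v) for sp, v in values.items()}
    return values, dropped


def independent_contrasts(
    phylo: Phylogeny,
    trait: Mapping[str, float] | pd.Series,
    log_transform: bool = False,
) -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    At each internal node of the (pruned, binary) tree the contrast is
    (x1 - x2)/sqrt(v1 + v2); the ancestral value is the
    precision-weighted mean of the children and the parent branch is
    extended by v1*v2/(v1 + v2).  Tips lacking the trait are pruned
    first; under ``log_transform`` non-positive values are dropped with
    a warning.
    """
    values, dropped = _usable_trait(trait, log_transform)
    usable = [lb for lb in phylo.tip_labels if lb in values]
    if len(usable) < 2:
        raise TreeError("need at least 2 tips with trait values")
    dropped = dropped + [lb for lb in phylo.tip_labels if lb not in values]
    sub = phylo.pruned_to(usable)
    contrasts: list[float] = []
    variances: list[float] = []
    node_ids: list[str] = []
    state: dict[int, tuple[float, float]] = {}  # node -> (value, effective length)
    for node in sub.tree.postorder_node_iter():
        edge = node.edge.length or 0.0
        if node.is_leaf():
            state[id(node)] = (values[node.taxon.label], edge)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise TreeError("tree not binary after pruning")
        (x1, v1), (x2, v2) = (state.pop(id(c)) for c in children)
        v_sum = v1 + v2
        if v_sum <= 0:
            raise TreeError(
                f"zero expected variance at {_describe_node(node)}; "
                "sister branches both have zero length"
            )
        contrasts.append((x1 - x2) / math.sqrt(v_sum))
        variances.append(v_sum)
        node_ids.append(_describe_node(node))
        anc = (x1 * v2 + x2 * v1) / v_sum
        state[id(node)] = (anc, edge + v1 * v2 / v_sum)
    return ContrastSet(
        node_ids=node_ids,
        contrasts=np.asarray(contrasts),
        variances=np.asarray(variances),
        tip_count=len(usable),
        dropped=dropped,
    )


def contrast_frame(
    phylo: Phylogeny,
    table: pd.DataFrame,
    columns: Sequence[str],
    log_transform: bool = True,
) -> pd.DataFrame:
    """Contrasts for several traits on one common pruned tree.

    Rows of ``table`` (indexed by species) are kept only if every column
    is present (and positive, under log), so all traits share the same
    node order — required when contrasts are correlated or regressed
    against each other.
    """
    sub_table = table[list(columns)].dropna()
    if log_transform:
        sub_table = sub_table[(sub_table > 0).all(axis=1)]
    keep = [lb for lb in phylo.tip_labels if lb in sub_table.index]
    if len(keep) < 3:
        raise TreeError("fewer than 3 species with complete data")
    sub = phylo.pruned_to(keep)
    out = {}
    node_ids = None
    for col in columns:
        cs = independent_contrasts(sub, sub_table[col], log_transform=log_transform)
        out[col] = cs.contrasts
        node_ids = cs.node_ids
    return pd.DataFrame(out, index=node_ids)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaFit:
    """Maximum-likelihood Pagel's lambda with LRT against lambda = 0."""

    lambda_hat: float
    logL_at_hat: float
    logL_at_zero: float
    lrt_p: float
    n_tips: int

    @property
    def lrt_statistic(self) -> float:
        return 2.0 * (self.logL_at_hat - self.logL_at_zero)


def _profile_loglik(lam: float, x: np.ndarray, C: np.ndarray) -> float:
    """Log-likelihood with mean and BM rate profiled out analytically."""
    n = len(x)
    V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise TreeError(f"singular phylogenetic covariance: {exc}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ones = np.ones(n)
    Vi_x = linalg.cho_solve(cho, x)
    Vi_1 = linalg.cho_solve(cho, ones)
    mu = (ones @ Vi_x) / (ones @ Vi_1)
    resid = x - mu
    sigma2 = float(resid @ linalg.cho_solve(cho, resid)) / n
    if sigma2 <= 0:
        raise TreeError("zero residual variance; trait is constant")
    return -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)


def pagel_lambda(
    phylo: Phylogeny,
    trait: Mapping[str, float] | pd.Series,
    log_transform: bool = False,
) -> LambdaFit:
    """Profile-ML estimate of Pagel's lambda on [0, 1], with an LRT.

    lambda multiplies the off-diagonal entries of the Brownian-motion
    covariance; the likelihood is profiled analytically over the
    ancestral mean and BM rate and maximized numerically over lambda.
    The likelihood-ratio statistic against lambda = 0 is referred to
    chi-square with 1 df (anti-conservative at the boundary, the
    standard practice for this test).
    """
    values, _ = _usable_trait(trait, log_transform)
    usable = [lb for lb in phylo.tip_labels if lb in values]
    if len(usable) < 4:
        raise TreeError("Pagel's lambda needs at least 4 tips with data")
    labels, C = phylo.pruned_to(usable).vcv()
    x = np.asarray([values[lb] for lb in labels], dtype=float)
    _check_not_singular(labels, C)

    def neg(lam: float) -> float:
        return -_profile_loglik(lam, x, C)

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    candidates = [(0.0, -neg(0.0)), (1.0, -neg(1.0)), (float(res.x), -res.fun)]
    lambda_hat, logL_hat = max(candidates, key=lambda t: t[1])
    logL_zero = dict(candidates)[0.0]
    stat = max(0.0, 2.0 * (logL_hat - logL_zero))
    p = float(stats.chi2.sf(stat, df=1))
    return LambdaFit(
        lambda_hat=lambda_hat,
        logL_at_hat=logL_hat,
        logL_at_zero=logL_zero,
        lrt_p=p,
        n_tips=len(usable),
    )


def _check_not_singular(labels: list[str], C: np.ndarray) -> None:
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if math.isclose(C[i, j], C[i, i]) and math.isclose(C[i, j], C[j, j]):
                raise TreeError(
                    f"tips {labels[i]!r} and {labels[j]!r} are at zero "
                    "phylogenetic distance; covariance is singular"
                )
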