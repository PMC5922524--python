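"""Relationships among final sub-regions.

Sub-region species lists (pooled over member sites) are compared with
the Simpson dissimilarity and clustered by UPGMA (average linkage).
Node support comes from bootstrapping species columns of the
group × species incidence — the only exchangeable unit in an incidence
table — with each replicate re-deriving the dissimilarity and the tree.
Nodes are identified by their leaf set (bipartition), not by height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .betadiv import DissimilarityMatrix, simpson_dissimilarity
from .data import OccurrenceTable

__all__ = ["Dendrogram", "upgma", "bootstrap_support"]

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Rooted UPGMA merge tree over group labels."""

    labels: list[str]
    linkage_matrix: np.ndarray
    support: dict[frozenset, float] | None = None

    def clades(self) -> list[frozenset]:
        """Leaf set of every internal node (including the root)."""
        n = len(self.labels)
        sets: dict[int, frozenset] = {i: frozenset([self.labels[i]])
                                      for i in range(n)}
        out = []
        for i, (a, b, _, _) in enumerate(self.linkage_matrix):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + i] = merged
            out.append(merged)
        return out

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cophenetic(self) -> DissimilarityMatrix:
        coph = cophenet(self.linkage_matrix)
        return DissimilarityMatrix(self.labels,
                                   np.minimum(squareform(coph), 1.0))

    def to_newick(self, include_support: bool = True) -> str:
        """Newick string with optional support values as node labels."""
        n = len(self.labels)
        children: dict[int, tuple[int, int]] = {}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage_matrix):
            children[n + i] = (int(a), int(b))
            height[n + i] = h
        leafset: dict[int, frozenset] = {i: frozenset([self.labels[i]])
                                         for i in range(n)}

        def render(node: int) -> tuple[str, frozenset]:
            if node < n:
                return self.labels[node], leafset[node]
            a, b = children[node]
            sa, fa = render(a)
            sb, fb = render(b)
            fs = fa | fb
            la = height[node] - height[a]
            lb = height[node] - height[b]
            label = ""
            if include_support and self.support and fs in self.support:
                label = f"{self.support[fs]:.2f}"
            return f"({sa}:{la:.6g},{sb}:{lb:.6g}){label}", fs

        body, _ = render(n + len(children) - 1)
        return body + ";"


def upgma(d: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomeration of a group dissimilarity matrix."""
    if d.n < 3:
        raise ValueError("need at least three groups")
    if np.any(np.isnan(d.d)):
        raise ValueError("NaN in dissimilarity matrix")
    z = linkage(d.condensed(), method="average")
    return Dendrogram(list(d.labels), z)


def bootstrap_support(group_incidence: OccurrenceTable, n_boot: int = 1000,
                      seed: int = 0, max_redraws: int = 100) -> Dendrogram:
    """UPGMA tree with bootstrap node support.

    Each replicate resamples species columns with replacement, rebuilds
    the group Simpson matrix and the UPGMA tree, and scores every
    original internal node by the fraction of replicate trees containing
    the same leaf set.  Replicates that leave some group without species
    are redrawn (and counted in the log).
    """
    if group_incidence.n_sites < 3:
        raise ValueError("need at least three groups")
    if group_incidence.n_species < 2:
        raise ValueError("need at least two species")
    base_d = simpson_dissimilarity(group_incidence)
    tree = upgma(base_d)
    clades = tree.clades()
    counts = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    n_sp = group_incidence.n_species
    redraws = 0
    for _ in range(n_boot):
        for _attempt in range(max_redraws):
            cols = rng.integers(0, n_sp, size=n_sp)
            inc = group_incidence.incidence[:, cols]
            if np.all(inc.sum(axis=1) > 0):
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a replicate without empty groups")
        rep = OccurrenceTable(group_incidence.sites,
                              [f"b{j}" for j in range(n_sp)], inc)
        rep_tree = upgma(simpson_dissimilarity(rep))
        rep_clades = set(rep_tree.clades())
        for c in clades:
            if c in rep_clades:
                counts[c] += 1
    if redraws:
        logger.info("bootstrap_support: %d replicate redraws due to empty "
                    "groups", redraws)
    tree.support = {c: counts[c] / n_boot for c in clades}
    return tree
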