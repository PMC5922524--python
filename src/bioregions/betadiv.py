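"""Simpson (βsim) turnover and shared-species accounting.

βsim isolates the turnover component of beta diversity: for two sites
with ``a`` shared species and ``b``/``c`` species unique to each,

    βsim = min(b, c) / (min(b, c) + a)

so a site nested inside a richer one scores 0 regardless of the richness
difference.  This richness independence is why βsim is the standard
choice for bioregionalization from incidence data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import OccurrenceTable

__all__ = ["DissimilarityMatrix", "TurnoverNetwork",
           "simpson_dissimilarity", "shared_species_counts"]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity with labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(float))


@dataclass
class TurnoverNetwork:
    """Species totals, exclusives, and pairwise shared counts per group."""

    groups: list
    total_species: np.ndarray
    exclusive_species: np.ndarray
    shared: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.shared, index=self.groups, columns=self.groups)
        df.insert(0, "exclusive", self.exclusive_species)
        df.insert(0, "total", self.total_species)
        return df


def simpson_dissimilarity(table: OccurrenceTable) -> DissimilarityMatrix:
    """Pairwise βsim among all sites of an incidence table.

    Computed by incidence-matrix arithmetic: the shared-species counts
    for all pairs come from one matrix product, and ``b``/``c`` follow
    from the row richness.  Pairs with ``a + min(b, c) = 0`` (both sites
    empty of comparable species) score 0 by convention; empty sites are
    rejected outright since they should have been filtered.
    """
    if table.n_sites < 2:
        raise ValueError("need at least two sites")
    rich = table.richness()
    if np.any(rich == 0):
        raise ValueError("empty site rows present; run filter_localities first")
    x = table.incidence.astype(np.float64)
    a = x @ x.T
    b = rich[:, None] - a
    c = rich[None, :] - a
    m = np.minimum(b, c)
    denom = m + a
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against fp noise
    return DissimilarityMatrix(list(table.sites), d)


def simpson_pair(set_i: set, set_j: set) -> float:
    """βsim of two explicit species sets (reference implementation)."""
    a = len(set_i & set_j)
    b = len(set_i - set_j)
    c = len(set_j - set_i)
    m = min(b, c)
    return 0.0 if (m + a) == 0 else m / (m + a)


def shared_species_counts(table: OccurrenceTable, site_group) -> TurnoverNetwork:
    """Pool member sites per group and count total/exclusive/shared species.

    ``site_group`` maps every site_id to a group label (dict or pandas
    Series).  Group incidence is the union over member sites; shared
    counts come from set algebra on the pooled lists.
    """
    groups_of = dict(site_group) if not isinstance(site_group, dict) else site_group
    missing = [s for s in table.sites if s not in groups_of]
    if missing:
        raise ValueError(f"unlabeled sites: {missing[:5]}")
    labels = sorted(set(groups_of[s] for s in table.sites))
    g_idx = {g: i for i, g in enumerate(labels)}
    pooled = np.zeros((len(labels), table.n_species), dtype=np.uint8)
    for i, s in enumerate(table.sites):
        pooled[g_idx[groups_of[s]]] |= table.incidence[i]
    total = pooled.sum(axis=1).astype(int)
    shared = (pooled.astype(np.int64) @ pooled.T.astype(np.int64)).astype(int)
    n_groups_per_species = pooled.sum(axis=0)
    exclusive = np.array([int((pooled[i] & (n_groups_per_species == 1)).sum())
                          for i in range(len(labels))])
    return TurnoverNetwork(labels, total, exclusive, shared)


def pooled_incidence(table: OccurrenceTable, site_group) -> OccurrenceTable:
    """Group × species incidence obtained by pooling member sites."""
    net_groups = sorted(set(dict(site_group)[s] for s in table.sites))
    groups_of = dict(site_group)
    g_idx = {g: i for i, g in enumerate(net_groups)}
    pooled = np.zeros((len(net_groups), table.n_species), dtype=np.uint8)
    for i, s in enumerate(table.sites):
        pooled[g_idx[groups_of[s]]] |= table.incidence[i]
    return OccurrenceTable([str(g) for g in net_groups], list(table.species), pooled)
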