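"""Site registries and site-by-species incidence tables.

The pipeline's primary input is a long-format occurrence list of
(site_id, species_name) presences plus a registry of site coordinates in
decimal degrees.  Incidence is held as a dense binary matrix with sites
and species in lexicographic order so that every downstream result is
reproducible from the input files alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SiteRegistry", "OccurrenceTable", "read_occurrences",
           "read_registry", "filter_localities"]

logger = logging.getLogger(__name__)


@dataclass
class SiteRegistry:
    """Site identifiers with WGS84 coordinates."""

    site_ids: list[str]
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site_ids in registry")
        if np.any(np.abs(self.lon) > 180) or np.any(np.abs(self.lat) > 90):
            raise ValueError("coordinates outside valid lon/lat ranges")

    def __len__(self) -> int:
        return len(self.site_ids)

    def subset(self, site_ids: list[str]) -> "SiteRegistry":
        idx = {s: i for i, s in enumerate(self.site_ids)}
        rows = [idx[s] for s in site_ids]
        return SiteRegistry(list(site_ids), self.lon[rows], self.lat[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": self.site_ids,
                             "lon": self.lon, "lat": self.lat})


@dataclass
class OccurrenceTable:
    """Binary site × species incidence."""

    sites: list[str]
    species: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.sites), len(self.species)):
            raise ValueError("incidence shape does not match labels")
        uniq = np.unique(self.incidence)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("incidence must be binary")
        self.incidence = self.incidence.astype(np.uint8)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def richness(self) -> np.ndarray:
        return self.incidence.sum(axis=1).astype(int)

    def species_sets(self) -> list[set[str]]:
        sp = np.asarray(self.species, dtype=object)
        return [set(sp[row.astype(bool)]) for row in self.incidence]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.sites, columns=self.species)

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame) -> "OccurrenceTable":
        """Build from a two-column (site_id, species) frame of presences."""
        pairs = pairs.drop_duplicates()
        sites = sorted(pairs.iloc[:, 0].astype(str).unique())
        species = sorted(pairs.iloc[:, 1].astype(str).unique())
        si = {s: i for i, s in enumerate(sites)}
        pi = {p: i for i, p in enumerate(species)}
        inc = np.zeros((len(sites), len(species)), dtype=np.uint8)
        for s, p in zip(pairs.iloc[:, 0].astype(str), pairs.iloc[:, 1].astype(str)):
            inc[si[s], pi[p]] = 1
        return cls(sites, species, inc)


def read_occurrences(path) -> OccurrenceTable:
    """Read a long-format CSV of (site_id, species) presences.

    Duplicated rows collapse to a single presence.  Sites and species are
    ordered lexicographically.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("occurrence file must have site_id and species columns")
    cols = [c.lower() for c in df.columns]
    try:
        s_col = df.columns[cols.index("site_id")]
        p_col = df.columns[cols.index("species")]
    except ValueError as exc:
        raise ValueError("missing 'site_id' or 'species' column") from exc
    if df.empty:
        raise ValueError("occurrence file is empty")
    return OccurrenceTable.from_pairs(df[[s_col, p_col]])


def read_registry(path) -> SiteRegistry:
    """Read a CSV of site_id, lon, lat."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("site_id", "lon", "lat"):
        if need not in cols:
            raise ValueError(f"registry missing column '{need}'")
    df = df.sort_values(cols["site_id"], kind="stable")
    return SiteRegistry(list(df[cols["site_id"]].astype(str)),
                        df[cols["lon"]].to_numpy(float),
                        df[cols["lat"]].to_numpy(float))


def filter_localities(table: OccurrenceTable, min_species: int = 5) -> OccurrenceTable:
    """Drop sites with fewer than ``min_species`` species.

    Species left with zero occurrences after site removal are dropped as
    well.  The default of five species per locality follows standard
    practice for floristic compilations, where poorer lists say more
    about collection effort than about the community.
    """
    rich = table.richness()
    keep_sites = rich >= min_species
    if not np.any(keep_sites):
        raise ValueError("all sites removed by the richness filter")
    n_dropped = int((~keep_sites).sum())
    inc = table.incidence[keep_sites]
    keep_species = inc.sum(axis=0) > 0
    n_sp_dropped = int((~keep_species).sum())
    if n_dropped or n_sp_dropped:
        logger.info("filter_localities: dropped %d sites (<%d species) and %d "
                    "species with no remaining occurrences",
                    n_dropped, min_species, n_sp_dropped)
    sites = [s for s, k in zip(table.sites, keep_sites) if k]
    species = [p for p, k in zip(table.species, keep_species) if k]
    return OccurrenceTable(sites, species, inc[:, keep_species])
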