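"""Fading-record observation proxy: the alive-tree subset.

Tree-ring reconstructions only observe trees that were alive (and big
enough to core) at sampling time, so the early part of a stand's history
is systematically under-represented — dead trees left no cores.  This
module applies the same observation process to simulator output: for a
candidate coring year, it rebuilds the species basal-area history using
only the trees that would have been alive and larger than the coring
threshold in that year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gapsim import StandSimulation

__all__ = ["AliveSubsetTrajectory", "alive_tree_subset", "subset_table"]

#: Default coring threshold (cm DBH); trees at or below it are not cored.
DEFAULT_MIN_DBH = 10.0


@dataclass
class AliveSubsetTrajectory:
    """Species BA history reconstructed from trees alive and large at coring.

    ``ba[t-1]`` is the summed basal area at simulation year ``t`` (1-based,
    t <= coring_year) of exactly those trees that are alive in
    ``coring_year`` with DBH strictly above the coring threshold then.
    """

    species: str
    coring_year: int
    years: np.ndarray
    ba: np.ndarray
    n_trees: int

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ba = np.asarray(self.ba, dtype=float)
        if self.years.shape != self.ba.shape:
            raise ValueError("years and ba lengths differ")


def alive_tree_subset(
    stand: StandSimulation,
    coring_year: int,
    min_dbh: float = DEFAULT_MIN_DBH,
) -> dict[str, AliveSubsetTrajectory]:
    """Reconstruct per-species BA history from the coreable trees only.

    A tree contributes iff it is alive at ``coring_year`` (its death year,
    if any, is >= the coring year) and its DBH then strictly exceeds
    ``min_dbh``.  Each contributing tree's basal area is accumulated from
    its own increments back to its birth year, exactly as a ring-width
    reconstruction would.
    """
    if not (1 <= coring_year <= stand.n_years):
        raise ValueError(
            f"coring_year {coring_year} outside simulated span 1..{stand.n_years}"
        )
    years = np.arange(1, coring_year + 1)
    out: dict[str, AliveSubsetTrajectory] = {}
    for sp in sorted(stand.species_ba_by_year):
        ba = np.zeros(coring_year)
        n = 0
        for tree in stand.trees:
            if tree.species != sp or not tree.alive_in(coring_year):
                continue
            if tree.dbh_at(coring_year) <= min_dbh:
                continue
            n += 1
            stop = min(tree.last_year, coring_year)
            dbh = tree.dbh_by_year[: stop - tree.birth_year + 1]
            ba[tree.birth_year - 1: stop] += np.pi * (dbh / 2.0) ** 2
        out[sp] = AliveSubsetTrajectory(
            species=sp, coring_year=int(coring_year), years=years, ba=ba, n_trees=n
        )
    return out


def subset_table(subsets: dict[str, AliveSubsetTrajectory]) -> pd.DataFrame:
    """Tidy table (species, coring_year, year, ba_cm2, n_trees) of subsets."""
    rows = [pd.DataFrame({
        "species": s.species, "coring_year": s.coring_year,
        "year": s.years, "ba_cm2": s.ba, "n_trees": s.n_trees,
    }) for s in sorted(subsets.values(), key=lambda s: s.species)]
    if not rows:
        return pd.DataFrame(columns=["species", "coring_year", "year", "ba_cm2", "n_trees"])
    return pd.concat(rows, ignore_index=True)
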