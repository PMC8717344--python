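"""Ring-width processing: basal-area increment and species totals.

Converts per-tree ring-width series (mm/yr) into basal-area increments via
the outside-in radius assignment, applies the missing-outer-ring exclusion,
and accumulates species-level basal-area trajectories per site.  Readers
are provided for a tidy CSV layout and for Tucson-style decadal ring-width
text (.rwl).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "FieldBASeries",
    "MissingOuterRingError",
    "effective_radius",
    "basal_area_increment",
    "species_ba_trajectory",
    "read_rings_csv",
    "read_tucson",
    "write_field_series_csv",
    "read_field_series_csv",
]

logger = logging.getLogger(__name__)

MM_PER_CM = 10.0


class MissingOuterRingError(ValueError):
    """Raised when a core lacks its outermost ring and must be excluded."""


@dataclass
class RingSeries:
    """One increment core: annual ring widths plus tree metadata.

    Widths are stored innermost-to-outermost in mm; ``years`` are the
    matching calendar years, strictly increasing by one.  ``diam_at_core``
    is the tree's diameter at coring height (cm) and ``bark_width`` the
    average bark thickness (cm).
    """

    tree_id: str
    species: str
    site_id: str
    years: np.ndarray
    widths: np.ndarray  # mm per year
    diam_at_core: float = 0.0
    bark_width: float = 0.0
    outer_ring_present: bool = True

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.years.shape != self.widths.shape:
            raise ValueError(
                f"{self.tree_id}: years and widths lengths differ "
                f"({len(self.years)} vs {len(self.widths)})"
            )
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValueError(f"{self.tree_id}: years must increase by exactly 1")
        if np.any(self.widths <= 0):
            raise ValueError(f"{self.tree_id}: ring widths must be positive")

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class FieldBASeries:
    """Species basal-area trajectory at one site (observed or synthetic).

    ``ba`` holds basal area (cm^2) per year; ``sigma_eps`` the known noise
    SD for synthetic series; ``truth`` optional hidden generating metadata
    (true parameters, coring year) used by recovery experiments.
    """

    site_id: str
    species: str
    years: np.ndarray
    ba: np.ndarray
    sigma_eps: float | None = None
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ba = np.asarray(self.ba, dtype=float)
        if self.years.shape != self.ba.shape:
            raise ValueError("years and ba lengths differ")
        if np.any(self.ba < 0):
            raise ValueError("basal area must be >= 0")

    def __len__(self) -> int:
        return len(self.ba)


def effective_radius(rs: RingSeries) -> float:
    """Tree radius (cm) used for the outside-in reconstruction.

    The larger of the ring-width sum and the measured radius
    ``diam_at_core/2 - bark_width``; the ring-width sum is the fallback
    when the measured radius is smaller (e.g. shrunken or damaged cores).
    """
    if len(rs) == 0:
        raise ValueError(f"{rs.tree_id}: series has no rings")
    ring_sum_cm = float(np.sum(rs.widths)) / MM_PER_CM
    measured_cm = rs.diam_at_core / 2.0 - rs.bark_width
    r = max(ring_sum_cm, measured_cm)
    if r <= 0:
        raise ValueError(f"{rs.tree_id}: nonpositive effective radius {r}")
    return r


def basal_area_increment(rs: RingSeries) -> np.ndarray:
    """Annual basal-area increments (cm^2) via the outside-in approach.

    The outermost ring year gets the effective radius; each earlier radius
    is obtained by subtracting that year's ring width.  Cores with missing
    outer rings cannot be anchored and are excluded.
    """
    if not rs.outer_ring_present:
        raise MissingOuterRingError(
            f"{rs.tree_id}: core is missing its outer ring and was not used"
        )
    r_outer = effective_radius(rs)
    w_cm = rs.widths / MM_PER_CM
    # radius at the end of each ring year, outside-in
    radii = r_outer - (np.cumsum(w_cm[::-1])[::-1] - w_cm)
    inner = radii - w_cm
    bai = np.pi * (radii**2 - inner**2)
    return bai


def species_ba_trajectory(
    series_set: Iterable[RingSeries],
    site_id: str,
) -> dict[str, FieldBASeries]:
    """Cumulative species basal-area trajectories from a set of cores.

    Per species, BA(t) is the sum over trees of all basal-area increments
    laid down in years <= t, so the trajectory is the growing stand basal
    area of the cored trees.  Series from other sites are rejected; series
    failing the outer-ring filter must already have been excluded.
    """
    series = list(series_set)
    if not series:
        logger.warning("species_ba_trajectory: empty series collection for site %s", site_id)
        return {}
    by_species: dict[str, list[RingSeries]] = {}
    for rs in series:
        if rs.site_id != site_id:
            raise ValueError(f"series {rs.tree_id} belongs to site {rs.site_id!r}, not {site_id!r}")
        by_species.setdefault(rs.species, []).append(rs)

    out: dict[str, FieldBASeries] = {}
    for sp, group in sorted(by_species.items()):
        y0 = min(int(rs.years[0]) for rs in group)
        y1 = max(int(rs.years[-1]) for rs in group)
        years = np.arange(y0, y1 + 1)
        annual = np.zeros(len(years))
        for rs in group:
            bai = basal_area_increment(rs)
            annual[rs.years - y0] += bai
        out[sp] = FieldBASeries(site_id=site_id, species=sp, years=years,
                                ba=np.cumsum(annual))
    return out


def read_rings_csv(path) -> list[RingSeries]:
    """Read ring series from a tidy CSV (one row per tree-year).

    Required columns: tree_id, species, site_id, year, width_mm.
    Optional per-tree columns: diam_at_core_cm, bark_width_cm,
    outer_ring_present (defaults 0, 0, True).
    """
    df = pd.read_csv(path)
    required = {"tree_id", "species", "site_id", "year", "width_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for tree_id, grp in df.groupby("tree_id", sort=True):
        grp = grp.sort_values("year")
        first = grp.iloc[0]
        out.append(RingSeries(
            tree_id=str(tree_id),
            species=str(first["species"]),
            site_id=str(first["site_id"]),
            years=grp["year"].to_numpy(),
            widths=grp["width_mm"].to_numpy(),
            diam_at_core=float(first.get("diam_at_core_cm", 0.0) or 0.0),
            bark_width=float(first.get("bark_width_cm", 0.0) or 0.0),
            outer_ring_present=bool(first.get("outer_ring_present", True)),
        ))
    return out


def read_tucson(
    path,
    metadata: Mapping[str, Mapping] | pd.DataFrame | None = None,
) -> list[RingSeries]:
    """Read Tucson-style decadal ring-width text (.rwl).

    Each line: series id (cols 1-8), decade year, then up to ten width
    values.  A stop marker of 999 signals units of 0.01 mm, -9999 units of
    0.001 mm.  The format carries no tree metadata, so ``metadata`` may map
    series id -> dict with species, site_id, diam_at_core_cm,
    bark_width_cm, outer_ring_present.  Malformed lines raise with their
    line number.
    """
    if isinstance(metadata, pd.DataFrame):
        metadata = {str(r["tree_id"]): r for _, r in metadata.iterrows()}
    metadata = metadata or {}

    raw: dict[str, dict[int, float]] = {}
    scale: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise ValueError(f"{path}:{lineno}: malformed decadal line")
            try:
                decade = int(rest[0])
                values = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            store = raw.setdefault(sid, {})
            for i, v in enumerate(values):
                if v == 999:
                    scale[sid] = 0.01
                    break
                if v == -9999:
                    scale[sid] = 0.001
                    break
                year = decade + i
                if year in store:
                    raise ValueError(f"{path}:{lineno}: duplicate year {year} for {sid}")
                store[year] = float(v)

    out = []
    for sid in sorted(raw):
        if sid not in scale:
            raise ValueError(f"{path}: series {sid} has no stop marker (999/-9999)")
        years = np.array(sorted(raw[sid]))
        if len(years) > 1 and np.any(np.diff(years) != 1):
            raise ValueError(f"{path}: series {sid} has non-contiguous years")
        widths = np.array([raw[sid][y] for y in years]) * scale[sid]
        meta = dict(metadata.get(sid, {}))
        out.append(RingSeries(
            tree_id=sid,
            species=str(meta.get("species", "UNK")),
            site_id=str(meta.get("site_id", "UNK")),
            years=years,
            widths=widths,
            diam_at_core=float(meta.get("diam_at_core_cm", 0.0)),
            bark_width=float(meta.get("bark_width_cm", 0.0)),
            outer_ring_present=bool(meta.get("outer_ring_present", True)),
        ))
    return out


def write_field_series_csv(series: Mapping[str, FieldBASeries] | Iterable[FieldBASeries], path) -> None:
    """Write field basal-area series to a tidy CSV (site_id, species, year, ba_cm2)."""
    if isinstance(series, Mapping):
        series = list(series.values())
    rows = [pd.DataFrame({
        "site_id": fs.site_id, "species": fs.species,
        "year": fs.years, "ba_cm2": fs.ba,
    }) for fs in series]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_field_series_csv(path) -> dict[tuple[str, str], FieldBASeries]:
    """Read field basal-area series written by :func:`write_field_series_csv`."""
    df = pd.read_csv(path)
    out = {}
    for (site, sp), grp in df.groupby(["site_id", "species"], sort=True):
        grp = grp.sort_values("year")
        out[(str(site), str(sp))] = FieldBASeries(
            site_id=str(site), species=str(sp),
            years=grp["year"].to_numpy(), ba=grp["ba_cm2"].to_numpy(),
        )
    return out
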