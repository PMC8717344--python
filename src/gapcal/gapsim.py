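"""Toy individual-based forest gap simulator.

A deliberately small gap model in the JABOWA/FORET lineage: every tree is
tracked individually, grows an annual diameter increment gated by growing
degree-days, and dies either from background mortality tied to its species'
life expectancy or from stress mortality after repeated years of
below-minimum growth.  Stands start from bare ground and are driven by
monthly climate drawn from climate normals.

The simulator exists to generate realistic multi-species basal-area
trajectories whose response to the calibratable traits (``g``, ``dbh_min``)
is monotone, so that the downstream proxy/selection/calibration stages can
be exercised and validated end to end on data with known ground truth.

Growth uses the classic gap-model logistic kernel
``g * D * (1 - D / Dmax) * resource_factor``; background mortality uses the
standard convention ``p_bg = 4.605 / max_age`` under which roughly 1% of a
cohort reaches its species' maximum age.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ringproc import FieldBASeries

__all__ = [
    "SpeciesParams",
    "ClimateNormals",
    "SiteConditions",
    "TreeRecord",
    "StandSimulation",
    "growing_degree_days",
    "annual_dbh_increment",
    "step_mortality",
    "mortality_draws",
    "run_stand",
    "synth_field_data",
    "GDD_BASE_C",
    "BACKGROUND_MORTALITY_CONSTANT",
    "RECRUIT_DBH_CM",
]

#: Base temperature for growing degree-days (deg C).
GDD_BASE_C = 5.0

#: -ln(0.01): background hazard scaling so ~1% of trees reach max_age.
BACKGROUND_MORTALITY_CONSTANT = 4.605

#: DBH assigned to a newly recruited sapling (cm).
RECRUIT_DBH_CM = 1.0

_DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)


@dataclass(frozen=True)
class SpeciesParams:
    """Calibratable trait vector for one species.

    Parameters
    ----------
    name : str
        Species label (e.g. ``"PIGL"`` for *Picea glauca*).
    g : float
        Maximum growth scalar controlling the speed of early DBH increment
        growth (cm/yr scale).
    dbh_min : float
        Minimum annual DBH increment (cm/yr); below it the tree is
        "stressed" and, after at least two consecutive stressed years,
        eligible for stress mortality.
    max_age : float
        Life expectancy (yr); sets the annual background mortality rate.
    dd_min : float
        Minimum growing degree-days (base 5 degC) required for any growth.
    dmax : float
        Maximum attainable DBH (cm).
    p_stress : float
        Annual stress-mortality probability once stressed; constrained to
        the empirical range [0.21, 0.33].
    recruit_rate : float
        Expected new saplings per year (Poisson rate).
    growth_sd : float
        SD of the per-tree lognormal growth multiplier (individual vigor).
        Individuals of the same cohort differ in microsite and genetics, so
        their increments scatter around the species kernel; this is also
        what makes the stress threshold ``dbh_min`` act gradually on a
        population instead of as an all-or-nothing cliff.
    """

    name: str
    g: float = 0.25
    dbh_min: float = 0.08
    max_age: float = 250.0
    dd_min: float = 280.0
    dmax: float = 60.0
    p_stress: float = 0.27
    recruit_rate: float = 3.0
    growth_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError(f"{self.name}: g must be > 0, got {self.g}")
        if self.dbh_min < 0:
            raise ValueError(f"{self.name}: dbh_min must be >= 0, got {self.dbh_min}")
        if self.max_age <= 0:
            raise ValueError(f"{self.name}: max_age must be > 0, got {self.max_age}")
        if self.dd_min < 0:
            raise ValueError(f"{self.name}: dd_min must be >= 0, got {self.dd_min}")
        if self.dmax <= 0:
            raise ValueError(f"{self.name}: dmax must be > 0, got {self.dmax}")
        if not (0.21 <= self.p_stress <= 0.33):
            raise ValueError(
                f"{self.name}: p_stress must lie in [0.21, 0.33], got {self.p_stress}"
            )
        if self.recruit_rate < 0:
            raise ValueError(f"{self.name}: recruit_rate must be >= 0")
        if self.growth_sd < 0:
            raise ValueError(f"{self.name}: growth_sd must be >= 0")

    @property
    def p_background(self) -> float:
        """Annual background mortality probability, 4.605 / max_age."""
        return BACKGROUND_MORTALITY_CONSTANT / self.max_age

    def replace(self, **kwargs) -> "SpeciesParams":
        """Return a copy with the given fields substituted (re-validated)."""
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ClimateNormals:
    """Monthly climate normals (mean and SD of temperature and precipitation)."""

    monthly_temp_mean: np.ndarray
    monthly_temp_sd: np.ndarray
    monthly_precip_mean: np.ndarray
    monthly_precip_sd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("monthly_temp_mean", "monthly_temp_sd",
                     "monthly_precip_mean", "monthly_precip_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 values, got shape {arr.shape}")
            object.__setattr__(self, name, arr)
        if np.any(self.monthly_temp_sd < 0) or np.any(self.monthly_precip_sd < 0):
            raise ValueError("climate normal SDs must be >= 0")

    @classmethod
    def boreal_interior(cls) -> "ClimateNormals":
        """Normals loosely typical of interior-Alaska boreal forest."""
        temp = np.array([-20.0, -17.0, -10.0, 0.0, 8.0, 14.0, 16.0, 13.0, 7.0, -3.0, -14.0, -19.0])
        temp_sd = np.full(12, 2.0)
        precip = np.array([15.0, 12.0, 10.0, 12.0, 20.0, 35.0, 55.0, 50.0, 35.0, 25.0, 20.0, 18.0])
        precip_sd = np.full(12, 8.0)
        return cls(temp, temp_sd, precip, precip_sd)


@dataclass(frozen=True)
class SiteConditions:
    """One-knob stand-in for site resource limitation.

    ``resource_factor`` multiplies every increment (light/water/nutrient
    limitation folded into a single scalar); ``gdd_offset`` shifts the
    annual degree-day sum (elevation / aspect effect).
    """

    site_id: str = "SITE"
    resource_factor: float = 1.0
    gdd_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.resource_factor <= 1):
            raise ValueError("resource_factor must lie in (0, 1]")


@dataclass
class TreeRecord:
    """Per-tree life history from one simulation.

    ``dbh_by_year`` covers simulation years ``birth_year..last_year`` where
    ``last_year`` is ``death_year`` for dead trees and the final simulated
    year otherwise.  ``death_year is None`` means the tree survived the run.
    """

    tree_id: str
    species: str
    birth_year: int
    death_year: int | None
    dbh_by_year: np.ndarray
    stress_counter: int = 0

    @property
    def last_year(self) -> int:
        return self.birth_year + len(self.dbh_by_year) - 1

    def dbh_at(self, year: int) -> float:
        """DBH (cm) in a given simulation year; raises if outside the lifespan."""
        if not (self.birth_year <= year <= self.last_year):
            raise ValueError(
                f"tree {self.tree_id} has no DBH for year {year} "
                f"(alive {self.birth_year}..{self.last_year})"
            )
        return float(self.dbh_by_year[year - self.birth_year])

    def alive_in(self, year: int) -> bool:
        end = self.last_year if self.death_year is None else self.death_year
        return self.birth_year <= year <= end


@dataclass
class StandSimulation:
    """Result of one seeded bare-ground stand simulation."""

    trees: list[TreeRecord]
    species_ba_by_year: dict[str, np.ndarray]
    years: np.ndarray
    seed: int
    params_used: dict[str, SpeciesParams]
    site: SiteConditions = field(default_factory=SiteConditions)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def recompute_ba(self) -> dict[str, np.ndarray]:
        """Recompute species basal area per year directly from tree DBHs."""
        out = {sp: np.zeros(self.n_years) for sp in self.species_ba_by_year}
        for tree in self.trees:
            end = tree.last_year if tree.death_year is None else tree.death_year
            idx = np.arange(tree.birth_year, end + 1) - 1
            dbh = tree.dbh_by_year[: end - tree.birth_year + 1]
            out[tree.species][idx] += np.pi * (dbh / 2.0) ** 2
        return out

    def tree_table(self) -> pd.DataFrame:
        """Tidy per-tree-per-year table (tree_id, species, year, dbh_cm, bai_cm2, alive)."""
        rows = []
        for tree in self.trees:
            years = np.arange(tree.birth_year, tree.last_year + 1)
            dbh = tree.dbh_by_year
            prev = np.concatenate([[0.0], dbh[:-1]])
            bai = np.pi * ((dbh / 2.0) ** 2 - (prev / 2.0) ** 2)
            end = tree.last_year if tree.death_year is None else tree.death_year
            rows.append(pd.DataFrame({
                "tree_id": tree.tree_id,
                "species": tree.species,
                "year": years,
                "dbh_cm": dbh,
                "bai_cm2": bai,
                "alive": years <= end,
            }))
        if not rows:
            return pd.DataFrame(
                columns=["tree_id", "species", "year", "dbh_cm", "bai_cm2", "alive"]
            )
        return pd.concat(rows, ignore_index=True)

    def ba_table(self) -> pd.DataFrame:
        """Tidy per-species-per-year basal area table."""
        rows = []
        for sp, ba in sorted(self.species_ba_by_year.items()):
            rows.append(pd.DataFrame({"species": sp, "year": self.years, "ba_cm2": ba}))
        return pd.concat(rows, ignore_index=True)


def growing_degree_days(
    monthly_temps: Sequence[float],
    days_per_month: Sequence[float] | None = None,
) -> float:
    """Annual growing degree-days: sum of max(0, T_m - 5degC) * days_m.

    A monthly approximation of the daily thermal sum; months whose mean is
    below the 5 degC base contribute nothing.
    """
    temps = np.asarray(monthly_temps, dtype=float)
    days = _DAYS_PER_MONTH if days_per_month is None else np.asarray(days_per_month, dtype=float)
    if temps.shape != (12,):
        raise ValueError(f"expected 12 monthly temperatures, got shape {temps.shape}")
    if days.shape != (12,):
        raise ValueError(f"expected 12 day counts, got shape {days.shape}")
    if np.any(days <= 0):
        raise ValueError("day counts must be positive")
    return float(np.sum(np.maximum(0.0, temps - GDD_BASE_C) * days))


def annual_dbh_increment(
    dbh: float | np.ndarray,
    sp: SpeciesParams,
    gdd: float,
    site: SiteConditions,
) -> float | np.ndarray:
    """Annual DBH increment (cm) for one or many trees of a species.

    Zero when the year's degree-day sum (plus site offset) falls below the
    species' ``dd_min`` gate, otherwise the logistic kernel
    ``g * D * (1 - D/dmax) * resource_factor`` clipped at zero.
    """
    dbh_arr = np.asarray(dbh, dtype=float)
    if np.any(dbh_arr <= 0):
        raise ValueError("dbh must be positive")
    if gdd + site.gdd_offset < sp.dd_min:
        inc = np.zeros_like(dbh_arr)
    else:
        inc = sp.g * dbh_arr * (1.0 - dbh_arr / sp.dmax) * site.resource_factor
        inc = np.maximum(inc, 0.0)
    return float(inc) if np.isscalar(dbh) else inc


def mortality_draws(
    stress_counters: np.ndarray,
    sp: SpeciesParams,
    increments: np.ndarray,
    uniforms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised annual stress accounting and mortality decision.

    Parameters
    ----------
    stress_counters : int array
        Consecutive below-minimum-growth years entering this year.
    increments : float array
        This year's DBH increments (cm).
    uniforms : (n, 2) float array
        Independent U(0,1) draws: column 0 decides background mortality,
        column 1 stress mortality.

    Returns
    -------
    dies : bool array
    new_counters : int array
        Updated stress counters (incremented on a below-minimum year,
        reset to zero otherwise).
    """
    stress_counters = np.asarray(stress_counters)
    increments = np.asarray(increments, dtype=float)
    uniforms = np.asarray(uniforms, dtype=float)
    new_counters = np.where(increments < sp.dbh_min, stress_counters + 1, 0)
    dies_bg = uniforms[..., 0] < sp.p_background
    dies_stress = (new_counters >= 2) & (uniforms[..., 1] < sp.p_stress)
    return dies_bg | dies_stress, new_counters


def step_mortality(
    tree: TreeRecord,
    sp: SpeciesParams,
    increment: float,
    rng: np.random.Generator,
    year: int | None = None,
) -> bool:
    """Apply one year of mortality to a single tree; returns True if it survives.

    Background mortality (probability ``4.605/max_age``) applies every year;
    stress mortality (probability ``p_stress``) additionally applies once the
    tree has grown below ``dbh_min`` for at least two consecutive years.
    On death, ``death_year`` is set (to ``year`` when given, else the last
    recorded year).
    """
    dies, counters = mortality_draws(
        np.array([tree.stress_counter]), sp, np.array([increment]), rng.random((1, 2))
    )
    tree.stress_counter = int(counters[0])
    if dies[0]:
        tree.death_year = int(year) if year is not None else tree.last_year
        return False
    return True


class _SpeciesState:
    """Growing arrays for one species during a simulation."""

    def __init__(self, sp: SpeciesParams, n_years: int, recruit_counts: np.ndarray,
                 seed: int, sp_index: int):
        self.sp = sp
        self.n_years = n_years
        n_total = int(recruit_counts.sum())
        self.birth = np.repeat(np.arange(1, n_years + 1), recruit_counts)
        self.death = np.full(n_total, -1)  # -1 = alive at end
        self.dbh = np.full((n_total, n_years), np.nan)
        self.stress = np.zeros(n_total, dtype=int)
        # Per-tree uniforms keyed by (seed, species index, tree index) so a
        # tree's mortality draws do not depend on how many neighbours are
        # alive: common-random-number coupling across parameter values.
        if n_total:
            seqs = np.random.SeedSequence(entropy=(int(seed), int(sp_index))).spawn(n_total)
            rngs = [np.random.default_rng(s) for s in seqs]
            self.uniforms = np.stack([r.random((n_years, 2)) for r in rngs])
            self.growth_mult = np.exp(
                sp.growth_sd * np.array([r.standard_normal() for r in rngs])
            )
        else:
            self.uniforms = np.zeros((0, n_years, 2))
            self.growth_mult = np.zeros(0)


def run_stand(
    params: Sequence[SpeciesParams] | Mapping[str, SpeciesParams],
    site: SiteConditions,
    normals: ClimateNormals,
    years: int,
    seed: int,
) -> StandSimulation:
    """Simulate one stand from bare ground for ``years`` years.

    Each year: draw monthly climate from the normals, grow every living
    tree, apply stress and background mortality, then recruit
    Poisson(recruit_rate) saplings at 1 cm DBH.  Deterministic given
    ``seed``.  Simulation years are 1-based; a tree recruited in year t has
    its first DBH recorded at t.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    if isinstance(params, Mapping):
        species = [params[k] for k in sorted(params)]
    else:
        species = sorted(params, key=lambda p: p.name)
    if not species:
        raise ValueError("at least one species is required")
    if len({p.name for p in species}) != len(species):
        raise ValueError("duplicate species names")

    root = np.random.SeedSequence(int(seed))
    climate_ss, recruit_ss = root.spawn(2)
    climate_rng = np.random.default_rng(climate_ss)
    temps = (normals.monthly_temp_mean
             + climate_rng.standard_normal((years, 12)) * normals.monthly_temp_sd)
    # Precipitation is drawn to keep the climate stream complete even though
    # the toy growth kernel does not consume it (water limitation is folded
    # into SiteConditions.resource_factor).
    _ = (normals.monthly_precip_mean
         + climate_rng.standard_normal((years, 12)) * normals.monthly_precip_sd)
    gdd_by_year = np.array([growing_degree_days(temps[t]) for t in range(years)])

    recruit_rngs = {p.name: np.random.default_rng(s)
                    for p, s in zip(species, recruit_ss.spawn(len(species)))}
    states: dict[str, _SpeciesState] = {}
    for i, sp in enumerate(species):
        counts = recruit_rngs[sp.name].poisson(sp.recruit_rate, size=years)
        states[sp.name] = _SpeciesState(sp, years, counts, seed, i)

    for t in range(1, years + 1):
        gdd = gdd_by_year[t - 1]
        for sp in species:
            st = states[sp.name]
            grown = (st.birth < t) & ((st.death == -1) | (st.death >= t))
            if grown.any():
                prev = st.dbh[grown, t - 2]
                # individual vigor scales the species kernel
                inc = annual_dbh_increment(prev, sp, gdd, site) * st.growth_mult[grown]
                st.dbh[grown, t - 1] = prev + inc
                dies, counters = mortality_draws(
                    st.stress[grown], sp, inc, st.uniforms[grown, t - 1, :]
                )
                st.stress[grown] = counters
                idx = np.flatnonzero(grown)
                st.death[idx[dies]] = t
            born = st.birth == t
            st.dbh[born, t - 1] = RECRUIT_DBH_CM

    trees: list[TreeRecord] = []
    ba = {sp.name: np.zeros(years) for sp in species}
    for sp in species:
        st = states[sp.name]
        for k in range(len(st.birth)):
            b = int(st.birth[k])
            d = None if st.death[k] == -1 else int(st.death[k])
            end = years if d is None else d
            traj = st.dbh[k, b - 1: end]
            trees.append(TreeRecord(
                tree_id=f"{sp.name}_{k:04d}",
                species=sp.name,
                birth_year=b,
                death_year=d,
                dbh_by_year=traj.copy(),
                stress_counter=int(st.stress[k]),
            ))
            ba[sp.name][b - 1: end] += np.pi * (traj / 2.0) ** 2

    return StandSimulation(
        trees=trees,
        species_ba_by_year=ba,
        years=np.arange(1, years + 1),
        seed=int(seed),
        params_used={sp.name: sp for sp in species},
        site=site,
    )


def synth_field_data(
    stand: StandSimulation,
    coring_year: int,
    min_dbh: float = 10.0,
    sigma_eps: float = 0.0,
    bias_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int | None = None,
) -> dict[str, FieldBASeries]:
    """Generate synthetic "field" basal-area series from a simulated stand.

    Applies the fading-record observation process (alive-tree subset at
    ``coring_year``), then an optional smooth bias ``bias_fn(t)`` and i.i.d.
    Gaussian noise with SD ``sigma_eps`` (cm^2), clipping at zero.  The
    generating parameters and coring year are stored as hidden truth for
    recovery experiments.
    """
    from .fading_proxy import alive_tree_subset

    if not (1 <= coring_year <= stand.n_years):
        raise ValueError(
            f"coring_year {coring_year} outside simulated span 1..{stand.n_years}"
        )
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be >= 0")
    rng = np.random.default_rng(seed)
    subsets = alive_tree_subset(stand, coring_year, min_dbh=min_dbh)
    out: dict[str, FieldBASeries] = {}
    for sp_name, subset in sorted(subsets.items()):
        ys = subset.ba.copy()
        measured = subset.ba > 0  # no rings exist before the oldest tree
        if bias_fn is not None:
            ys = ys + measured * np.asarray(
                bias_fn(subset.years.astype(float)), dtype=float)
        if sigma_eps > 0:
            noise = rng.normal(0.0, sigma_eps, size=len(ys))
            ys = ys + measured * noise
        ys = np.maximum(ys, 0.0)
        out[sp_name] = FieldBASeries(
            site_id=stand.site.site_id,
            species=sp_name,
            years=subset.years.copy(),
            ba=ys,
            sigma_eps=sigma_eps,
            truth={
                "coring_year": int(coring_year),
                "params": {k: dataclasses.asdict(v) for k, v in stand.params_used.items()},
                "seed": stand.seed,
                "min_dbh": float(min_dbh),
            },
        )
    return out
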