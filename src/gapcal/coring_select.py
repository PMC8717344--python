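"""Optimal coring-year selection by GAM/AIC scan.

Field tree-ring reconstructions are anchored in calendar time but not in
successional time: the stand's age when the cores were taken is unknown.
To place the field record inside a bare-ground simulation, every candidate
simulation year is treated as a possible coring year; the alive-tree
subset at that year is compared to the field series with a penalized
additive model scored by AIC, and the per-simulation argmin years are
combined across an ensemble of stands by their median — the site's
optimal coring time — which doubles as a stand-age estimate.

The additive model works on log(1 + BA): basal area is positive and
multiplicative, and the log scale weights the young, small-BA end of the
record — where candidate coring ages differ most — on equal terms with
the mature end.  The subset enters as an offset (slope fixed at one: the
two series are the same physical quantity in the same units) and the
smooth of time, which absorbs residual temporal structure, carries a
ridge penalty on all of its coefficients.  The ridge (rather than a
curvature penalty) is deliberate: a curvature penalty leaves linear
trends free, and a free trend would absorb exactly the successional
signal that distinguishes candidate coring ages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines

from .fading_proxy import DEFAULT_MIN_DBH, AliveSubsetTrajectory, alive_tree_subset
from .gapsim import StandSimulation
from .ringproc import FieldBASeries

__all__ = [
    "CoringScan",
    "StandAgeEstimate",
    "DegenerateFitError",
    "InsufficientOverlapError",
    "score_coring_year",
    "optimal_coring_time",
]

logger = logging.getLogger(__name__)

#: Minimum overlapping years between field record and subset trajectory.
MIN_OVERLAP = 8

#: AIC range below which the candidate scan is flagged as unstable (the
#: classic "indistinguishable models" unit is ~2 AIC points).
AIC_STABILITY_RANGE = 2.0

#: Floor on the residual variance entering the Gaussian log-likelihood, so
#: that an exact fit yields a very negative but finite AIC.
_SCALE_FLOOR = 1e-12


class DegenerateFitError(ValueError):
    """Raised when the subset predictor has zero variance."""


class InsufficientOverlapError(ValueError):
    """Raised when field and subset series overlap fewer than MIN_OVERLAP years."""


@dataclass
class CoringScan:
    """AIC scan over candidate coring years for an ensemble of stands."""

    table: pd.DataFrame  # columns: stand, candidate_year, aic
    argmin_by_stand: dict[int, int]
    site_optimal_year: float
    tie_stands: list[int] = field(default_factory=list)
    unstable_stands: list[int] = field(default_factory=list)
    skipped: list[tuple[int, int, str]] = field(default_factory=list)


@dataclass
class StandAgeEstimate:
    """Stand age inferred from the optimal-coring-year procedure.

    ``chronology_age`` is what the ring records alone would suggest (the
    longest record length); ``stand_age_samples`` are the per-simulation
    optimal coring years, i.e. candidate ages of the stand since bare
    ground.
    """

    site_id: str
    chronology_age: int
    stand_age_samples: np.ndarray
    quantiles: dict[str, float]

    @classmethod
    def from_samples(cls, site_id: str, chronology_age: int,
                     samples: Sequence[int]) -> "StandAgeEstimate":
        arr = np.asarray(samples, dtype=float)
        qs = np.quantile(arr, [0.025, 0.25, 0.5, 0.75, 0.975])
        return cls(site_id=site_id, chronology_age=int(chronology_age),
                   stand_age_samples=arr,
                   quantiles=dict(zip(["q025", "q25", "q50", "q75", "q975"], map(float, qs))))


def _noise_floor(fs: FieldBASeries) -> float:
    """Basal area below which a record value is indistinguishable from noise.

    Three noise SDs when the record carries a known noise level, else
    1 cm^2 (ring widths are measured to sub-millimetre precision, so a
    noise-free record is resolved essentially down to zero).
    """
    if fs.sigma_eps:
        return max(1.0, 3.0 * float(fs.sigma_eps))
    return 1.0


def _chronology_age(fs: FieldBASeries) -> int:
    """Years spanned by the record from its first resolvable basal area.

    Synthetic alive-subset records carry leading zero years before the
    oldest surviving tree's birth; a real ring chronology starts at the
    innermost measured ring, so the comparable age is the span from the
    first value above the noise floor.
    """
    pos = np.flatnonzero(fs.ba > _noise_floor(fs))
    return int(len(fs.ba) - pos[0]) if len(pos) else 0


def _gaussian_llf(resid: np.ndarray) -> float:
    n = len(resid)
    scale = max(float(np.mean(resid**2)), _SCALE_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * scale) + 1.0)


@lru_cache(maxsize=64)
def _spline_basis(n: int, df: int) -> np.ndarray:
    t = np.arange(n, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return BSplines(t[:, None], df=[df], degree=[3]).basis


def _fit_one_species(y: np.ndarray, x: np.ndarray, basis_df: int,
                     alpha: float, floor: float = 1.0) -> tuple[float, float]:
    """Penalized additive fit of field BA on (subset BA, smooth of time).

    Both series are censored at the noise floor and log-transformed; the
    subset is an offset (slope one) and the residual log-ratio is smoothed
    by a B-spline basis under a ridge penalty ``alpha`` on every
    coefficient.  Returns (log-likelihood, effective df); the Gaussian
    log-likelihood uses a floored scale so an exact fit stays finite.
    """
    n = len(y)
    if np.ptp(x) <= 0:
        raise DegenerateFitError("subset predictor has zero variance")
    df = int(max(4, min(basis_df, n - 3)))
    B = _spline_basis(n, df)
    z = np.log(np.maximum(y, floor)) - np.log(np.maximum(x, floor))
    A = B.T @ B + alpha * np.eye(B.shape[1])
    coef = np.linalg.solve(A, B.T @ z)
    edf = float(np.trace(np.linalg.solve(A, B.T @ B)))
    resid = z - B @ coef
    return _gaussian_llf(resid), edf


def _trim_leading_zeros(fs: FieldBASeries) -> np.ndarray:
    """Field BA from the first resolvable (above-noise-floor) year onward."""
    pos = np.flatnonzero(fs.ba > _noise_floor(fs))
    return fs.ba[pos[0]:] if len(pos) else fs.ba[:0]


def score_coring_year(
    field_series: Mapping[str, FieldBASeries],
    subsets: Mapping[str, AliveSubsetTrajectory],
    basis_df: int = 10,
    alpha: float = 10.0,
) -> float:
    """AIC of the candidate coring year implied by ``subsets``.

    The subset's coring year is aligned to the field record's final year.
    Every candidate is scored on the same observations — the field
    record's ring-bearing span — so AIC values are comparable across
    candidates: a candidate younger than the record has its subset
    left-padded with zeros (no stand existed before bare ground).  One GAM
    is fitted per species present in both inputs and the species
    log-likelihoods and effective dfs are summed:
    ``AIC = 2 * total_edf - 2 * total_llf``.
    """
    total_llf = 0.0
    total_edf = 0.0
    n_fit = 0
    for sp in sorted(field_series):
        if sp not in subsets:
            continue
        fs, sub = field_series[sp], subsets[sp]
        y = _trim_leading_zeros(fs)
        L = len(y)
        if L < MIN_OVERLAP:
            raise InsufficientOverlapError(
                f"{sp}: field record has only {L} ring-bearing years (< {MIN_OVERLAP})"
            )
        x = sub.ba
        if len(x) < L:
            x = np.concatenate([np.zeros(L - len(x)), x])
        x = x[-L:]
        llf, edf = _fit_one_species(y, x, basis_df, alpha, floor=_noise_floor(fs))
        total_llf += llf
        total_edf += edf
        n_fit += 1
    if n_fit == 0:
        raise ValueError("no species shared between field series and subsets")
    return 2.0 * total_edf - 2.0 * total_llf


def optimal_coring_time(
    stands: Sequence[StandSimulation],
    field_series: Mapping[str, FieldBASeries],
    candidate_years: Sequence[int] | None = None,
    min_dbh: float = DEFAULT_MIN_DBH,
    stride: int = 1,
    basis_df: int = 10,
    alpha: float = 10.0,
    site_id: str = "SITE",
    min_candidate_year: int = 20,
) -> tuple[CoringScan, StandAgeEstimate]:
    """Scan candidate coring years across an ensemble of simulations.

    For every stand, each candidate year's alive-tree subset is scored
    against the field record; the stand's optimum is its argmin-AIC year
    (exact ties resolve to the earliest year and are flagged).  The site
    optimum is the median of the per-stand optima.  Stands whose AIC range
    is below ~2 points are flagged unstable.  The returned
    :class:`StandAgeEstimate` uses the longest field record length as the
    chronology age.
    """
    if not stands:
        raise ValueError("at least one stand simulation is required")
    T = min(s.n_years for s in stands)
    chron_age = max(_chronology_age(fs) for fs in field_series.values())
    if candidate_years is None:
        # a stand is at least as old as its oldest surviving ring record
        start = max(min_candidate_year, chron_age)
        if start > T:
            raise ValueError(
                f"field record spans {chron_age} years but simulations only {T}"
            )
        candidate_years = list(range(start, T + 1, stride))
    else:
        candidate_years = sorted(int(c) for c in candidate_years)
        bad = [c for c in candidate_years if not (1 <= c <= T)]
        if bad:
            raise ValueError(f"candidate years {bad} outside simulated span 1..{T}")
    if not candidate_years:
        raise ValueError("no candidate years to scan")

    records = []
    argmins: dict[int, int] = {}
    ties, unstable, skipped = [], [], []
    for i, stand in enumerate(stands):
        aics: dict[int, float] = {}
        for c in candidate_years:
            subsets = alive_tree_subset(stand, c, min_dbh=min_dbh)
            try:
                aic = score_coring_year(field_series, subsets,
                                        basis_df=basis_df, alpha=alpha)
            except (DegenerateFitError, InsufficientOverlapError) as exc:
                skipped.append((i, c, str(exc)))
                continue
            aics[c] = aic
            records.append({"stand": i, "candidate_year": c, "aic": aic})
        if not aics:
            continue
        best = min(aics.values())
        winners = [c for c, a in aics.items() if a == best]
        if len(winners) > 1:
            ties.append(i)
            logger.info("stand %d: AIC tie among years %s; taking earliest", i, winners)
        argmins[i] = min(winners)
        if max(aics.values()) - best < AIC_STABILITY_RANGE:
            unstable.append(i)
            logger.warning("stand %d: AIC range < %.1f; optimum is unstable",
                           i, AIC_STABILITY_RANGE)

    if not argmins:
        raise RuntimeError("all candidate fits failed or were skipped")

    site_opt = float(np.median(list(argmins.values())))
    scan = CoringScan(
        table=pd.DataFrame.from_records(records),
        argmin_by_stand=argmins,
        site_optimal_year=site_opt,
        tie_stands=ties,
        unstable_stands=unstable,
        skipped=skipped,
    )
    est = StandAgeEstimate.from_samples(site_id, chron_age, list(argmins.values()))
    return scan, est
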