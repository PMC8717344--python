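"""One-at-a-time parameter sensitivity scored by PC1-score variance.

Each species parameter is varied one at a time across equally spaced
levels of a uniform prior centred on its default, the simulator is run at
every level, and each run's basal-area trajectory is reduced to its first
principal-component score.  The parameter whose levels spread those
scores the most — the largest PC1-score variance — is the most sensitive:
PC1 captures the dominant mode of trajectory shape, so a parameter that
moves trajectories along that mode matters most for calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gapsim import ClimateNormals, SiteConditions, SpeciesParams, run_stand

__all__ = [
    "OATDesign",
    "SensitivityResult",
    "oat_design",
    "pc1_scores",
    "rank_parameters",
    "oat_sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass
class OATDesign:
    """One-at-a-time design: each row substitutes one parameter level.

    ``rows`` is a tidy table (species, parameter, level_index, level_value);
    ``param_sets`` holds, when the defaults are a full ``SpeciesParams``,
    the validated parameter object for each row.
    """

    rows: pd.DataFrame
    defaults: Mapping[str, float]
    half_widths: Mapping[str, float]
    n_levels: int
    species: str
    param_sets: list[SpeciesParams] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SensitivityResult:
    """Per-parameter PC1-score variances and the resulting ranking."""

    variances: dict[str, float]
    most_sensitive: str
    ranking: list[str]
    tie: bool = False

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.ranking,
            "pc1_variance": [self.variances[p] for p in self.ranking],
            "rank": np.arange(1, len(self.ranking) + 1),
        })


def oat_design(
    defaults: SpeciesParams | Mapping[str, float],
    half_widths: Mapping[str, float],
    n_levels: int = 8,
    species: str | None = None,
) -> OATDesign:
    """Build a one-at-a-time design over a uniform prior per parameter.

    For each parameter named in ``half_widths``, ``n_levels`` equally
    spaced levels span ``[default - w, default + w]``; every design row
    differs from the defaults in exactly that one coordinate.  When
    ``defaults`` is a full :class:`SpeciesParams`, each substituted
    parameter set is validated and an invariant violation (e.g. a
    ``p_stress`` level outside [0.21, 0.33]) is a design error naming the
    parameter.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    if any(w < 0 for w in half_widths.values()):
        raise ValueError("half_widths must be >= 0")

    if isinstance(defaults, SpeciesParams):
        default_map = {k: getattr(defaults, k) for k in half_widths}
        species = species or defaults.name
        base: SpeciesParams | None = defaults
    else:
        default_map = {k: float(defaults[k]) for k in half_widths}
        species = species or "SPECIES"
        base = None

    records = []
    param_sets: list[SpeciesParams] = []
    for pname in half_widths:
        d, w = default_map[pname], float(half_widths[pname])
        levels = np.linspace(d - w, d + w, n_levels)
        for i, level in enumerate(levels):
            records.append({
                "species": species, "parameter": pname,
                "level_index": i, "level_value": float(level),
            })
            if base is not None:
                try:
                    param_sets.append(base.replace(**{pname: float(level)}))
                except ValueError as exc:
                    raise ValueError(
                        f"OAT level {level!r} for parameter {pname!r} violates "
                        f"species invariants: {exc}"
                    ) from exc

    return OATDesign(
        rows=pd.DataFrame.from_records(records),
        defaults=default_map,
        half_widths=dict(half_widths),
        n_levels=n_levels,
        species=species,
        param_sets=param_sets or None,
    )


def pc1_scores(traj_matrix: np.ndarray) -> np.ndarray:
    """First principal-component score of each trajectory (row).

    Columns (years) are centred; scores are the projections of the centred
    rows onto the leading eigenvector of the column covariance.  The sign
    is fixed so the largest-magnitude loading is positive.  A constant
    matrix yields all-zero scores.
    """
    X = np.asarray(traj_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"need at least 2 simulations x 2 years, got shape {X.shape}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0.0):
        return np.zeros(X.shape[0])
    # SVD of the centred matrix: scores = U * s along the first right
    # singular vector (the PC1 loading).
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loading = Vt[0]
    scores = U[:, 0] * s[0]
    j = np.argmax(np.abs(loading))
    if loading[j] < 0:
        scores = -scores
    return scores


def rank_parameters(scores_by_parameter: Mapping[str, Sequence[float]]) -> SensitivityResult:
    """Rank parameters by the sample variance of their PC1 scores.

    The most sensitive parameter attains the maximum variance; exact ties
    break lexicographically by parameter name and are flagged.
    """
    if not scores_by_parameter:
        raise ValueError("scores_by_parameter is empty")
    variances: dict[str, float] = {}
    for pname, scores in scores_by_parameter.items():
        arr = np.asarray(scores, dtype=float)
        if arr.size < 2:
            raise ValueError(f"parameter {pname!r} has fewer than 2 scores")
        variances[pname] = float(np.var(arr, ddof=1))
    vmax = max(variances.values())
    top = sorted(p for p, v in variances.items() if v == vmax)
    tie = len(top) > 1
    if tie:
        logger.info("sensitivity tie among %s; selecting %r lexicographically", top, top[0])
    ranking = sorted(variances, key=lambda p: (-variances[p], p))
    return SensitivityResult(
        variances=variances, most_sensitive=top[0], ranking=ranking, tie=tie
    )


def oat_sensitivity(
    defaults: SpeciesParams,
    half_widths: Mapping[str, float],
    other_species: Sequence[SpeciesParams],
    site: SiteConditions,
    normals: ClimateNormals,
    years: int,
    seed: int,
    n_levels: int = 8,
) -> tuple[SensitivityResult, OATDesign, np.ndarray]:
    """Full OAT sensitivity analysis for one species at one site.

    Runs the simulator once per design row (the varied species plus any
    fixed companion species), collects the varied species' basal-area
    trajectory, computes PC1 scores across all of that species' runs, and
    ranks parameters by score variance.  All runs share the simulation
    seed so parameter effects are compared under common random numbers.

    Returns the ranking, the design, and the (rows x years) trajectory
    matrix.
    """
    design = oat_design(defaults, half_widths, n_levels=n_levels)
    assert design.param_sets is not None
    trajs = np.zeros((len(design), years))
    for i, sp in enumerate(design.param_sets):
        stand = run_stand([sp, *other_species], site, normals, years, seed)
        trajs[i] = stand.species_ba_by_year[sp.name]
    scores = pc1_scores(trajs)
    by_param = {
        pname: scores[design.rows["parameter"].to_numpy() == pname]
        for pname in half_widths
    }
    return rank_parameters(by_param), design, trajs
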