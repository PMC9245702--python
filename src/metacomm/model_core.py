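"""Core model definitions for stochastic Lotka-Volterra metacommunities.

A metacommunity consists of ``S`` species living on ``P`` habitat patches.
On each patch every species grows logistically (growth rate ``r``, carrying
capacity ``K``) and is suppressed by interspecific competition of relative
strength ``alpha`` (0 < alpha < 1 is the niche-partitioning regime; alpha = 1
is neutral; alpha > 1 promotes competitive exclusion).  Patches are coupled by
dispersal at rate ``lam``, either between nearest neighbours on a periodic 1-D
lattice or uniformly between all patches (global dispersal).  Demographic
noise enters through Poisson-distributed abundance updates (see
:mod:`metacomm.simulator`), so abundances are nonnegative integers.

This module holds parameter containers, the deterministic right-hand sides,
and the observables shared by the simulator, the mean-field theory and the
pattern analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "HeterogeneousParams",
    "Observables",
    "ParameterError",
    "equilibrium_abundance",
    "effective_growth_factor",
    "effective_growth_factor_field",
    "dispersal_term",
    "deterministic_rates",
    "compute_observables",
]

TOPOLOGIES = ("nearest_neighbor_1d", "global")


class ParameterError(ValueError):
    """Raised when a model parameter violates its invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Homogeneous metacommunity parameters.

    Parameters
    ----------
    r : float
        Per-capita growth rate (per generation), ``r > 0``.
    K : float
        Carrying capacity (individuals per patch per species), ``K >= 0``.
    alpha : float
        Interspecific competition strength relative to self-limitation
        (dimensionless, ``alpha >= 0``).  The weak-competition regime is
        ``0 < alpha << 1``; larger values are accepted.
    lam : float
        Dispersal rate (per generation), ``lam >= 0``.
    S, P : int
        Number of species and number of patches.
    topology : {"nearest_neighbor_1d", "global"}
        Dispersal topology.  The 1-D lattice uses periodic boundaries.
    dt : float
        Euler substep for the deterministic drift, in generations.  Must
        divide one generation evenly; the demographic (Poisson) update is
        applied once per generation so that the noise variance per unit time
        equals the abundance, i.e. the noise amplitude ``omega`` is 1.
    omega : float
        Demographic noise amplitude.  Fixed to 1 by the integration scheme;
        kept as an explicit field so the time unit (generations = 1/omega)
        is self-documenting.
    """

    r: float = 0.3
    K: float = 10.0
    alpha: float = 0.1
    lam: float = 0.4
    S: int = 1
    P: int = 200
    topology: str = "nearest_neighbor_1d"
    dt: float = 0.1
    omega: float = 1.0

    def __post_init__(self) -> None:
        problems = []
        if not self.r > 0:
            problems.append(f"r must be > 0, got {self.r}")
        if self.K < 0:
            problems.append(f"K must be >= 0, got {self.K}")
        if self.alpha < 0:
            problems.append(f"alpha must be >= 0, got {self.alpha}")
        if self.lam < 0:
            problems.append(f"lam must be >= 0, got {self.lam}")
        if not (isinstance(self.S, (int, np.integer)) and self.S >= 1):
            problems.append(f"S must be a positive integer, got {self.S}")
        if not (isinstance(self.P, (int, np.integer)) and self.P >= 1):
            problems.append(f"P must be a positive integer, got {self.P}")
        if self.topology not in TOPOLOGIES:
            problems.append(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        if not self.dt > 0:
            problems.append(f"dt must be > 0, got {self.dt}")
        elif abs(1.0 / self.dt - round(1.0 / self.dt)) > 1e-9:
            problems.append(f"dt must divide one generation evenly, got {self.dt}")
        if self.omega != 1.0:
            problems.append("omega is fixed to 1 by the Poisson update scheme")
        if problems:
            raise ParameterError("; ".join(problems))

    @property
    def substeps_per_generation(self) -> int:
        return round(1.0 / self.dt)


@dataclass(frozen=True)
class HeterogeneousParams:
    """Per-species growth/dispersal rates and a per-pair interaction matrix.

    ``r_i`` and ``lam_i`` have shape ``(S,)``; ``alpha_ij`` has shape
    ``(S, S)`` with an unused diagonal.  The generating standard deviations
    ``sigma_r``, ``sigma_alpha``, ``sigma_lam`` are recorded for provenance.
    After sanitization (see :func:`metacomm.simulator.draw_heterogeneous_params`)
    all ``r_i`` are positive and all ``lam_i`` nonnegative.
    """

    r_i: np.ndarray
    lam_i: np.ndarray
    alpha_ij: np.ndarray
    sigma_r: float = 0.0
    sigma_alpha: float = 0.0
    sigma_lam: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_i", np.asarray(self.r_i, dtype=float))
        object.__setattr__(self, "lam_i", np.asarray(self.lam_i, dtype=float))
        object.__setattr__(self, "alpha_ij", np.asarray(self.alpha_ij, dtype=float))
        S = self.r_i.shape[0]
        problems = []
        if self.lam_i.shape != (S,):
            problems.append(f"lam_i shape {self.lam_i.shape} != ({S},)")
        if self.alpha_ij.shape != (S, S):
            problems.append(f"alpha_ij shape {self.alpha_ij.shape} != ({S}, {S})")
        if not np.all(self.r_i > 0):
            problems.append("all r_i must be > 0 after sanitization")
        if not np.all(self.lam_i >= 0):
            problems.append("all lam_i must be >= 0 after sanitization")
        if min(self.sigma_r, self.sigma_alpha, self.sigma_lam) < 0:
            problems.append("sigmas must be >= 0")
        if problems:
            raise ParameterError("; ".join(problems))

    @property
    def S(self) -> int:
        return self.r_i.shape[0]

    def alpha_offdiag(self) -> np.ndarray:
        """Interaction matrix with the (unused) diagonal zeroed."""
        a = self.alpha_ij.copy()
        np.fill_diagonal(a, 0.0)
        return a


def _as_field(values: np.ndarray, params: ModelParams) -> np.ndarray:
    field_arr = np.asarray(values, dtype=float)
    if field_arr.shape != (params.P, params.S):
        raise ParameterError(
            f"abundance field shape {field_arr.shape} does not match (P, S) = "
            f"({params.P}, {params.S})"
        )
    if np.any(field_arr < 0):
        raise ParameterError("abundance field must be nonnegative")
    return field_arr


def equilibrium_abundance(K: float, alpha: float, S: int) -> float:
    """Deterministic coexistence abundance ``N* = K / [1 + alpha (S - 1)]``.

    This is the stable fixed point at which all species coexist on all
    patches at equal abundance when noise is ignored.  It decreases with the
    number of species for ``alpha > 0``: crowding a patch with weakly
    competing species thins out every one of them.
    """
    if not K > 0:
        raise ParameterError(f"K must be > 0, got {K}")
    if alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {alpha}")
    if not S >= 1:
        raise ParameterError(f"S must be >= 1, got {S}")
    return K / (1.0 + alpha * (S - 1))


def _competitor_load(field_arr: np.ndarray, params: ModelParams,
                     het: Optional[HeterogeneousParams]) -> np.ndarray:
    """Competition felt by each (patch, species): sum_{j != i} alpha_ij N_xj."""
    if het is None:
        total = field_arr.sum(axis=1, keepdims=True)
        return params.alpha * (total - field_arr)
    return field_arr @ het.alpha_offdiag().T


def effective_growth_factor_field(values: np.ndarray, params: ModelParams,
                                  het: Optional[HeterogeneousParams] = None) -> np.ndarray:
    """Effective growth factor ``g_eff(x, i)`` for every patch and species.

    ``g_eff(x,i) = 1 - (alpha/K) sum_{j != i} N_xj`` in the homogeneous model;
    with heterogeneous parameters it generalizes to
    ``1 - (r / r_i) sum_{j != i} alpha_ij N_xj / K``.  It is the species'
    growth rate relative to its competitor-free growth rate, so
    ``g_eff <= 1``, with equality exactly when the patch hosts no competitor.
    """
    field_arr = _as_field(values, params)
    if params.K == 0:  # empty world: no competition to feel
        return np.ones_like(field_arr)
    load = _competitor_load(field_arr, params, het)
    if het is None:
        return 1.0 - load / params.K
    return 1.0 - (params.r / het.r_i)[None, :] * load / params.K

def effective_growth_factor(values: np.ndarray, x: int, i: int, params: ModelParams,
                            het: Optional[HeterogeneousParams] = None) -> float:
    """``g_eff`` of species ``i`` on patch ``x`` (0-based indices)."""
    if not (0 <= x < params.P and 0 <= i < params.S):
        raise IndexError(f"(x, i) = ({x}, {i}) out of range for (P, S) = ({params.P}, {params.S})")
    return float(effective_growth_factor_field(values, params, het)[x, i])


def dispersal_term(values: np.ndarray, params: ModelParams,
                   het: Optional[HeterogeneousParams] = None) -> np.ndarray:
    """Dispersal contribution to the deterministic rates.

    Nearest-neighbour 1-D: ``(1/2) lam (N_{x+1,i} + N_{x-1,i} - 2 N_{x,i})``
    with periodic indices.  Global: ``lam (Nbar_i - N_{x,i})`` where
    ``Nbar_i`` is the patch average.  Summed over patches the term vanishes
    for every species: dispersal redistributes, it neither creates nor
    destroys individuals.
    """
    field_arr = _as_field(values, params)
    lam = params.lam if het is None else het.lam_i[None, :]
    if params.topology == "nearest_neighbor_1d":
        lap = np.roll(field_arr, 1, axis=0) + np.roll(field_arr, -1, axis=0) - 2.0 * field_arr
        return 0.5 * lam * lap
    return lam * (field_arr.mean(axis=0, keepdims=True) - field_arr)


def deterministic_rates(values: np.ndarray, params: ModelParams,
                        het: Optional[HeterogeneousParams] = None,
                        fixed_g: Optional[float] = None) -> np.ndarray:
    """Deterministic time derivative of every abundance.

    The growth part is ``r_i N [g_eff(x,i) - N/K]``; with ``fixed_g`` the
    interaction-derived ``g_eff`` is replaced by a constant control parameter
    ``g``, which decouples the species (the single-species reference
    dynamics used in the directed-percolation analysis).  The dispersal part
    comes from :func:`dispersal_term`.
    """
    field_arr = _as_field(values, params)
    if fixed_g is None:
        geff = effective_growth_factor_field(field_arr, params, het)
    else:
        geff = fixed_g
    r = params.r if het is None else het.r_i[None, :]
    growth = r * field_arr * (geff - field_arr / params.K) if params.K > 0 else (
        np.zeros_like(field_arr))
    return growth + dispersal_term(field_arr, params, het)


@dataclass(frozen=True)
class Observables:
    """Summary observables of one abundance field.

    ``mean_abundance`` is the global mean ``N = (PS)^-1 sum N_xi``;
    ``species_mean`` and ``patch_mean`` are the per-species and per-patch
    averages (both average back to the global mean); ``geff_local`` is the
    full ``g_eff(x,i)`` matrix, ``geff_species`` its patch average per
    species, and ``local_diversity`` counts species present per patch.
    """

    mean_abundance: float
    species_mean: np.ndarray
    patch_mean: np.ndarray
    geff_local: np.ndarray
    geff_species: np.ndarray
    local_diversity: np.ndarray

    @property
    def mean_geff(self) -> float:
        return float(self.geff_local.mean())

    @property
    def n_extant_species(self) -> int:
        return int(np.count_nonzero(self.species_mean > 0))

    @property
    def mean_local_diversity(self) -> float:
        return float(self.local_diversity.mean())


def compute_observables(values: np.ndarray, params: ModelParams,
                        het: Optional[HeterogeneousParams] = None) -> Observables:
    field_arr = _as_field(values, params)
    geff = effective_growth_factor_field(field_arr, params, het)
    return Observables(
        mean_abundance=float(field_arr.mean()),
        species_mean=field_arr.mean(axis=0),
        patch_mean=field_arr.mean(axis=1),
        geff_local=geff,
        geff_species=geff.mean(axis=0),
        local_diversity=(field_arr > 0).sum(axis=1),
    )
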