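"""Stochastic time integration of the metacommunity dynamics.

The integrator advances one generation at a time.  Within a generation the
deterministic drift (growth, competition, dispersal) is integrated with
Euler-forward substeps of size ``dt``; the resulting mean abundance ``m`` is
then replaced by a Poisson(m) draw, independently for every patch and
species.  A Poisson redraw has variance equal to its mean, so applying it
once per generation injects demographic noise of variance ``N`` per unit
time — the square-root noise of the underlying model with amplitude
``omega = 1``.  Clipping negative Euler means at zero preserves the
absorbing (all-extinct) state: a site with ``m = 0`` stays empty with
probability one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import (
    HeterogeneousParams,
    ModelParams,
    ParameterError,
    compute_observables,
    deterministic_rates,
)

__all__ = [
    "DispersalOperator",
    "RecordingPolicy",
    "Trajectory",
    "OccupancyMatrix",
    "IntegrationError",
    "initial_condition",
    "step",
    "run",
    "draw_heterogeneous_params",
    "occupancy",
]

logger = logging.getLogger(__name__)

RngLike = Union[int, np.random.Generator, None]


class IntegrationError(RuntimeError):
    """Raised when the Euler/Poisson update produces a non-finite mean."""


def _rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class DispersalOperator:
    """Dispersal operator bound to a topology, rate(s) and patch count.

    Thin wrapper over :func:`metacomm.model_core.dispersal_term`; mainly a
    named handle for tests and diagnostics.
    """

    params: ModelParams
    het: Optional[HeterogeneousParams] = None

    def __call__(self, values: np.ndarray) -> np.ndarray:
        from .model_core import dispersal_term

        return dispersal_term(values, self.params, self.het)


@dataclass(frozen=True)
class RecordingPolicy:
    """What to record while integrating.

    ``sample_every`` (generations) controls the observable sampling
    interval.  ``occupancy_species`` lists species indices whose
    presence/absence row is stored at every sample (``"all"`` stores every
    species).  ``fields_every`` optionally stores full abundance fields at a
    coarser interval.  ``log_every`` emits an INFO progress line.
    """

    sample_every: float = 1.0
    occupancy_species: Union[Sequence[int], str, None] = None
    fields_every: Optional[float] = None
    log_every: Optional[float] = None


@dataclass
class Trajectory:
    """Recorded output of one integration run."""

    times: np.ndarray
    observables: pd.DataFrame
    params: ModelParams
    het: Optional[HeterogeneousParams]
    seed: Optional[int]
    final_field: np.ndarray
    final_time: float
    occupancy: Dict[int, np.ndarray] = dataclass_field(default_factory=dict)
    fields: Optional[np.ndarray] = None
    field_times: Optional[np.ndarray] = None
    fixed_g: Optional[float] = None
    global_extinction_time: Optional[float] = None

    def occupancy_matrix(self, species: int) -> "OccupancyMatrix":
        return occupancy(self, species)

    @property
    def species_mean_final(self) -> np.ndarray:
        """Patch-averaged abundance of every species at the final sample."""
        return self.final_field.mean(axis=0)

    def geff_species_final(self) -> np.ndarray:
        """Patch-averaged effective growth factor per species, final sample."""
        from .model_core import effective_growth_factor_field

        return effective_growth_factor_field(self.final_field, self.params, self.het).mean(axis=0)


@dataclass(frozen=True)
class OccupancyMatrix:
    """Presence/absence (``N > 0``) of one species over (time, patch)."""

    matrix: np.ndarray  # bool, shape (n_samples, P)
    times: np.ndarray
    species: int
    dt_sample: float

    def __post_init__(self) -> None:
        if self.matrix.dtype != bool:
            object.__setattr__(self, "matrix", self.matrix.astype(bool))


def initial_condition(params: ModelParams, rng: RngLike = None) -> np.ndarray:
    """Initial field: independent Poisson(K) draws for every patch/species.

    This realizes "carrying capacity plus small random perturbations" with
    integer abundances, mean ``K`` and O(sqrt(K)) fluctuation.
    """
    gen = _rng(rng)
    return gen.poisson(params.K, size=(params.P, params.S)).astype(np.int64)


def _euler_generation(values: np.ndarray, params: ModelParams,
                      het: Optional[HeterogeneousParams],
                      fixed_g: Optional[float]) -> np.ndarray:
    """Deterministic drift over one generation (Euler substeps, clipped at 0)."""
    m = np.asarray(values, dtype=float)
    dt = params.dt
    for _ in range(params.substeps_per_generation):
        m = m + dt * deterministic_rates(m, params, het, fixed_g)
        if not np.all(np.isfinite(m)):  # before clipping hides a -inf drift
            bad = np.argwhere(~np.isfinite(m))[0]
            raise IntegrationError(
                f"non-finite Euler drift at patch {bad[0]}, species {bad[1]}; "
                "the parameters drive the integration to overflow"
            )
        np.maximum(m, 0.0, out=m)
    return m


def step(values: np.ndarray, params: ModelParams, rng: RngLike = None,
         het: Optional[HeterogeneousParams] = None, noise: bool = True,
         fixed_g: Optional[float] = None) -> np.ndarray:
    """Advance the field by one generation.

    Returns an integer field drawn entry-wise from Poisson(m), where ``m`` is
    the deterministic one-generation update of the current field.  With
    ``noise=False`` the deterministic (float) update is returned instead —
    a diagnostic mode used to test fixed points and conservation laws.
    """
    m = _euler_generation(values, params, het, fixed_g)
    if not noise:
        return m
    return _rng(rng).poisson(m).astype(np.int64)


def run(params: ModelParams, T: float, rng: RngLike = None,
        het: Optional[HeterogeneousParams] = None,
        record: Optional[RecordingPolicy] = None,
        initial: Optional[np.ndarray] = None, noise: bool = True,
        fixed_g: Optional[float] = None,
        stop_on_global_extinction: bool = False) -> Trajectory:
    """Integrate for ``T`` generations and record observables.

    The run is reproducible given an integer seed: the same seed produces a
    bit-identical trajectory.  ``initial`` defaults to Poisson(K) draws from
    the same generator.  If ``stop_on_global_extinction`` is set the loop
    ends as soon as every species is globally extinct (the absorbing state;
    nothing can happen afterwards).
    """
    if not T > 0:
        raise ParameterError(f"T must be > 0, got {T}")
    record = record or RecordingPolicy()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = _rng(rng)

    N = initial_condition(params, gen) if initial is None else np.array(initial)
    if het is not None and het.S != params.S:
        raise ParameterError(f"heterogeneous S = {het.S} does not match params.S = {params.S}")

    n_gen = int(round(T))
    sample_int = max(1, int(round(record.sample_every)))
    n_samples = n_gen // sample_int

    occ_species: Sequence[int]
    if record.occupancy_species == "all":
        occ_species = range(params.S)
    elif record.occupancy_species is None:
        occ_species = ()
    else:
        occ_species = tuple(record.occupancy_species)
        if any(not 0 <= s < params.S for s in occ_species):
            raise IndexError(f"occupancy species indices {occ_species} out of range")
    occ = {s: np.zeros((n_samples, params.P), dtype=bool) for s in occ_species}

    field_int = int(round(record.fields_every)) if record.fields_every else None
    stored_fields, field_times = [], []
    log_int = int(round(record.log_every)) if record.log_every else None

    times = np.zeros(n_samples)
    rows = np.zeros((n_samples, 4))
    extinct_mask = np.zeros(params.S, dtype=bool)
    global_ext_time: Optional[float] = None

    k = 0
    t_final = 0
    for t in range(1, n_gen + 1):
        N = step(N, params, gen, het=het, noise=noise, fixed_g=fixed_g)
        t_final = t
        if t % sample_int == 0:
            obs = compute_observables(N, params, het)
            times[k] = t
            rows[k] = (obs.mean_abundance, obs.mean_geff, obs.n_extant_species,
                       obs.mean_local_diversity)
            for s in occ_species:
                occ[s][k] = N[:, s] > 0
            k += 1
            newly_extinct = (obs.species_mean == 0) & ~extinct_mask
            if newly_extinct.any():
                extinct_mask |= newly_extinct
                logger.info("generation %d: %d species newly globally extinct (%d total)",
                            t, int(newly_extinct.sum()), int(extinct_mask.sum()))
        if field_int and t % field_int == 0:
            stored_fields.append(N.copy())
            field_times.append(t)
        if log_int and t % log_int == 0:
            logger.info("generation %d / %d: mean abundance %.4f", t, n_gen,
                        float(np.mean(N)))
        if not N.any():
            if global_ext_time is None:
                global_ext_time = float(t)
            if stop_on_global_extinction:
                break

    times = times[:k]
    rows = rows[:k]
    obs_df = pd.DataFrame(rows, columns=["mean_abundance", "mean_geff",
                                         "n_extant_species", "mean_local_diversity"])
    obs_df.insert(0, "time", times)
    return Trajectory(
        times=times,
        observables=obs_df,
        params=params,
        het=het,
        seed=seed if isinstance(seed, int) else None,
        final_field=np.asarray(N),
        final_time=float(t_final),
        occupancy={s: occ[s][:k] for s in occ_species},
        fields=np.array(stored_fields) if stored_fields else None,
        field_times=np.array(field_times, dtype=float) if field_times else None,
        fixed_g=fixed_g,
        global_extinction_time=global_ext_time,
    )


def draw_heterogeneous_params(r: float, lam: float, alpha: float,
                              sigma_r: float, sigma_lam: float, sigma_alpha: float,
                              S: int, rng: RngLike = None) -> HeterogeneousParams:
    """Draw per-species growth/dispersal rates and a random interaction matrix.

    ``r_i ~ Normal(r, sigma_r^2)``, ``lam_i ~ Normal(lam, sigma_lam^2)`` and
    ``alpha_ij ~ Normal(alpha, sigma_alpha^2)`` for every ordered pair
    ``i != j`` (the matrix is not symmetrized; each direction is drawn
    independently).  Negative dispersal draws are replaced by the mean
    ``lam``; nonpositive growth draws are likewise replaced by ``r`` so the
    per-capita rates keep their sign.  The diagonal of ``alpha_ij`` is
    unused and stored as zero.
    """
    if min(sigma_r, sigma_lam, sigma_alpha) < 0:
        raise ParameterError("sigmas must be >= 0")
    gen = _rng(rng)
    r_i = gen.normal(r, sigma_r, size=S) if sigma_r > 0 else np.full(S, float(r))
    lam_i = gen.normal(lam, sigma_lam, size=S) if sigma_lam > 0 else np.full(S, float(lam))
    alpha_ij = (gen.normal(alpha, sigma_alpha, size=(S, S)) if sigma_alpha > 0
                else np.full((S, S), float(alpha)))
    r_i[r_i <= 0] = r
    lam_i[lam_i < 0] = lam
    np.fill_diagonal(alpha_ij, 0.0)
    return HeterogeneousParams(r_i=r_i, lam_i=lam_i, alpha_ij=alpha_ij,
                               sigma_r=sigma_r, sigma_alpha=sigma_alpha,
                               sigma_lam=sigma_lam)


def occupancy(trajectory: Trajectory, species: int) -> OccupancyMatrix:
    """Presence/absence matrix of one species, from stored occupancy or fields."""
    if not 0 <= species < trajectory.params.S:
        raise IndexError(f"species {species} out of range for S = {trajectory.params.S}")
    if species in trajectory.occupancy:
        mat = trajectory.occupancy[species]
        times = trajectory.times[: mat.shape[0]]
        dt_sample = float(times[1] - times[0]) if times.size > 1 else 1.0
        return OccupancyMatrix(matrix=mat, times=times, species=species,
                               dt_sample=dt_sample)
    if trajectory.fields is not None:
        mat = trajectory.fields[:, :, species] > 0
        ft = trajectory.field_times
        dt_sample = float(ft[1] - ft[0]) if ft is not None and ft.size > 1 else 1.0
        return OccupancyMatrix(matrix=mat, times=ft, species=species, dt_sample=dt_sample)
    raise ValueError(
        f"trajectory stores neither occupancy for species {species} nor full fields; "
        "set RecordingPolicy.occupancy_species or fields_every"
    )
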