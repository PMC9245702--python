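"""Self-consistent mean-field theory for global dispersal.

With all-to-all dispersal at rate ``lam/P`` per patch pair, each local
population experiences the rest of the metacommunity only through the mean
abundance ``Nbar``.  Treating that mean as a deterministic field maps a
species' local dynamics onto a Brownian particle in a fixed potential, whose
stationary abundance density is

    P(N) = (1/Z) * N^(2 lam Nbar - 1) * exp(-K r [(g_eff - lam/r) - N/K]^2),

with the mean-field effective growth factor
``g_eff = 1 - (alpha/K)(S-1) Nbar``.  Demanding that the mean of this
density reproduce ``Nbar`` closes the theory.  The density interpolates
between a Fisher log-series shape (small ``lam * Nbar``, power ``N^-1``
times an exponential envelope) and a Gaussian of mode ``K (g_eff - lam/r)``
and variance ``K/(2r)`` (large ``K r``).

The mean abundance bifurcates from zero at a critical dispersal rate
``lambda_c``; because ``g_eff -> 1`` as ``Nbar -> 0``, the bifurcation point
is independent of ``alpha`` and ``S``.  For weak dispersal it approaches
``lambda_c ~ exp(-K r) * sqrt(r / (4 pi K))``: the rescue rate needed to
offset the exponentially rare fluctuation to extinction at the bottom of
the logistic potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .model_core import ParameterError

__all__ = [
    "MeanFieldSolution",
    "DegenerateFisherLimitError",
    "ConvergenceError",
    "abundance_density",
    "mean_abundance",
    "solve_self_consistent",
    "critical_dispersal",
    "critical_dispersal_small_lambda",
    "critical_growth_factor_meanfield",
]


class DegenerateFisherLimitError(ValueError):
    """The density's N^-1 endpoint is non-integrable (``lam * Nbar == 0``)."""


class ConvergenceError(RuntimeError):
    """Root bracketing or bisection failed; diagnostics in the message."""


@dataclass(frozen=True)
class MeanFieldSolution:
    """Self-consistent solution of the global-dispersal mean-field theory."""

    nbar: float
    geff: float
    Z: float
    r: float
    K: float
    lam: float
    alpha: float
    S: int
    converged: bool
    residual: float
    roots: tuple = ()

    @property
    def survives(self) -> bool:
        return self.nbar > 0


def _validate(r: float, K: float, lam: float) -> None:
    if not (r > 0 and K > 0):
        raise ParameterError(f"r and K must be > 0, got r={r}, K={K}")
    if lam < 0:
        raise ParameterError(f"lam must be >= 0, got {lam}")


def _moments(nbar: float, r: float, K: float, lam: float, g: float):
    """Normalization Z and mean of the unnormalized density for given Nbar.

    The power-law endpoint ``N^(eps-1)`` with ``eps = 2 lam Nbar`` is
    integrated analytically on ``(0, delta]`` (where the Gaussian factor is
    constant to machine precision) and numerically in log-space elsewhere —
    both tails are then well controlled for any ``eps > 0``.
    """
    eps = 2.0 * lam * nbar
    if eps <= 0:
        raise DegenerateFisherLimitError(
            f"lam * Nbar = {lam * nbar / 2:.3g} gives a non-integrable N^-1 endpoint "
            "(the degenerate Fisher limit); the density is defined only for lam * Nbar > 0"
        )
    b = g - lam / r
    width = np.sqrt(K / (2.0 * r))

    def gauss(N):
        return np.exp(-K * r * (b - N / K) ** 2)

    n_max = max(K * b, 0.0) + 12.0 * width + 1.0
    delta = min(1e-8 * K, 0.1 * n_max)
    t0, t1 = np.log(delta), np.log(n_max)
    z_tail = quad(lambda t: np.exp(eps * t) * gauss(np.exp(t)), t0, t1, limit=200)[0]
    z_head = gauss(0.0) * delta ** eps / eps
    m_tail = quad(lambda t: np.exp((eps + 1.0) * t) * gauss(np.exp(t)), t0, t1, limit=200)[0]
    m_head = gauss(0.0) * delta ** (1.0 + eps) / (1.0 + eps)
    return z_head + z_tail, m_head + m_tail


def _geff_of(nbar: float, K: float, alpha: float, S: int) -> float:
    return 1.0 - (alpha / K) * (S - 1) * nbar


def abundance_density(N, nbar: float, r: float, K: float, lam: float,
                      alpha: float = 0.0, S: int = 1,
                      g: Optional[float] = None) -> np.ndarray:
    """Normalized stationary abundance density evaluated at ``N`` (> 0).

    ``g`` overrides the interaction-derived mean-field effective growth
    factor; by default ``g = 1 - (alpha/K)(S-1) nbar``.
    """
    _validate(r, K, lam)
    if nbar < 0:
        raise ParameterError(f"nbar must be >= 0, got {nbar}")
    if g is None:
        g = _geff_of(nbar, K, alpha, S)
    Z, _ = _moments(nbar, r, K, lam, g)
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ParameterError("the density is defined for N > 0")
    eps = 2.0 * lam * nbar
    b = g - lam / r
    return N ** (eps - 1.0) * np.exp(-K * r * (b - N / K) ** 2) / Z


def mean_abundance(nbar: float, r: float, K: float, lam: float,
                   alpha: float = 0.0, S: int = 1,
                   g: Optional[float] = None) -> float:
    """Mean ``<N>_P`` of the abundance density parameterized by ``nbar``."""
    if g is None:
        g = _geff_of(nbar, K, alpha, S)
    Z, M1 = _moments(nbar, r, K, lam, g)
    if not Z > 0 or not np.isfinite(Z):  # all mass underflowed: empty state
        return 0.0
    return M1 / Z


def _nonzero_roots(r: float, K: float, lam: float, alpha: float, S: int,
                   fixed_g: Optional[float], tol: float,
                   n_grid: int = 160) -> List[float]:
    """All positive roots of F(nbar) = <N>(nbar) - nbar on (0, K]."""

    def F(nb: float) -> float:
        g = fixed_g if fixed_g is not None else _geff_of(nb, K, alpha, S)
        return mean_abundance(nb, r, K, lam, g=g) - nb

    grid = np.linspace(1e-6 * K, K, n_grid)
    vals = np.array([F(x) for x in grid])
    roots: List[float] = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(float(brentq(F, grid[i], grid[i + 1], xtol=tol)))
    return roots


def solve_self_consistent(r: float, K: float, lam: float, alpha: float = 0.0,
                          S: int = 1, tolerance: float = 1e-6) -> MeanFieldSolution:
    """Solve ``Nbar = <N>_P`` and return the equilibrium solution.

    ``Nbar = 0`` is always a root (the absorbing state).  Below the critical
    dispersal rate it is the only one and is returned with ``nbar = 0``;
    above it, the largest positive root (the stable branch) is returned.
    """
    _validate(r, K, lam)
    if S < 1:
        raise ParameterError(f"S must be >= 1, got {S}")
    if lam == 0:
        return MeanFieldSolution(nbar=0.0, geff=1.0, Z=np.nan, r=r, K=K, lam=lam,
                                 alpha=alpha, S=S, converged=True, residual=0.0)
    roots = _nonzero_roots(r, K, lam, alpha, S, None, tolerance)
    if not roots:
        return MeanFieldSolution(nbar=0.0, geff=1.0, Z=np.nan, r=r, K=K, lam=lam,
                                 alpha=alpha, S=S, converged=True, residual=0.0)
    nbar = max(roots)
    g = _geff_of(nbar, K, alpha, S)
    Z, M1 = _moments(nbar, r, K, lam, g)
    residual = abs(M1 / Z - nbar) / max(nbar, 1.0)
    return MeanFieldSolution(nbar=nbar, geff=g, Z=Z, r=r, K=K, lam=lam,
                             alpha=alpha, S=S, converged=residual < tolerance,
                             residual=residual, roots=tuple(roots))


def _survives(r: float, K: float, lam: float, fixed_g: Optional[float],
              tol: float = 1e-9) -> bool:
    if lam <= 0:
        return False
    return bool(_nonzero_roots(r, K, lam, 0.0, 1, fixed_g, tol, n_grid=120))


def critical_dispersal(r: float, K: float, tolerance: float = 1e-3) -> float:
    """Bifurcation point ``lambda_c`` located by bisection on the dispersal rate.

    Uses the single-species case; the bifurcation point is independent of
    ``alpha`` and the number of species because the effective growth factor
    tends to one as ``Nbar`` vanishes.  ``tolerance`` is relative.
    """
    _validate(r, K, 0.0)
    hi = max(4.0 * critical_dispersal_small_lambda(r, K), 1e-6)
    for _ in range(60):
        if _survives(r, K, hi, None):
            break
        hi *= 4.0
    else:
        raise ConvergenceError(f"no surviving phase found up to lam = {hi:.3g}")
    lo = hi / 4.0
    while _survives(r, K, lo, None):
        hi, lo = lo, lo / 4.0
        if lo < 1e-300:
            raise ConvergenceError("survival persists at arbitrarily small lam")
    while (hi - lo) > tolerance * hi:
        mid = 0.5 * (lo + hi)
        if _survives(r, K, mid, None):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def critical_dispersal_small_lambda(r: float, K: float) -> float:
    """Weak-dispersal asymptote ``lambda_c ~ exp(-K r) sqrt(r / (4 pi K))``.

    Valid deep in the ``K lam << K r`` regime with ``K r >> 1``, where the
    stationary density is a narrow Gaussian around ``K`` plus an
    exponentially small weight at the extinction boundary.
    """
    _validate(r, K, 0.0)
    return float(np.exp(-K * r) * np.sqrt(r / (4.0 * np.pi * K)))


def critical_growth_factor_meanfield(r: float, K: float, lam: float,
                                     tolerance: float = 1e-3) -> float:
    """Critical growth factor ``g_c(lam)`` of the single-species mean field.

    Substitutes a fixed control parameter ``g`` for the effective growth
    factor and bisects on ``g`` for the appearance of a nonzero
    self-consistent root.  ``g_c -> 1`` as ``lam`` decreases to
    ``lambda_c`` and is nonincreasing in ``lam``.
    """
    _validate(r, K, lam)
    hi = 1.0
    while not _survives(r, K, lam, hi):
        hi *= 2.0
        if hi > 64:
            raise ConvergenceError(
                f"no surviving phase up to g = {hi:.0f} at lam = {lam:.4g}; "
                "the dispersal rate appears to be far below the critical rate"
            )
    lo = 0.0
    if _survives(r, K, lam, lo):
        raise ConvergenceError("survival at g = 0; cannot bracket the threshold")
    while (hi - lo) > tolerance:
        mid = 0.5 * (lo + hi)
        if _survives(r, K, lam, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
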