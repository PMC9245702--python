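# Methods

## Model and assumptions

The package integrates generalized Lotka–Volterra metacommunity dynamics
for S species on P patches,

∂t N_{x,i} = r N_{x,i}(1 − (α/K)Σ_{j≠i}N_{x,j} − N_{x,i}/K)
           + Σ_y λ_{y,x}(N_{y,i} − N_{x,i}) + √N_{x,i} η,

under two dispersal topologies: a periodic 1-D lattice with
nearest-neighbour rate λ/2 per direction, and global dispersal at λ/P per
patch pair. The model assumes (i) identical growth parameters across
species unless heterogeneity is drawn explicitly, (ii) interspecific
competition weaker than self-limitation (0 < α < 1; the analyses target
α ≪ 1, but any α ≥ 0 is accepted), and (iii) demographic noise as the only
stochastic force — no environmental (multiplicative) noise, which would
shift thresholds and exponents. Two-dimensional or arbitrary-graph
topologies and continuous-space kernels are out of scope.

Rewriting the growth term as r N [g_eff − N/K] defines the effective
growth factor g_eff(x,i) = 1 − (α/K)Σ_{j≠i}N_{x,j}; both groupings are
implemented and tested to agree to floating-point accuracy. With
heterogeneous parameters the dynamics use per-species r_i, λ_i and an
interaction matrix α_ij, and
g_eff(x,i) = 1 − (r/r_i)Σ_{j≠i} α_ij N_{x,j}/K. In the per-species growth
term the competition load enters through r (the ensemble-mean rate), so
that g_eff remains the ratio of suppressed to competitor-free growth.

## Integration scheme and the noise scale

Each generation is advanced in two stages:

1. **Drift.** Euler-forward substeps of size `dt` (default 0.1
   generations) integrate growth, competition and dispersal. Negative
   intermediate means are clipped at zero; `dt` must divide one generation
   evenly. The substeps resolve stiff transients — e.g. the initial
   relaxation from N = K to N* = K/[1 + α(S−1)] when S is large, where a
   unit Euler step would overshoot below zero and artificially exterminate
   whole species.
2. **Demographic noise.** Once per generation every abundance is replaced
   by a Poisson draw with the drifted mean. A Poisson redraw has variance
   equal to its mean, so one redraw per generation injects variance N per
   unit time — exactly the √N-noise of the model with amplitude ω = 1,
   which fixes the time unit (generations = 1/ω). Redrawing per substep
   instead would inflate the noise variance to N/dt per generation and
   silently change every threshold; ω is therefore not a tunable knob but
   a property of the scheme, and `ModelParams.omega` only documents it.

The Poisson update keeps abundances integer, makes the all-extinct state
exactly absorbing, and needs no small-noise approximation at low N (where
a Langevin scheme would fail). A noise-free diagnostic mode exposes the
bare Euler flow for fixed-point and conservation tests. The integrator is
stable for λ·dt ≤ 1; all study conditions satisfy this by an order of
magnitude.

The initial condition draws every abundance independently from
Poisson(K): integer-valued, mean K, O(√K) perturbation. Heterogeneous
parameters are drawn once per run: r_i ~ N(r, σ_r²), λ_i ~ N(λ, σ_λ²),
α_ij ~ N(α, σ_α²) independently for each ordered pair (no symmetrization —
the competitive effect of i on j and of j on i are treated as independent
traits). Negative λ_i draws are reset to λ exactly; nonpositive r_i draws
are reset to r by the same rule (at the study value σ_r = 0.03 around
r = 0.3 such draws are vanishingly rare).

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| r | 0.3 | 1/generation | reference growth rate of all study conditions |
| K | 10 | individuals/patch | small enough that demographic noise matters |
| α | 0.1 | — | weak competition / niche partitioning regime |
| λ | 0.4 | 1/generation | comfortably above the dispersal threshold |
| dt | 0.1 | generations | drift error ≪ K per substep; resolves stiff transients |
| P | 200 | patches | smallest size with a sharp survival classification |

## Mean-field theory (global dispersal)

The stationary abundance density
P(N) = Z⁻¹ N^{2λN̄−1} exp(−Kr[(g_eff − λ/r) − N/K]²), with
g_eff = 1 − (α/K)(S−1)N̄, is normalized by splitting the integral at
δ = 10⁻⁸K: on (0, δ] the Gaussian factor is constant to machine precision
and the power-law head integrates analytically to G(0)δ^ε/ε (ε = 2λN̄);
on [δ, N_max] adaptive quadrature runs in log-abundance, with
N_max = max(K·(g_eff − λ/r), 0) + 12√(K/(2r)) covering the Gaussian tail.
At ε = 0 the density is non-integrable (the Fisher log-series limit
P ∝ x^N/N); this is signalled as a dedicated exception rather than
returned as a number.

Self-consistency demands N̄ = ⟨N⟩_P. Roots of F(N̄) = ⟨N⟩_P(N̄) − N̄ are
bracketed on a 160-point grid over (0, K] and refined by Brent's method;
N̄ = 0 is always a root (absorbing state), and the largest positive root —
the stable branch — is returned as the equilibrium, with the residual
|⟨N⟩_P − N̄|/max(N̄, 1) reported (default tolerance 10⁻⁶).

The critical dispersal rate is located by bisection on the existence of a
positive root, with geometric bracket expansion seeded by the
weak-dispersal asymptote λ_c ≈ e^{−Kr}√(r/(4πK)); because g_eff → 1 as
N̄ → 0, the bifurcation point is independent of α and S (tested
numerically). The asymptote itself follows from balancing the
exponentially small density weight at the extinction boundary,
e^{−Kr}, against the Gaussian bulk of width √(K/(2r)); the package states
no closed form for the opposite (strong-dispersal) limit and relies on the
bisection there. The mean-field critical growth factor g_c(λ) substitutes
a fixed g for g_eff and bisects on g; for λ below λ_c it correctly exceeds
one. Monotonicity of both bisections was established by brute-force grid
scans in the test suite before being relied upon. The theory treats N̄ and
the patch-mean as deterministic fields, so it degrades when the diversity
per patch approaches one (α ≲ 1) — that regime is deliberately untreated.

## Critical growth factor and pattern statistics (short-range dispersal)

`estimate_gc` bisects the fixed-g single-species lattice dynamics on g:
at each candidate, 20 replicate lattices (P = 200, vectorized along the
species axis since fixed-g dynamics decouple) run for 10⁴ generations from
the Poisson(K) initial condition and are classified as surviving if any
patch is occupied at the end; the estimate is the crossing of survival
frequency 1/2, returned with its bracketing interval (default width
0.002). Finite T and P make this a slightly biased, finite-size proxy for
the asymptotic threshold — the reason the near-critical protocol below
runs just *above* the bracket rather than at the midpoint.

`critical_pattern_statistics` runs the single-species lattice at
g = (bracket upper end) + 0.002, inside the active phase but as close to
criticality as survival of the observation window allows; if the lattice
nevertheless dies before yielding 10⁴ cluster samples, g is nudged up by
another 0.002 and the run repeated (at most three times). Occupancy is
sampled once per generation after a 10⁴-generation burn-in.

Extinction-cluster lengths are maximal runs of contiguous empty patches in
each sampled snapshot, with periodic wraparound; a fully extinct snapshot
contributes one censored run (its length is not resolved by the ring).
Recolonization times are maximal blocks of consecutive empty samples of
one patch bounded by occupied samples; blocks open at either window edge,
and never-occupied patches, are censored. Censored items are excluded
from all fits, as in standard survival analysis.

Power laws are fitted to the pooled samples by discrete maximum likelihood
on [x_min, x_max] using the truncated-zeta likelihood, with a multinomial
bootstrap standard error (200 resamples) and a Kolmogorov–Smirnov goodness
diagnostic calibrated by parametric bootstrap (refitting each synthetic
sample; data with systematic curvature, e.g. geometric tails, fail it).
Defaults: x_min = 2 (the single-site bin is dominated by lattice
discreteness), and x_max from the largest contiguous log-bin (8 bins per
decade) still holding ≥ 10 samples, additionally capped at P/10 for
lengths and a tenth of the window for times — within a decade of the
system size the ring geometry and near-global extinctions distort the
tail, and with millions of pooled samples the bin-occupancy rule alone
would reach into that regime. The exponents are reported as positive
magnitudes a with P(x) ∝ x^−a; the corresponding negative slopes are the
γ and δ of 1-D directed percolation, whose reference magnitudes 1.747
(lengths) and 1.840 (times) are exported as package constants.

## What the generator emulates — and what it does not

Synthetic inputs are the simulator's own stochastic trajectories; the
study conditions are r = 0.3, K = 10, α = 0.1, with λ ∈ {0.32–0.89} for
lattice work, S up to 100 (self-organization) and the heterogeneity scales
σ_α = 0.5/S, σ_λ = 0.03. These reproduce demographic-noise-dominated,
weakly competing communities. They do not emulate environmental
fluctuations, spatially structured habitat quality, trophic
interactions or speciation; passing tests therefore demonstrate the
self-organization and directed-percolation phenomenology of the model
class, not of any particular natural community.

## Problem sizes and numerical choices in the tests

The test suite and the acceptance script run at the reference sizes where
that is cheap (P = 1000, 5×10⁴-generation windows for pattern exponents;
P = 500 for the mean-field comparison) and at moderately reduced sizes
where the full reference runs add nothing but wall-clock time
(dispersal-threshold sweeps at P = 200 and 10⁴ generations; the
heterogeneity experiment at S = 60, P = 400 instead of S = 300,
P = 2000). The dispersal-threshold sweep uses a λ grid of 10 points on
[0.002, 0.02]: under the unit-generation noise normalization the
finite-time threshold for K = 10 sits near λ ≈ 0.01, and a grid must
straddle it to locate a boundary. Survival in sweeps is classified by
majority — at least half the species extant at the final sample — which
makes the classification comparable across S.

## Known limitations

- One-dimensional lattices and uniform global coupling only.
- The g_c protocol classifies survival at finite time and size; its
  bracket is a protocol-defined quantity, not the asymptotic DP threshold.
- Near-critical exponent fits carry a systematic offset that depends on
  the distance g − g_c and the fit range; the defaults keep this within a
  few hundredths, well inside the tolerance used in the checks.
- The mean-field solution ignores fluctuations of the patch- and
  species-means and is quantitatively reliable only for α ≪ 1.
- Exponent conventions assume the unit-generation Poisson noise scale; a
  different redraw interval would rescale thresholds (but not the
  universality class).
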