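# metacomm

Stochastic metacommunity dynamics at the edge of extinction: a simulator,
an analytical mean-field theory and directed-percolation pattern analysis
for species-rich communities of weakly competing species coupled by
self-consistent dispersal.

## The scientific problem

In a *metacommunity* — a set of habitat patches coupled by dispersal — the
pool of migrants that rescues a locally extinct population is generated by
the metacommunity itself, not by an external "mainland". This
self-consistency has sharp consequences when many species compete weakly:

1. **A dispersal threshold.** Below a critical dispersal rate λ_c every
   species eventually goes globally extinct by demographic noise alone;
   above it the mean abundance bifurcates to nonzero values.
2. **Self-organization to the extinction threshold.** As the number of
   species *S* grows, each species' patch-averaged *effective growth
   factor* is pushed down toward the critical value g_c(λ) of a single,
   decoupled species — every species ends up barely surviving.
3. **Directed-percolation patterns.** With short-range dispersal, the
   near-critical dynamics produce fractal spatiotemporal extinction
   patterns: the distributions of extinction-cluster lengths *l* and
   recolonization times τ follow power laws with the exponents of
   one-dimensional directed percolation, P(l) ~ l^−1.747 and
   P(τ) ~ τ^−1.840.

This package is for theoretical/spatial ecologists who want these results
reproducible at desk scale, and for anyone needing a clean, tested
contact-process-style lattice simulator with Poisson demographic noise.

## The model

Abundances N_{x,i} of species i ∈ {1..S} on patches x ∈ {1..P} follow
generalized Lotka–Volterra dynamics

  ∂t N_{x,i} = r N_{x,i} (1 − (α/K) Σ_{j≠i} N_{x,j} − N_{x,i}/K)
             + Σ_y λ_{y,x} (N_{y,i} − N_{x,i}) + √N_{x,i} η,

with growth rate *r*, carrying capacity *K*, interspecific competition
strength α (0 < α ≪ 1: niche partitioning), and demographic noise of unit
amplitude (time is measured in generations). Dispersal is either
nearest-neighbour on a periodic 1-D lattice, where the coupling reduces to
(λ/2)(N_{x+1,i} + N_{x−1,i} − 2N_{x,i}), or global, where it reduces to
λ(N̄_i − N_{x,i}). Grouping the growth term as
r N [g_eff(x,i) − N/K] defines the effective growth factor
g_eff(x,i) = 1 − (α/K) Σ_{j≠i} N_{x,j} ≤ 1.

The integrator advances the drift with Euler-forward substeps and replaces
the abundance once per generation by a Poisson draw with the drifted mean —
integer abundances, an exactly absorbing extinct state, and noise variance
N per generation.

Modules:

- `metacomm.model_core` — parameters, deterministic rates, observables.
- `metacomm.simulator` — stochastic integration, initial conditions,
  heterogeneous parameter draws, occupancy matrices.
- `metacomm.meanfield` — the global-dispersal abundance density
  P(N) ∝ N^{2λN̄−1} exp(−Kr[(g_eff−λ/r) − N/K]²), its self-consistent
  solution, λ_c and the mean-field g_c.
- `metacomm.dp_analysis` — single-species reference dynamics, g_c
  estimation by survival bisection, extinction-run / recolonization-time
  extraction and discrete power-law fits.
- `metacomm.cli_io` — `metacomm` command-line tool, YAML configs, HDF5/CSV
  output, scaled-down reference experiments.

## Worked example

```python
import metacomm as mc

# a species-rich community self-organizes to the extinction threshold
params = mc.ModelParams(r=0.3, K=10.0, alpha=0.1, lam=0.4, S=100, P=200)
traj = mc.run(params, 10_000, rng=150, record=mc.RecordingPolicy(sample_every=100))
print(f"mean effective growth factor after 10^4 generations: "
      f"{traj.observables['mean_geff'].iloc[-1]:.3f}")

gc = mc.estimate_gc(r=0.3, K=10.0, lam=0.4, rng=99)
print(f"single-species critical growth factor g_c(0.4): "
      f"{gc.value:.3f} (bracket [{gc.lo:.3f}, {gc.hi:.3f}])")

sol = mc.solve_self_consistent(r=0.3, K=10.0, lam=0.1, alpha=0.1, S=5)
print(f"mean-field mean abundance at lambda=0.1, S=5: {sol.nbar:.3f} "
      f"(g_eff = {sol.geff:.3f}, residual {sol.residual:.1e})")
print(f"mean-field critical dispersal rate: {mc.critical_dispersal(0.3, 10.0):.5f} "
      f"(weak-dispersal asymptote {mc.critical_dispersal_small_lambda(0.3, 10.0):.5f})")
```

prints

```
mean effective growth factor after 10^4 generations: 0.422
single-species critical growth factor g_c(0.4): 0.440 (bracket [0.439, 0.441])
mean-field mean abundance at lambda=0.1, S=5: 5.819 (g_eff = 0.767, residual 2.8e-09)
mean-field critical dispersal rate: 0.00258 (weak-dispersal asymptote 0.00243)
```

The first two lines are the self-organization result: with 100 weakly
competing species the community's mean effective growth factor (0.422) has
been driven to within 0.02 of the single-species survival threshold
(0.440) — every species operates at the edge of extinction. The last two
lines show the mean-field machinery: the self-consistent mean abundance
under global dispersal and the bifurcation point of the mean abundance,
which agrees with its weak-dispersal closed form.

The same experiments are available from the shell, e.g.

```
metacomm simulate --s 100 --p 200 --lam 0.4 --t 10000 --seed 1 --out out/
metacomm dp --mode gc --lam 0.4 --seed 1 --out-dir out_gc/
metacomm reproduce --figure fig5 --scale 0.2 --out-dir repro/
```

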