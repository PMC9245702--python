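"""Stochastic integrator: noise statistics, conservation, reproducibility."""

import numpy as np
import pytest

from metacomm import (
    HeterogeneousParams,
    ModelParams,
    RecordingPolicy,
    draw_heterogeneous_params,
    equilibrium_abundance,
    initial_condition,
    occupancy,
    run,
    step,
)
from metacomm.simulator import IntegrationError


class TestInitialCondition:
    def test_mean_matches_carrying_capacity(self, rng):
        params = ModelParams(K=10.0, S=50, P=200)
        field = initial_condition(params, rng)
        assert field.dtype.kind == "i"
        assert field.mean() == pytest.approx(10.0, rel=0.02)

    def test_zero_capacity_gives_empty_field(self, rng):
        params = ModelParams(K=0.0, S=2, P=5)
        assert not initial_condition(params, rng).any()

    def test_seeded_draws_are_reproducible(self):
        params = ModelParams(S=4, P=9)
        np.testing.assert_array_equal(initial_condition(params, 7),
                                      initial_condition(params, 7))


class TestStep:
    def test_all_zero_field_is_absorbing(self, small_params, rng):
        zero = np.zeros((small_params.P, small_params.S))
        for _ in range(20):
            zero = step(zero, small_params, rng)
        assert not zero.any()

    def test_poisson_mean_and_variance_match_euler_drift(self):
        # with dt = 1 one step is a single Euler update followed by the
        # Poisson redraw, so across replicates the sample mean is the drift
        # and the sample variance equals that mean
        params = ModelParams(r=0.3, K=10.0, alpha=0.0, lam=0.0, S=1, P=1, dt=1.0)
        n0 = 5.0
        gen = np.random.default_rng(5)
        draws = np.array([step(np.array([[n0]]), params, gen)[0, 0]
                          for _ in range(20000)])
        drift = n0 + 0.3 * n0 * (1 - n0 / 10.0)
        assert draws.mean() == pytest.approx(drift, rel=0.02)
        assert draws.var() == pytest.approx(drift, rel=0.05)

    def test_noise_free_mode_keeps_equilibrium_stationary(self, rng):
        for topology in ("nearest_neighbor_1d", "global"):
            params = ModelParams(alpha=0.1, S=4, P=7, lam=0.5, topology=topology)
            nstar = equilibrium_abundance(params.K, params.alpha, params.S)
            field = np.full((7, 4), nstar)
            for _ in range(50):
                field = step(field, params, rng, noise=False)
            np.testing.assert_allclose(field, nstar, rtol=1e-9)

    def test_noise_free_dispersal_conserves_totals(self, rng):
        # r -> 0 is approximated by a growth-free drift: fixed_g with r*g = 0
        params = ModelParams(r=1e-300, K=10.0, alpha=0.0, lam=0.9, S=3, P=16)
        field = initial_condition(params, rng).astype(float)
        totals = field.sum(axis=0)
        for _ in range(200):
            field = step(field, params, rng, noise=False)
        np.testing.assert_allclose(field.sum(axis=0), totals, rtol=1e-9)

    @pytest.mark.filterwarnings("ignore:overflow", "ignore:invalid value")
    def test_nonfinite_rates_raise_integration_error(self):
        params = ModelParams(r=1e300, K=1e-300, S=1, P=2, lam=0.0, dt=1.0)
        with pytest.raises(IntegrationError, match="patch"):
            step(np.array([[1e300], [0.0]]), params, np.random.default_rng(0))


class TestRun:
    def test_identical_seeds_identical_trajectories(self, small_params):
        t1 = run(small_params, 40, rng=11,
                 record=RecordingPolicy(occupancy_species="all"))
        t2 = run(small_params, 40, rng=11,
                 record=RecordingPolicy(occupancy_species="all"))
        np.testing.assert_array_equal(t1.final_field, t2.final_field)
        assert t1.observables.equals(t2.observables)
        np.testing.assert_array_equal(t1.occupancy[0], t2.occupancy[0])

    def test_times_strictly_increasing_and_fields_nonnegative(self, small_params):
        traj = run(small_params, 30, rng=3,
                   record=RecordingPolicy(fields_every=5.0))
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.fields >= 0)
        assert traj.fields.dtype.kind == "i"

    def test_zero_dispersal_leads_to_global_extinction(self):
        # isolated small populations die by demographic noise alone
        params = ModelParams(r=0.3, K=3.0, alpha=0.1, lam=0.0, S=2, P=10)
        traj = run(params, 4000, rng=9, stop_on_global_extinction=True)
        assert traj.global_extinction_time is not None
        assert not traj.final_field.any()

    def test_species_decouple_without_competition(self):
        # alpha = 0: cross-species abundance correlation is statistical noise
        params = ModelParams(r=0.3, K=10.0, alpha=0.0, lam=0.6, S=2, P=50)
        traj = run(params, 600, rng=21, record=RecordingPolicy(fields_every=2.0))
        a = traj.fields[100:, :, 0].mean(axis=1)
        b = traj.fields[100:, :, 1].mean(axis=1)
        rho = np.corrcoef(a, b)[0, 1]
        assert abs(rho) < 0.25

    def test_absorbing_state_persists_per_species(self):
        params = ModelParams(r=0.3, K=4.0, alpha=0.0, lam=0.3, S=4, P=6)
        traj = run(params, 3000, rng=4, record=RecordingPolicy(occupancy_species="all"))
        for s in range(4):
            col = traj.occupancy[s].any(axis=1).astype(int)
            # once the species-wide occupancy hits zero it never recovers
            dead_at = np.flatnonzero(col == 0)
            if dead_at.size:
                assert not col[dead_at[0]:].any()


class TestHeterogeneousDraws:
    def test_zero_sigmas_are_degenerate(self, rng):
        het = draw_heterogeneous_params(0.3, 0.4, 0.1, 0.0, 0.0, 0.0, 5, rng)
        assert set(het.r_i) == {0.3}
        assert set(het.lam_i) == {0.4}
        off = het.alpha_offdiag()
        assert np.all(off[~np.eye(5, dtype=bool)] == 0.1)

    def test_negative_dispersal_draws_reset_to_mean(self):
        # huge sigma forces many negative raw draws; all must equal lam exactly
        het = draw_heterogeneous_params(0.3, 0.4, 0.1, 0.0, 50.0, 0.0, 200,
                                        np.random.default_rng(0))
        assert np.all(het.lam_i >= 0)
        n_reset = np.count_nonzero(het.lam_i == 0.4)
        assert n_reset > 50  # about half the draws land below zero

    def test_nonpositive_growth_draws_reset_to_mean(self):
        het = draw_heterogeneous_params(0.3, 0.4, 0.1, 50.0, 0.0, 0.0, 200,
                                        np.random.default_rng(0))
        assert np.all(het.r_i > 0)
        assert np.count_nonzero(het.r_i == 0.3) > 50

    def test_interaction_draws_center_on_alpha(self):
        het = draw_heterogeneous_params(0.3, 0.4, 0.1, 0.0, 0.0, 0.02, 300,
                                        np.random.default_rng(3))
        off = het.alpha_ij[~np.eye(300, dtype=bool)]
        assert off.mean() == pytest.approx(0.1, abs=3 * 0.02 / np.sqrt(off.size))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(Exception):
            HeterogeneousParams(r_i=np.ones(3), lam_i=np.ones(4),
                                alpha_ij=np.zeros((3, 3)))


class TestOccupancy:
    def test_all_zero_trajectory_gives_all_false(self):
        params = ModelParams(K=0.0, S=2, P=5)
        traj = run(params, 10, rng=0, record=RecordingPolicy(occupancy_species="all"))
        assert not occupancy(traj, 1).matrix.any()

    def test_full_field_gives_all_true(self):
        params = ModelParams(r=0.3, K=500.0, alpha=0.0, lam=0.0, S=1, P=4)
        traj = run(params, 20, rng=0, record=RecordingPolicy(occupancy_species="all"))
        assert occupancy(traj, 0).matrix.all()

    def test_out_of_range_species_rejected(self, small_params):
        traj = run(small_params, 5, rng=0,
                   record=RecordingPolicy(occupancy_species="all"))
        with pytest.raises(IndexError):
            occupancy(traj, 99)
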