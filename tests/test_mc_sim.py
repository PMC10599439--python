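"""Kinetic MC: configuration bookkeeping, equilibrium fidelity, cluster
statistics, detailed balance on small lattices.

Stochastic comparisons are scaled to small volumes (hundreds to a few
thousand sites) so the whole suite stays fast; the statistical criteria
(3 standard errors across replicate lattices) are independent of scale.
"""

import math

import numpy as np
import pytest

from dslattice import (
    BindingParameters,
    MCConfig,
    cluster_size_no_gaps,
    cluster_size_with_gaps,
    equilibrium_density,
    gap_lengths,
    mc_cluster_stats,
    run_mc,
    solve_total_ligand,
)
from dslattice.ising_core import activity_at_density
from dslattice.mc_sim import conc_from_molecules, molecules_from_conc, sample_states

SMALL_VOLUME = 1e-15  # ~900 sites at 1.5 µM: fast but statistically useful


class TestConfig:
    def test_reference_lattice_size(self):
        # 1.5 µM sites in 10 fL is the ~9,000-site reference system
        cfg = MCConfig(Kd=10, ligand_conc=1.0, site_conc=1.5, volume=1e-14, seed=0)
        assert cfg.n_sites == 9033

    def test_ligand_count_range(self):
        assert molecules_from_conc(0.098, 1e-14) == 590
        assert abs(molecules_from_conc(50.0, 1e-14) - 301107) <= 1

    def test_site_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            MCConfig(Kd=10, ligand_conc=1.0, site_conc=1.5, volume=1e-14,
                     n_sites=5000, seed=0)

    def test_oversized_dt_refused(self):
        with pytest.raises(ValueError):
            MCConfig(Kd=10, ligand_conc=1.0, dt=1.0, seed=0)

    def test_exactly_one_ligand_spec(self):
        with pytest.raises(ValueError):
            MCConfig(Kd=10, seed=0)
        with pytest.raises(ValueError):
            MCConfig(Kd=10, ligand_conc=1.0, ligand_count=100, seed=0)


class TestTrajectoryBookkeeping:
    def test_ligand_conservation_and_reproducibility(self):
        cfg = MCConfig(Kd=10, omega1=3, omega2=2, ligand_conc=2.0,
                       volume=SMALL_VOLUME, t_end=1.0, seed=5)
        traj = run_mc(cfg)
        assert np.all(traj.bound_counts >= 0)
        assert np.all(traj.bound_counts <= min(cfg.n_sites, cfg.ligand_count))
        assert traj.final_occupancy.sum() == traj.bound_counts[-1]
        traj2 = run_mc(cfg)
        np.testing.assert_array_equal(traj.bound_counts, traj2.bound_counts)

    def test_equilibrium_window_selection(self):
        cfg = MCConfig(Kd=10, ligand_conc=5.0, volume=SMALL_VOLUME, t_end=5.0, seed=1)
        traj = run_mc(cfg)
        nu, se = equilibrium_density(traj)
        sel = (traj.times >= traj.times[-1] - 0.2 - 1e-12)
        assert sel.sum() == 11  # 11 samples over the last 0.2 s at 0.02 s
        assert se >= 0
        with pytest.raises(ValueError):
            equilibrium_density(traj, (100.0, 101.0))

    def test_constant_trajectory_zero_se(self):
        from dslattice.mc_sim import MCTrajectory

        cfg = MCConfig(Kd=10, ligand_conc=1.0, volume=SMALL_VOLUME, seed=2)
        traj = MCTrajectory(
            times=np.arange(11) * 0.02,
            bound_counts=np.full(11, 5),
            final_occupancy=np.zeros(cfg.n_sites, dtype=np.int8),
            config=cfg,
            seed_used=2,
        )
        nu, se = equilibrium_density(traj, (0.0, 0.2))
        assert se == 0.0 and nu == pytest.approx(5 / cfg.n_sites)


class TestEquilibriumAgainstAnalytic:
    def test_langmuir_with_depletion(self):
        p = BindingParameters(Kd=10)
        expected = solve_total_ligand(p, 1.5, 10.0)[2]
        nus = []
        for seed in range(6):
            cfg = MCConfig(Kd=10, ligand_conc=10.0, volume=SMALL_VOLUME,
                           t_end=2.0, seed=seed)
            nus.append(equilibrium_density(run_mc(cfg), (1.8, 2.0))[0])
        se = np.std(nus, ddof=1) / math.sqrt(len(nus))
        assert abs(np.mean(nus) - expected) < 3 * max(se, 1e-4)

    @pytest.mark.parametrize("L_total", [0.5, 2.0, 10.0])
    def test_cooperative_overlay(self, L_total):
        p = BindingParameters(Kd=10, omega1=10, omega2=2)
        expected = solve_total_ligand(p, 1.5, L_total)[2]
        nus = []
        for seed in range(5):
            cfg = MCConfig(Kd=10, omega1=10, omega2=2, ligand_conc=L_total,
                           volume=SMALL_VOLUME, t_end=5.0, seed=100 + seed)
            nus.append(equilibrium_density(run_mc(cfg))[0])
        se = np.std(nus, ddof=1) / math.sqrt(len(nus))
        assert abs(np.mean(nus) - expected) < 3 * max(se, 2e-3)

    def test_stationarity_of_late_windows(self):
        cfg = MCConfig(Kd=10, omega1=10, omega2=2, ligand_conc=2.0,
                       volume=SMALL_VOLUME, t_end=5.0, seed=7)
        traj = run_mc(cfg)
        nu1, se1 = equilibrium_density(traj, (3.6, 4.2))
        nu2, se2 = equilibrium_density(traj, (4.4, 5.0))
        assert abs(nu1 - nu2) < 3 * math.hypot(se1, se2) + 3e-3

    def test_dt_invariance(self):
        # halving the time step must not shift the equilibrium density
        # beyond combined seed noise
        def mean_nu(pmax):
            vals = []
            for seed in range(4):
                cfg = MCConfig(Kd=10, omega1=5, omega2=2, ligand_conc=2.0,
                               volume=SMALL_VOLUME, t_end=4.0, seed=200 + seed,
                               max_event_prob=pmax)
                vals.append(equilibrium_density(run_mc(cfg))[0])
            return np.mean(vals), np.std(vals, ddof=1) / 2
        nu_a, se_a = mean_nu(0.05)
        nu_b, se_b = mean_nu(0.025)
        assert abs(nu_a - nu_b) < 3 * math.hypot(se_a, se_b) + 3e-3


class TestClusterStatistics:
    def test_hand_counted_snapshot(self):
        s = mc_cluster_stats(np.array([1, 1, 0, 1, 1, 0, 0]))
        assert s.C_nogap == pytest.approx(2.0)  # runs {2, 2}
        assert s.C_sgap == pytest.approx(5.0)  # one composite cluster, sites 1-5
        assert s.n_gap1_per_site == pytest.approx(1 / 7)
        assert s.n_gapGE2_per_site == 0.0  # trailing free pair is an end, not a gap

    def test_fully_occupied(self):
        s = mc_cluster_stats(np.ones(50, dtype=int))
        assert s.C_nogap == 50 and s.C_sgap == 50

    def test_trailing_single_free_site_is_not_a_gap(self):
        s = mc_cluster_stats(np.array([1, 1, 1, 0]))
        assert s.C_sgap == 3.0 and s.n_gap1_per_site == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            mc_cluster_stats(np.array([]))

    def test_equilibrium_cluster_stats_match_closed_forms(self):
        # moderate cooperativities, ~900 sites, 10 replicate lattices
        p = BindingParameters(Kd=10, omega1=2, omega2=5)
        x, _ = activity_at_density(p, 0.5)
        Lt = x * p.Kd + 1.5 * 0.5
        cs, cn, gl = [], [], []
        for seed in range(10):
            cfg = MCConfig(Kd=10, omega1=2, omega2=5, ligand_conc=Lt,
                           volume=SMALL_VOLUME, t_end=5.0, seed=300 + seed)
            emp = mc_cluster_stats(run_mc(cfg).final_occupancy)
            cs.append(emp.C_sgap)
            cn.append(emp.C_nogap)
            gl.append(emp.G_all)
        g_ge2, g_all = gap_lengths(p, x)

        def check(samples, expected):
            se = np.std(samples, ddof=1) / math.sqrt(len(samples))
            assert abs(np.mean(samples) - expected) < 3 * se + 0.02 * expected

        check(cs, cluster_size_with_gaps(p, x))
        check(cn, cluster_size_no_gaps(p, x))
        check(gl, g_all)

    def test_wildtype_cluster_size_at_full_scale(self):
        # strong longitudinal cooperativity, ~9,000-site lattice: the
        # composite cluster size must land within 15% of the closed form
        p = BindingParameters(Kd=50, omega1=0.89, omega2=36.2)
        x, _ = activity_at_density(p, 0.5)
        Lt = x * 50 + 1.5 * 0.5
        cs = []
        for seed in range(3):
            cfg = MCConfig(Kd=50, omega1=0.89, omega2=36.2, ligand_conc=Lt,
                           site_conc=1.5, volume=1e-14, t_end=3.5, seed=400 + seed)
            cs.append(mc_cluster_stats(run_mc(cfg).final_occupancy).C_sgap)
        expected = cluster_size_with_gaps(p, x)
        assert abs(np.mean(cs) - expected) < 0.15 * expected


class TestDetailedBalance:
    def test_state_sampling_requires_small_lattice(self):
        cfg = MCConfig(Kd=10, ligand_conc=1.0, seed=0)
        with pytest.raises(ValueError):
            sample_states(cfg, 10)
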