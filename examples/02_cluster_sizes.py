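"""Bound-ligand cluster sizes at half saturation: 2D vs 1D description.

Uses the cooperativities fitted to wild-type and S3D-mutant cofilin
binding to actin filaments.  On the double-stranded lattice a single free
site does not break a cluster (the flanking ligands still touch
longitudinally), so the composite cluster size C_sgap greatly exceeds the
contiguous-run size C_nogap when longitudinal cooperativity dominates.
"""

from dslattice import BindingParameters, activity_at_density, oneD_cluster_sizes
from dslattice.cluster_stats import statistics_at_activity

cases = [
    ("WT cofilin ", BindingParameters(omega1=0.89, omega2=36.2), 22.0),
    ("S3D cofilin", BindingParameters(omega1=0.92, omega2=68.0), 54.4),
]

print("average bound-cluster sizes at binding density nu = 0.5 (subunits)")
print("             2D C_sgap  2D C_nogap  1D C_sgap  1D C_nogap")
for label, params, omega_1d in cases:
    x, _ = activity_at_density(params, 0.5)
    s = statistics_at_activity(params, x)
    cs1, cn1 = oneD_cluster_sizes(omega_1d, 0.5)
    print(f"{label}   {s.C_sgap:7.1f}    {s.C_nogap:7.1f}    {cs1:7.1f}    {cn1:7.1f}")

print(
    "\nThe double-stranded model predicts ~20-30 subunit composite clusters "
    "(matching cryo-EM observations of cofilin clusters), three to four "
    "times larger than the 1D nearest-neighbor model allows, while the "
    "contiguous runs between free sites stay short because strong "
    "longitudinal cooperativity scatters many single-site gaps."
)
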