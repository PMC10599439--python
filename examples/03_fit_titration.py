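"""Fit a noisy synthetic titration with the 2D and 1D models.

Generates a pyrene-quench style dataset (15% multiplicative uniform
noise) from known parameters, then recovers them by weighted least
squares.  The 1D fit of 2D-generated data inflates the single
cooperativity parameter far above either true value — the signature of a
lattice whose two cooperativities differ.
"""

from dslattice import BindingParameters, fit_1d, fit_2d, generate_dataset
from dslattice.synthetic_data import SyntheticDatasetSpec

truth = BindingParameters(Kd=10.0, omega1=10.0, omega2=2.0)
ds = generate_dataset(
    SyntheticDatasetSpec(truth, A_total=1.4, noise_frac=0.15, scale=1.0,
                         background=0.2, seed=42)
)

r2 = fit_2d(ds, weighting="inverse_signal")
r1 = fit_1d(ds, weighting="inverse_signal")

print("truth: Kd=10, omega1=10, omega2=2 (A_t=1.4 µM, 15% noise)")
print("2D fit:")
for name in ("Kd", "omega1", "omega2", "scale", "background"):
    print(f"  {name:10s} = {r2.params[name]:8.3f} +- {r2.errors[name]:.3f}")
for w in r2.warnings:
    print(f"  note: {w}")
print(f"1D fit: Kd = {r1.params['Kd']:.2f}, omega = {r1.params['omega']:.1f}")
print(
    "\nThe 2D fit recovers the generating parameters within its quoted "
    "uncertainties; the 1D model compensates for the missing second "
    "cooperativity with one large omega and a shifted Kd."
)
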