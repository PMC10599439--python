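# Methods

## Model

A double-stranded lattice of identical binding sites is linearized by
interleaving the two strands into a single chain, so that lateral
neighbors become first neighbors (cooperativity `ω1`) and longitudinal
neighbors become second neighbors (`ω2`).  A configuration with `n_b`
bound ligands, `p1` occupied first-neighbor pairs and `p2` occupied
second-neighbor pairs has statistical weight `x^n_b · ω1^p1 · ω2^p2`,
with `x = Ka·L_free` the reduced activity.  The model assumes: binding
stoichiometry 1 ligand per site, identical sites on both strands,
nearest-neighbor-only cooperativity, and a lattice long enough that end
effects vanish (the analytic results are infinite-lattice limits).

### Exact solution

Grouping configurations into alternating runs of free and bound sites and
summing the two run-generating series yields a quartic characteristic
polynomial `P(λ, x)` whose largest root `λ1` is the per-site grand
partition function.  Both series converge only for
`λ > max(1, ω1·ω2·x)`; the code asserts `λ1 ≥ max(1, ω1ω2x) − 1e−9` and a
relative quartic residual below `1e−8` at every evaluation.  Roots are
obtained from companion-matrix eigenvalues (`numpy.roots`) rather than
closed-form radicals, which are numerically fragile; complex eigenvalues
with relative imaginary part above `1e−9` are discarded.

The binding density is `ν = (x/λ1)·dλ1/dx`, evaluated through the
implicit derivative `dλ1/dx = −P_x/P_λ`.  Because `P` is quadratic in
`x`, the isotherm can also be generated with `λ` as the independent
variable: `x(λ)` is the unique nonnegative root of `A·x² + B·x + C = 0`
with

```
A = ω1(ω2−1)(ω2(λ−1)+1),   B = −λ[(ω1λ+1)ω2(λ−1)+1],   C = λ³(λ−1),
```

computed in the subtraction-free form `x = 2C/(−B + √(B²−4AC))`, which is
stable for `A → 0` (the `ω2 = 1` reduction) and for `ω2 < 1` (where `A <
0` and the two real roots have opposite signs).  The λ-sweep needs no
root finding and is used for curve generation; the x-sweep solves the
quartic per point and serves user-specified concentrations.  Both
procedures agree to machine precision (tested).

### Cluster statistics

Keeping the isolated-free-site weight `e0'` and the ≥2-free-run marker
`c` symbolic in the general quartic lets the per-site expected numbers of
single-site gaps (`n̄_gap=1/N = ∂lnλ1/∂ln e0'`) and of gaps of length ≥ 2
(`n̄_gap≥2/N = ∂lnλ1/∂ln c`) be read off as closed forms; the code
evaluates the printed closed forms directly and cross-checks them against
finite-difference derivatives of the general quartic in the tests.  From
these and `ν` follow

- `C_sgap = (ν + g1)/g2` — composite clusters spanning single-site gaps
  (their length counts the spanned gap sites), the natural cluster notion
  on a double-stranded lattice where ≥ 2 contiguous free sites are needed
  to break contact;
- `C_nogap = ν/(g1 + g2)` — contiguous bound runs;
- `G_ge2 = (1 − ν − g1)/g2` and `G_all = (1 − ν)/(g1 + g2)` — average gap
  lengths excluding/including single-site gaps.

All four are implemented from their printed closed forms in
`(λ1, x, ω1, ω2)` and verified against the count identities above to
`1e−8` and against exact ring enumeration to four decimals.  One symbol
in the source material's gap-length denominator (`n̄_sgap`) is not
defined anywhere; it is implemented as `n̄_gap=1`, which reproduces the
printed closed form exactly (verified algebraically and numerically).
At `x = 0` the gap lengths diverge; the code returns `+inf` rather than
raising so that profile code can clip.

### Known sensitivity of the published cluster values

Evaluating the closed forms at the printed weighted-average
cooperativities gives `C_sgap = 21.7`, `C_nogap = 1.7` for
`(ω1, ω2) = (0.89, 36.2)` and `28.8`, `1.7` for `(0.92, 68)`.  The
corresponding published table prints `21.1/1.8` and `29.1/1.7`.  The
discrepancy traces to parameter rounding: the same formulas give exactly
`21.1/1.8` at `ω1 = 0.92, ω2 = 36.2`, and the published parameters are
themselves weighted averages over several per-dataset fits, so the table
was evidently computed from unrounded per-fit values.  Our values are
validated independently against exact enumeration and large-lattice
Monte Carlo, so the package reports what the formulas give for the
printed parameters.

## Titration solving

For total-ligand titrations the mass balance
`f(λ) = Kd·x(λ) + A_t·ν(x(λ), λ) − L_t = 0` is monotone in `λ ≥ 1`.  It
is solved by safeguarded Newton iteration: a sign-changing bracket
`[1, λ_hi]` is grown geometrically, Newton steps use the analytic
derivative `df/dλ = (Kd + A_t ∂ν/∂x)·dx/dλ + A_t ∂ν/∂λ` (all partials
are rational functions of the quartic's polynomial partials; a
finite-difference variant is kept and compared in tests to `1e−9`), and
any step leaving the bracket falls back to bisection.  Convergence is to
`|f| ≤ 1e−12·max(1, L_t)`; every returned point satisfies mass
conservation to `1e−8·max(1, L_t)`.  Degenerate inputs: `L_t = 0` returns
the empty lattice, `A_t = 0` bypasses the solve (no depletion).

## Fitting

Both models are fitted by trust-region least squares
(`scipy.optimize.least_squares`, TRF) on log-transformed parameters, so
positivity holds by construction.  Observables: binding density directly,
or a signal `s = (1−ν)·scale + background` with the two nuisance
parameters co-fitted.  Weighting `w_i = 1/signal_i` implements the
Poisson-variance argument for photon-counting readouts and is the default
for noisy data; noiseless fits use unit weights.  Standard errors come
from the inverse Gauss–Newton Hessian on the log scale, scaled by the
reduced chi-square and transformed back (`SE(θ) = θ·SE(logθ)`).

Four starts are used, including the `ω1↔ω2` swap of the initial guess.
Two diagnostics are emitted as warnings rather than hidden:

- **Exchange degeneracy.** When both fitted cooperativities are ≥ 1, the
  model fitted with swapped `(ω1, ω2)` is often statistically
  indistinguishable.  After the best fit, a refit from the swapped
  parameters is compared by a likelihood-ratio allowance
  (`Δχ² ≤ max(0.01·χ², 9.21·s²)`, the 99% two-parameter threshold); if it
  is within the allowance the result carries a degeneracy warning.  Label
  assignment then requires external information such as observed cluster
  sizes.
- **Non-identifiability.** At 10–15% noise the unbounded maximum of the
  likelihood frequently runs along a steepness ridge
  (`Kd, ω1 → ∞, ω2 → 0` with compensating changes elsewhere) that the
  data cannot exclude.  Parameters are therefore bounded to physically
  plausible decades (`Kd ∈ [1e−3, 1e4] µM`, `ω ∈ [1e−3, 1e3]`), and a fit
  pinned within one log-unit of a bound, or with a singular covariance,
  is flagged: its point estimates and standard errors should not be
  used.  Recovery-coverage statements (truth within ±3 SE in ≥ 95% of
  cases) apply to fits that claim identified estimates; flagged fits are
  a minority under the reference conditions (8 of 24 grid combinations).

Inverse-variance weighted averaging pools replicate fits
(`μ = Σθᵢ/σᵢ² / Σ1/σᵢ²`, pooled SE `√(1/Σ1/σᵢ²)`); a zero-SE input is
treated as exact.  Simulation shows the pooled estimate beats the
median-accuracy single fit in a clear majority (~60–65%) of
meta-replicates of five noisy fits — a weaker advantage than one might
expect, because weighted-fit errors and their SEs are correlated.

## Kinetic Monte Carlo

A finite volume (default 10 fL) holds `N = site_conc·V·N_A` lattice sites
(9,033 at 1.5 µM) and an integer ligand pool (590 molecules at 0.098 µM
up to ~301,000 at 50 µM).  Each fixed time step visits every site once in
a fresh random permutation (the shuffled event queue): free sites bind
with probability `k_on·[L_free]·dt`, drawing down the pool immediately;
bound sites unbind with probability `k_off·dt/(ω1^a ω2^b)` where `a, b`
count occupied first/second neighbors at that moment.  Putting the
cooperativity entirely on dissociation satisfies detailed balance with
respect to the exact configuration weights — verified by chi-square
against full enumeration on a 12-site chain — and equilibrium
observables are insensitive to how the cooperativity is split between on-
and off-rates.  Boundaries are open chains (a linearized filament); end
corrections are negligible at thousands of sites.

Rate scale: no rate constants are published for this protocol, only that
5 s suffices to equilibrate.  The default `k_on = 20 /µM/s`
(`k_off = k_on·Kd`) makes the slowest relaxation — unbinding of a
doubly-coordinated interior ligand, `k_off/(ω1²ω2²)` — of order 1 s at
the reference parameters, and stationarity of late windows is asserted in
tests rather than assumed.  The time step is chosen so the largest
per-site event probability is ≤ 0.05 (user-supplied steps giving > 0.5
are refused).  A small finite-step bias (~0.5% in ν on the steep part of
an isotherm at the default step) halves with the step and is far below
the stochastic tolerances used anywhere; the distribution-sensitive
detailed-balance test runs at a 0.02 cap.

Equilibrium densities are means over the final 0.2 s (11 samples at the
0.02 s sampling interval of a 5 s run).

A consequence worth knowing before using the MC round trip as a
benchmark: refitting a single simulated titration (20 concentrations,
~8,400 sites, one run per concentration) with the exact 2D model recovers
`Kd` only to within roughly ±15–25%.  The per-point noise of the
equilibrium window (~0.002–0.003 in ν) is small, but the least-squares
surface has a nearly flat valley along the `ω1↔ω2` exchange direction
with compensating `Kd`, and the global minimum wanders along it from one
noise draw to the next (fitted splits range from `(17, 1.4)` to
`(1.2, 20)` for truth `(10, 2)`, with `Kd` between 9.5 and 12.9).  This
is an identifiability property of the model at this noise level, not an
optimizer or time-step artifact — it persists when the time step is
halved and when the fit is started at the generating parameters.  The 1D
refit of the same data is more stable (apparent `ω` ≈ 29–34, folding
both cooperativities into one).  Averaging replicate lattices or taking
denser concentration grids tightens the recovery; a single-curve round
trip should be read with the fit's own standard errors, which correctly
report the flatness.

Empirical cluster statistics
scan the final snapshot: contiguous runs for `C_nogap`, runs merged
across single free sites for `C_sgap` (the spanned site counts toward the
composite length; free runs touching the chain ends are not gaps).

## Oracles

Two independent validators guard the algebra:

- a numeric 4×4 transfer matrix over consecutive-site pair states, whose
  entry for appending site value `c` to state `(a, b)` is
  `x^c·ω1^(bc)·ω2^(ac)`; its dominant eigenvalue equals the quartic's
  largest root to `1e−10` across the test grid (pair states are the
  minimal memory for second-neighbor coupling);
- exact summation over all `2^N` configurations of an `N ≤ 22` ring
  (first/second neighbors mod N) or open chain, giving ν, gap counts and
  cluster/gap lengths as ratios of Boltzmann expectations.  Ring topology
  kills end effects, leaving O(1/N) corrections; a fully occupied ring
  counts as one cluster of size N, an empty ring as no gap.

## Synthetic data

The generator emulates pyrene-quench titrations: occupancy from the exact
solution (or from MC equilibration), readout
`signal = (1−ν)·scale + background`, multiplicative mean-preserving
uniform noise `·(1 + f·(U−0.5))` with `f ≤ 0.2` (a Gaussian variant of
matched variance exists for robustness checks).  Defaults: 20 log-spaced
total-ligand points from 0.098 to 50 µM (covering lag through
saturation), `A_t = 1.4 µM`, scale 1, background 0.2 (positive signal is
required by 1/signal weighting).  What it does **not** emulate: pyrene
photophysics, inner-filter effects, instrument drift, pipetting error
correlated across points.  Passing recovery tests on these data therefore
show correctness of the estimator given the assumed noise model, not
robustness to real-instrument systematics.

## Problem sizes used in the tests

Statistical tests run at reduced scale chosen so each criterion keeps its
meaning: MC-vs-analytic overlays and cluster-statistic checks use ~900
sites (1 fL) with 5–10 replicate lattices and 3-SE bands; the wild-type
composite-cluster check runs at the full 9,033 sites with 3 replicates
and a 15% band; the detailed-balance chi-square uses 10⁶ samples of a
12-site chain thinned every 200 steps (thinning makes the multinomial
sampling assumption of the chi-square test hold); the MC parameter
round trip runs the full ~8,400-site, 20-concentration titration once.
The parameter-recovery coverage grid is the full 24-combination grid with
one noise draw per combination.

## Known limitations

- Cluster-size *distributions* are not derived, only averages; spatial
  correlation functions are out of scope.
- The analytic side is equilibrium-only; kinetics exist only in the MC
  simulator.
- The exchange degeneracy means titration data alone cannot assign which
  cooperativity is lateral; the package warns but cannot resolve it.
- MC cooperativity placement (all on `k_off`) reproduces equilibrium
  exactly but is one of several kinetically distinct schemes; transient
  observables should not be over-interpreted.
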