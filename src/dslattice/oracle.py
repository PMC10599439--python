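"""Independent brute-force validators for the analytic solution.

Two cross-checks that share no code with the sequence-generating solution:

* a numeric pair-state transfer matrix whose dominant eigenvalue must
  equal the largest quartic root, and
* exact enumeration of all 2^N occupancy configurations of a small finite
  lattice (ring by default, open chain to quantify end effects), giving
  the binding density and cluster/gap statistics to which the
  infinite-lattice formulas converge with O(1/N) corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ising_core import BindingParameters

__all__ = [
    "FiniteLatticeSpec",
    "transfer_matrix",
    "transfer_matrix_dominant_eigenvalue",
    "enumerate_finite_lattice",
    "configuration_probabilities",
    "EnumerationResult",
]

#: 2^N states; beyond this enumeration is refused
MAX_ENUM_SITES = 22


@dataclass(frozen=True)
class FiniteLatticeSpec:
    """A small lattice to enumerate exactly."""

    n_sites: int
    params: BindingParameters
    x: float
    topology: str = "ring"  # "ring" | "chain"

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("n_sites must be >= 4")
        if self.n_sites > MAX_ENUM_SITES:
            raise ValueError(
                f"enumeration refused for n_sites={self.n_sites} "
                f"(cap {MAX_ENUM_SITES}: 2^N states)"
            )
        if self.topology not in ("ring", "chain"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.x < 0:
            raise ValueError("x must be >= 0")


def transfer_matrix(params: BindingParameters, x: float) -> np.ndarray:
    """4x4 transfer matrix over consecutive-site pair states (s_i, s_{i+1}).

    Adding a site with value c to pair state (a, b) carries weight
    x^c * omega1^(b c) * omega2^(a c); entries between inconsistent pairs
    (b mismatch) are zero.  One site of memory is exactly what the
    second-neighbor coupling requires.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    w1, w2 = params.omega1, params.omega2
    T = np.zeros((4, 4))
    for a in (0, 1):
        for b in (0, 1):
            for bp in (0, 1):
                for c in (0, 1):
                    if b != bp:
                        continue
                    T[2 * a + b, 2 * bp + c] = x**c * w1 ** (b * c) * w2 ** (a * c)
    return T


def transfer_matrix_dominant_eigenvalue(params: BindingParameters, x: float) -> float:
    """Largest-magnitude eigenvalue of the pair-state transfer matrix.

    Real and positive by Perron–Frobenius; must reproduce the largest
    quartic root of the sequence-generating solution.
    """
    ev = np.linalg.eigvals(transfer_matrix(params, x))
    lam = ev[np.argmax(np.abs(ev))]
    if abs(lam.imag) > 1e-9 * max(1.0, abs(lam.real)):
        raise ArithmeticError(f"dominant eigenvalue not real: {lam}")
    return float(lam.real)


@dataclass(frozen=True)
class EnumerationResult:
    """Exact finite-lattice expectations (ratios of Boltzmann averages)."""

    nu: float
    n_gap1_per_site: float
    n_gapGE2_per_site: float
    C_sgap: float
    C_nogap: float
    G_ge2: float
    G_all: float


def _rotl(v: np.ndarray, n: int, mask: int) -> np.ndarray:
    return ((v << 1) | (v >> (n - 1))) & mask


def _rotr(v: np.ndarray, n: int, mask: int) -> np.ndarray:
    return ((v >> 1) | (v << (n - 1))) & mask


def _boltzmann_weights(spec: FiniteLatticeSpec) -> tuple[np.ndarray, np.ndarray]:
    """(configs, weights): weight = x^nb * w1^(#first-pairs) * w2^(#second-pairs)."""
    n = spec.n_sites
    w1, w2 = spec.params.omega1, spec.params.omega2
    mask = (1 << n) - 1
    s = np.arange(1 << n, dtype=np.uint64)
    nb = np.bitwise_count(s)
    if spec.topology == "ring":
        p1 = np.bitwise_count(s & _rotl(s, n, mask))
        p2 = np.bitwise_count(s & _rotl(_rotl(s, n, mask), n, mask))
    else:
        p1 = np.bitwise_count(s & (s >> 1))
        p2 = np.bitwise_count(s & (s >> 2))
    def term(counts: np.ndarray, base: float) -> np.ndarray:
        # counts * log(base), with 0 * log(0) = 0 (zero-count terms drop out)
        logb = np.log(base) if base > 0 else -np.inf
        with np.errstate(invalid="ignore"):
            out = np.where(counts > 0, counts.astype(float) * logb, 0.0)
        return out

    logw = term(nb, spec.x) + term(p1, w1) + term(p2, w2)
    w = np.exp(logw - np.max(logw[np.isfinite(logw)]))
    return s, w


def configuration_probabilities(spec: FiniteLatticeSpec) -> np.ndarray:
    """Exact Boltzmann probability of every occupancy bit pattern 0..2^N-1."""
    _, w = _boltzmann_weights(spec)
    return w / w.sum()


def enumerate_finite_lattice(spec: FiniteLatticeSpec) -> EnumerationResult:
    """Exact nu and cluster/gap statistics by summation over all 2^N states.

    Ring topology only for the cluster statistics (a fully occupied ring
    counts as a single cluster of size N; an all-free ring contributes no
    gap).  Averages are ratios of Boltzmann expectations, matching the
    infinite-lattice definitions up to O(1/N).
    """
    n = spec.n_sites
    mask = (1 << n) - 1
    s, w = _boltzmann_weights(spec)
    Z = w.sum()
    nb = np.bitwise_count(s).astype(float)
    nu = float((w * nb).sum() / (Z * n))
    if spec.topology != "ring":
        return EnumerationResult(nu, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)

    f = (~s) & np.uint64(mask)
    # circular runs of free sites: run starts where f_i=1 and left neighbor 0
    starts = np.bitwise_count(f & ~_rotr(f, n, mask) & np.uint64(mask)).astype(float)
    all_free = s == 0
    n_runs = np.where(all_free, 0.0, starts)  # all-free ring: no bounded gap
    singles = np.bitwise_count(
        f & ~_rotr(f, n, mask) & ~_rotl(f, n, mask) & np.uint64(mask)
    ).astype(float)
    n_gap1 = np.where(all_free, 0.0, singles)
    n_gapGE2 = n_runs - n_gap1
    nfree = n - nb

    E = lambda q: float((w * q).sum() / Z)
    e_nb, e_g1, e_g2, e_nf = E(nb), E(n_gap1), E(n_gapGE2), E(nfree)
    c_sgap = (e_nb + e_g1) / e_g2 if e_g2 > 0 else np.inf
    c_nogap = e_nb / (e_g1 + e_g2) if (e_g1 + e_g2) > 0 else np.inf
    g_ge2 = (e_nf - e_g1) / e_g2 if e_g2 > 0 else np.inf
    g_all = e_nf / (e_g1 + e_g2) if (e_g1 + e_g2) > 0 else np.inf
    return EnumerationResult(
        nu, e_g1 / n, e_g2 / n, c_sgap, c_nogap, g_ge2, g_all
    )
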