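"""Bound-cluster and free-gap statistics on the infinite double-stranded lattice.

On a double-stranded polymer a single free site flanked by bound ligands is
not a true gap: the two ligands across it still touch longitudinally, so at
least two contiguous free sites are needed to break a bound cluster.  Two
cluster definitions therefore coexist:

* ``C_sgap`` — average size of composite clusters that span single-site
  gaps (cluster length counts those gap sites), and
* ``C_nogap`` — average size of contiguous bound runs, where any free site
  breaks the cluster.

All quantities are closed forms in (lambda1, x, omega1, omega2), obtained
by differentiating the grand partition function with respect to the
isolated-free-site weight (counting single-site gaps) and the >= 2 gap
marker.  Gap counts are reported per lattice site so the infinite-lattice
quantities are finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .ising_core import (
    BindingParameters,
    _P_lam,
    activity_at_density,
    largest_root,
    nu_from_lambda_x,
)

__all__ = [
    "ClusterStatistics",
    "gap_counts",
    "cluster_size_with_gaps",
    "cluster_size_no_gaps",
    "oneD_cluster_sizes",
    "gap_lengths",
    "cluster_profile",
    "profile_frame",
]


@dataclass(frozen=True)
class ClusterStatistics:
    """Per-site gap counts and average cluster/gap lengths at one state point."""

    nu: float
    x: float
    n_gap1_per_site: float
    n_gapGE2_per_site: float
    C_sgap: float
    C_nogap: float
    G_ge2: float
    G_all: float


def gap_counts(params: BindingParameters, x: float) -> tuple[float, float]:
    """Per-site expected counts of single-site gaps and of gaps of length >= 2.

    Derived from d ln Xi / d ln e0' and d ln Xi / d ln c at the physical
    weights; both vanish on the empty lattice (x = 0).
    """
    if x < 0:
        raise ValueError(f"x must be >= 0, got {x}")
    if x == 0.0:
        return 0.0, 0.0
    w1, w2 = params.omega1, params.omega2
    lam = largest_root(params, x)
    D = _P_lam(w1, w2, lam, x)
    g1 = (
        w2
        * x
        * (lam * lam - (w1 * x * (w2 - 1.0) + 1.0) * lam + w1 * x * (w2 - 1.0))
        / (lam * D)
    )
    g2 = x * (lam - w1 * x * (w2 - 1.0)) / (lam * D)
    return g1, g2


def cluster_size_with_gaps(params: BindingParameters, x: float) -> float:
    """Average composite bound-cluster size spanning single-site gaps.

    C_sgap = (N_bound + N_gap=1) / n_gap>=2, in subunits (bound sites plus
    the single free sites inside the cluster).
    """
    if x <= 0:
        raise ValueError(f"x must be > 0 (no bound clusters at x={x})")
    w1, w2 = params.omega1, params.omega2
    lam = largest_root(params, x)
    num = (
        w1 * w2 * lam**3
        + w2 * (2.0 - w1) * lam**2
        - ((w2 - 1.0) * (1.0 + 3.0 * w1 * w2 * x) + w2) * lam
        + (3.0 * w2 - 2.0) * w1 * x * (w2 - 1.0)
    )
    den = lam - w1 * x * (w2 - 1.0)
    return num / den


def cluster_size_no_gaps(params: BindingParameters, x: float) -> float:
    """Average contiguous bound-run size, any free site breaking the cluster.

    C_nogap = N_bound / (n_gap>=2 + n_gap=1).
    """
    if x <= 0:
        raise ValueError(f"x must be > 0 (no bound clusters at x={x})")
    w1, w2 = params.omega1, params.omega2
    lam = largest_root(params, x)
    num = (
        w1 * w2 * lam**3
        - w2 * (w1 - 1.0) * lam**2
        - (w2 - 1.0) * (1.0 + 2.0 * w1 * w2 * x) * lam
        + 2.0 * x * w1 * (w2 - 1.0) ** 2
    )
    den = (
        w2 * lam**2
        - (w1 * w2 * x + 1.0) * (w2 - 1.0) * lam
        + w1 * x * (w2 - 1.0) ** 2
    )
    return num / den


def oneD_cluster_sizes(omega: float, nu: float) -> tuple[float, float]:
    """(C_sgap, C_nogap) for the 1D nearest-neighbor lattice at density nu.

    Uses R = sqrt((1-2nu)^2 + 4 omega nu (1-nu)); the gap-breaking average
    has two equivalent printed forms, 2 nu (omega-1)/(R-1) and
    (R+1)/(2(1-nu)), which are asserted to agree.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if not (0.0 < nu < 1.0):
        raise ValueError(f"nu must lie in (0,1), got {nu}")
    R = math.sqrt((1.0 - 2.0 * nu) ** 2 + 4.0 * omega * nu * (1.0 - nu))
    c_sgap = (omega * (1.0 + R) - 2.0) / ((2.0 * omega - 1.0) * (1.0 - nu) + nu - R)
    c_nogap = (R + 1.0) / (2.0 * (1.0 - nu))
    if omega != 1.0:
        alt = 2.0 * nu * (omega - 1.0) / (R - 1.0)
        if abs(alt - c_nogap) > 1e-10 * max(1.0, c_nogap):
            raise ArithmeticError(
                f"1D C_nogap forms disagree: {alt} vs {c_nogap} "
                f"(omega={omega}, nu={nu})"
            )
    return c_sgap, c_nogap


def gap_lengths(params: BindingParameters, x: float) -> tuple[float, float]:
    """(G_ge2, G_all): average free-gap lengths excluding / including
    single-site gaps.  Both diverge (+inf) as x -> 0."""
    if x < 0:
        raise ValueError(f"x must be >= 0, got {x}")
    if x == 0.0:
        return math.inf, math.inf
    w1, w2 = params.omega1, params.omega2
    lam = largest_root(params, x)
    num_ge2 = (
        4.0 * lam**4
        - (3.0 + 4.0 * w1 * w2 * x) * lam**3
        + w2 * x * (3.0 * w1 - 4.0) * lam**2
        + x * (2.0 * (1.0 + 2.0 * w1 * w2 * x) * (w2 - 1.0) + w2) * lam
        - w1 * x * x * (3.0 * w2 - 2.0) * (w2 - 1.0)
    )
    g_ge2 = num_ge2 / (x * (lam - w1 * x * (w2 - 1.0)))
    num_all = (
        4.0 * lam**4
        - (3.0 + 4.0 * w1 * w2 * x) * lam**3
        + 3.0 * w2 * x * (w1 - 1.0) * lam**2
        + x * (w2 - 1.0) * (2.0 + 3.0 * w1 * w2 * x) * lam
        - 2.0 * x * x * w1 * (w2 - 1.0) ** 2
    )
    den_all = x * (
        w2 * lam**2
        - (1.0 + w1 * w2 * x) * (w2 - 1.0) * lam
        + w1 * x * (w2 - 1.0) ** 2
    )
    g_all = num_all / den_all
    return g_ge2, g_all


def statistics_at_activity(params: BindingParameters, x: float) -> ClusterStatistics:
    """All cluster/gap statistics at one reduced activity."""
    lam = largest_root(params, x) if x > 0 else 1.0
    nu = nu_from_lambda_x(params, lam, x) if x > 0 else 0.0
    g1, g2 = gap_counts(params, x)
    if x > 0:
        c_sgap = cluster_size_with_gaps(params, x)
        c_nogap = cluster_size_no_gaps(params, x)
        g_ge2, g_all = gap_lengths(params, x)
    else:
        c_sgap = c_nogap = 1.0
        g_ge2 = g_all = math.inf
    return ClusterStatistics(nu, x, g1, g2, c_sgap, c_nogap, g_ge2, g_all)


def cluster_profile(
    params: BindingParameters, nu_grid
) -> list[ClusterStatistics]:
    """Cluster statistics along a grid of binding densities (each in (0,1))."""
    out: list[ClusterStatistics] = []
    for nu in nu_grid:
        x, _ = activity_at_density(params, float(nu))
        out.append(statistics_at_activity(params, x))
    return out


def profile_frame(stats: list[ClusterStatistics]) -> pd.DataFrame:
    """Cluster profile as a DataFrame, ready for CSV export."""
    return pd.DataFrame(
        {
            "nu": [s.nu for s in stats],
            "x": [s.x for s in stats],
            "C_sgap": [s.C_sgap for s in stats],
            "C_nogap": [s.C_nogap for s in stats],
            "G_ge2": [s.G_ge2 for s in stats],
            "G_all": [s.G_all for s in stats],
            "n_gap1_per_site": [s.n_gap1_per_site for s in stats],
            "n_gapGE2_per_site": [s.n_gapGE2_per_site for s in stats],
        }
    )
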