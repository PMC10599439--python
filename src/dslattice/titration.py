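"""Binding isotherms versus free or total ligand concentration.

When only the total ligand concentration is known (the usual experimental
situation), the free concentration must be solved self-consistently from
mass conservation, L_total = L_free + A_total * nu.  With lambda as the
unknown this is a smooth, monotone scalar equation

    f(lambda) = Kd * x(lambda) + A_total * nu(x(lambda), lambda) - L_total = 0

solved here by a bracketed, safeguarded Newton iteration with the analytic
derivative df/dlambda (a finite-difference fallback is kept for
cross-checking).  Concentrations are in µM throughout; x = L_free/Kd is
dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ising_core import (
    BindingParameters,
    binding_density,
    dx_dlambda,
    free_activity_from_lambda,
    nu_from_lambda_x,
    nu_partials,
)

__all__ = [
    "TitrationPoint",
    "TitrationDataset",
    "solve_total_ligand",
    "isotherm",
    "signal_model",
    "signal_to_nu",
]

_MASS_TOL = 1e-8


@dataclass(frozen=True)
class TitrationPoint:
    """One point of a titration: concentrations, occupancy, readout."""

    L_total: float
    L_free: float
    A_total: float
    nu: float
    signal: float = math.nan

    def __post_init__(self) -> None:
        resid = abs(self.L_free + self.A_total * self.nu - self.L_total)
        if resid > _MASS_TOL * max(1.0, self.L_total):
            raise ValueError(
                f"mass conservation violated by {resid} at L_total={self.L_total}"
            )


@dataclass
class TitrationDataset:
    """An ordered titration (strictly increasing L_total, >= 5 points)."""

    L_total: np.ndarray
    signal: np.ndarray
    A_total: float
    L_free: np.ndarray | None = None
    nu: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L_total = np.asarray(self.L_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.L_total.size < 5:
            raise ValueError(f"need >= 5 points, got {self.L_total.size}")
        if np.any(np.diff(self.L_total) <= 0):
            raise ValueError("L_total must be strictly increasing")
        if np.any(self.L_total < 0) or self.A_total < 0:
            raise ValueError("concentrations must be >= 0")
        if self.L_total.shape != self.signal.shape:
            raise ValueError("L_total and signal must have the same length")

    def __len__(self) -> int:
        return int(self.L_total.size)


def _mass_balance(
    params: BindingParameters, A_total: float, L_total: float, lam: float
) -> tuple[float, float, float]:
    """(f(lambda), x, nu) of the mass-conservation residual."""
    x = free_activity_from_lambda(params, lam)
    nu = nu_from_lambda_x(params, lam, x)
    return params.Kd * x + A_total * nu - L_total, x, nu


def _mass_balance_derivative(
    params: BindingParameters, A_total: float, lam: float, x: float
) -> float:
    """Analytic df/dlambda = (Kd + At dnu/dx) dx/dlam + At dnu/dlam."""
    dxdl = dx_dlambda(params, lam, x)
    dnudl, dnudx = nu_partials(params, lam, x)
    return (params.Kd + A_total * dnudx) * dxdl + A_total * dnudl


def solve_total_ligand(
    params: BindingParameters,
    A_total: float,
    L_total: float,
    derivative: str = "analytic",
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[float, float, float, float]:
    """Solve mass conservation at one total-ligand concentration.

    Returns the consistent (lambda1, x, nu, L_free).  Newton steps use the
    analytic derivative (or a central finite difference when
    ``derivative="fd"``) and are safeguarded by a sign-changing bracket in
    lambda; any step leaving the bracket falls back to bisection.
    """
    if A_total < 0 or L_total < 0:
        raise ValueError("concentrations must be >= 0")
    if L_total == 0.0:
        return 1.0, 0.0, 0.0, 0.0
    if A_total == 0.0:
        x = L_total / params.Kd
        return math.nan, x, binding_density(params, x), L_total

    # bracket: f(1) = -L_total < 0; grow hi geometrically until f > 0
    lo, f_lo = 1.0, -L_total
    hi = 2.0
    f_hi, _, _ = _mass_balance(params, A_total, L_total, hi)
    while f_hi < 0.0:
        hi *= 2.0
        if hi > 1e15:
            raise ArithmeticError(
                f"failed to bracket mass balance at L_total={L_total} ({params})"
            )
        f_hi, _, _ = _mass_balance(params, A_total, L_total, hi)

    lam = 0.5 * (lo + hi)
    for _ in range(max_iter):
        f, x, nu = _mass_balance(params, A_total, L_total, lam)
        if abs(f) <= tol * max(1.0, L_total):
            break
        if f > 0.0:
            hi = lam
        else:
            lo = lam
        if derivative == "analytic":
            df = _mass_balance_derivative(params, A_total, lam, x)
        else:
            h = 1e-7 * max(1.0, lam)
            f_p, _, _ = _mass_balance(params, A_total, L_total, lam + h)
            f_m, _, _ = _mass_balance(params, A_total, L_total, max(lam - h, 1.0))
            df = (f_p - f_m) / (lam + h - max(lam - h, 1.0))
        lam_new = lam - f / df if (df > 0.0 and math.isfinite(df)) else math.nan
        lam = lam_new if lo < lam_new < hi else 0.5 * (lo + hi)
    else:
        raise ArithmeticError(
            f"mass-balance iteration did not converge at L_total={L_total} "
            f"(bracket [{lo}, {hi}], residual {f})"
        )
    L_free = params.Kd * x
    if abs(L_free + A_total * nu - L_total) > _MASS_TOL * max(1.0, L_total):
        raise ArithmeticError(f"mass conservation residual too large at {L_total}")
    return lam, x, nu, L_free


def signal_model(nu, scale: float, background: float):
    """Pyrene-quench style readout: signal = (1 - nu) * scale + background."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return (1.0 - np.asarray(nu)) * scale + background


def signal_to_nu(signal, scale: float, background: float):
    """Inverse of :func:`signal_model`, for normalizing fitted data."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    return 1.0 - (np.asarray(signal) - background) / scale


def isotherm(
    params: BindingParameters,
    A_total: float,
    L_grid,
    mode: str = "total",
    scale: float = 1.0,
    background: float = 0.0,
) -> list[TitrationPoint]:
    """Titration points along a ligand-concentration grid.

    mode="free": the grid is L_free and occupancy follows directly from the
    quartic; mode="total": the grid is L_total and each point solves mass
    conservation.  The signal column applies :func:`signal_model`.
    """
    grid = np.asarray(L_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("ligand grid must be nonnegative")
    pts: list[TitrationPoint] = []
    for L in grid:
        if mode == "free":
            nu = binding_density(params, L / params.Kd)
            pts.append(
                TitrationPoint(
                    L + A_total * nu, L, A_total, nu, float(signal_model(nu, scale, background))
                )
            )
        elif mode == "total":
            _, _, nu, L_free = solve_total_ligand(params, A_total, L)
            pts.append(
                TitrationPoint(
                    L, L_free, A_total, nu, float(signal_model(nu, scale, background))
                )
            )
        else:
            raise ValueError(f"mode must be 'free' or 'total', got {mode!r}")
    return pts


def isotherm_frame(points: list[TitrationPoint]) -> pd.DataFrame:
    """Isotherm as a DataFrame with a Scatchard column (nu/L_free vs nu)."""
    lf = np.array([p.L_free for p in points])
    nu = np.array([p.nu for p in points])
    with np.errstate(divide="ignore", invalid="ignore"):
        scat = np.where(lf > 0, nu / lf, np.inf)
    return pd.DataFrame(
        {
            "L_total": [p.L_total for p in points],
            "L_free": lf,
            "nu": nu,
            "signal": [p.signal for p in points],
            "scatchard_ratio": scat,
        }
    )
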