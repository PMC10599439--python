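"""Exact solution of the double-stranded Ising ligand-binding model.

An actin-like double-stranded polymer is linearized to a 1D lattice in
which the lateral cooperativity ``omega1`` couples first neighbors and the
longitudinal cooperativity ``omega2`` couples second neighbors.  The grand
partition function per site, ``lambda1``, is the largest root of a quartic
characteristic equation obtained with the sequence-generating method; the
binding density ``nu`` (fraction of occupied sites) follows by implicit
differentiation.

All concentrations enter through the reduced free-ligand activity
``x = Ka * L_free = L_free / Kd`` (dimensionless), so everything in this
module is independent of the dissociation constant except where a
:class:`BindingParameters` carries one for unit conversion downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingParameters",
    "GeneralSequenceWeights",
    "LatticePoint",
    "quartic_coefficients",
    "quartic_coefficients_general",
    "largest_root",
    "binding_density",
    "free_activity_from_lambda",
    "oneD_binding_density",
    "oneD_largest_root",
    "activity_at_density",
    "lambda_sweep",
    "x_sweep",
]

#: residual tolerance for the characteristic quartic at (lambda1, x)
_RESIDUAL_RTOL = 1e-8
#: allowed violation of the lower bounds lambda1 >= max(1, w1*w2*x)
_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class BindingParameters:
    """Free parameters of the binding model.

    Parameters
    ----------
    Kd : float
        Dissociation constant for binding to an isolated site
        (concentration units, conventionally µM). ``Ka = 1/Kd``.
    omega1 : float
        Lateral (first-neighbor after linearization) cooperativity,
        dimensionless, >= 0.  1 means no lateral cooperativity.
    omega2 : float
        Longitudinal (second-neighbor) cooperativity, dimensionless, >= 0.
    """

    Kd: float = 1.0
    omega1: float = 1.0
    omega2: float = 1.0

    def __post_init__(self) -> None:
        if not (self.Kd > 0):
            raise ValueError(f"Kd must be > 0, got {self.Kd}")
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError(
                f"cooperativities must be >= 0, got omega1={self.omega1}, "
                f"omega2={self.omega2}"
            )

    @property
    def Ka(self) -> float:
        """Association constant, exactly 1/Kd."""
        return 1.0 / self.Kd


@dataclass(frozen=True)
class GeneralSequenceWeights:
    """Statistical weights of the general sequence-generating construction.

    ``e0_iso`` weights an isolated free site, ``e0`` a free site inside a
    run of >= 2 free sites, ``x_iso``/``x`` the analogous bound-site
    weights, and ``c`` marks free runs of length >= 2 (a bookkeeping
    variable used to extract gap counts; physically ``c = 1``).  The
    stoichiometric defaults are ``e0_iso = e0 = c = 1`` and
    ``x_iso = x = Ka * L_free``.
    """

    e0_iso: float = 1.0
    e0: float = 1.0
    x_iso: float = 0.0
    x: float = 0.0
    c: float = 1.0

    def __post_init__(self) -> None:
        for name in ("e0_iso", "e0", "x_iso", "x", "c"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be >= 0")


@dataclass(frozen=True)
class LatticePoint:
    """A mutually consistent (x, lambda1, nu) triple on the isotherm."""

    x: float
    lambda1: float
    nu: float


def _check_x(x: float) -> None:
    if x < 0:
        raise ValueError(f"reduced activity x must be >= 0, got {x}")


def quartic_coefficients(params: BindingParameters, x: float) -> np.ndarray:
    """Coefficients (degree 4 -> 0) of the characteristic quartic.

    lambda^4 - (1 + w1 w2 x) lambda^3 + w2 x (w1 - 1) lambda^2
        + x (w2 - 1)(1 + w1 w2 x) lambda - w1 x^2 (w2 - 1)^2 = 0
    """
    _check_x(x)
    w1, w2 = params.omega1, params.omega2
    return np.array(
        [
            1.0,
            -(1.0 + w1 * w2 * x),
            w2 * x * (w1 - 1.0),
            x * (w2 - 1.0) * (1.0 + w1 * w2 * x),
            -w1 * x * x * (w2 - 1.0) ** 2,
        ]
    )


def quartic_coefficients_general(
    params: BindingParameters, weights: GeneralSequenceWeights
) -> np.ndarray:
    """General-weights characteristic quartic.

    Keeping the isolated-site weights and the gap marker ``c`` symbolic is
    what allows gap counts to be extracted by differentiation; with the
    stoichiometric defaults this reduces coefficient-wise to
    :func:`quartic_coefficients`.
    """
    w1, w2 = params.omega1, params.omega2
    e0p, e0 = weights.e0_iso, weights.e0
    xp, x, c = weights.x_iso, weights.x, weights.c
    return np.array(
        [
            1.0,
            -(e0 + w1 * w2 * x),
            -w2 * (e0p * xp - e0 * w1 * x),
            -(
                c * e0**2 * xp
                + e0p * w1 * w2 * x**2
                - e0 * e0p * w2 * xp
                - e0p * w1 * w2**2 * xp * x
            ),
            -e0
            * w1
            * x
            * (e0p * w2**2 * xp - c * e0 * w2 * xp - e0p * w2 * x + c * e0 * x),
        ]
    )


def largest_root(params: BindingParameters, x: float) -> float:
    """Largest real root lambda1 of the characteristic quartic.

    Solved via companion-matrix eigenvalues (``numpy.roots``); complex
    roots with relative imaginary part above 1e-9 are discarded.  The
    returned root satisfies ``lambda1 >= max(1, omega1*omega2*x)``, the
    convergence condition of both sequence-generating series.
    """
    _check_x(x)
    if x == 0.0:
        return 1.0
    coeffs = quartic_coefficients(params, x)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) <= 1e-9 * np.maximum(np.abs(roots.real), 1.0)].real
    if real.size == 0:
        raise ArithmeticError(
            f"no real root found for params={params}, x={x} (roots={roots})"
        )
    lam = float(real.max())
    lower = max(1.0, params.omega1 * params.omega2 * x)
    if lam < lower - _BOUND_TOL * max(1.0, lower):
        raise ArithmeticError(
            f"largest root {lam} violates lambda1 >= max(1, w1 w2 x) = {lower}"
        )
    lam = max(lam, lower)
    resid = abs(np.polyval(coeffs, lam))
    if resid > _RESIDUAL_RTOL * max(1.0, lam**4):
        raise ArithmeticError(
            f"quartic residual {resid} too large at lambda1={lam}, x={x}"
        )
    return lam


# -- polynomial partial derivatives of P(lambda, x) ---------------------------
# P = lam^4 - (1 + w1 w2 x) lam^3 + w2 x (w1-1) lam^2
#     + x (w2-1)(1 + w1 w2 x) lam - w1 x^2 (w2-1)^2
# P is quartic in lambda and quadratic in x; all partials are cheap
# polynomials, used for the binding density and the titration Newton solve.


def _P_lam(w1: float, w2: float, lam: float, x: float) -> float:
    return (
        4.0 * lam**3
        - 3.0 * (1.0 + w1 * w2 * x) * lam**2
        + 2.0 * w2 * x * (w1 - 1.0) * lam
        + x * (w2 - 1.0) * (1.0 + w1 * w2 * x)
    )


def _P_x(w1: float, w2: float, lam: float, x: float) -> float:
    return (
        -w1 * w2 * lam**3
        + w2 * (w1 - 1.0) * lam**2
        + (w2 - 1.0) * (1.0 + 2.0 * w1 * w2 * x) * lam
        - 2.0 * w1 * x * (w2 - 1.0) ** 2
    )


def _P_lamlam(w1: float, w2: float, lam: float, x: float) -> float:
    return (
        12.0 * lam**2
        - 6.0 * (1.0 + w1 * w2 * x) * lam
        + 2.0 * w2 * x * (w1 - 1.0)
    )


def _P_lamx(w1: float, w2: float, lam: float, x: float) -> float:
    return (
        -3.0 * w1 * w2 * lam**2
        + 2.0 * w2 * (w1 - 1.0) * lam
        + (w2 - 1.0) * (1.0 + 2.0 * w1 * w2 * x)
    )


def _P_xx(w1: float, w2: float, lam: float, x: float) -> float:
    return 2.0 * w1 * w2 * (w2 - 1.0) * lam - 2.0 * w1 * (w2 - 1.0) ** 2


def nu_from_lambda_x(params: BindingParameters, lam: float, x: float) -> float:
    """Binding density from a consistent (lambda1, x) pair.

    nu = (x / lambda1) * N / D with N = -dP/dx and D = dP/dlambda, the
    implicit-differentiation form of nu = (x/lambda) dlambda/dx.
    """
    if x == 0.0:
        return 0.0
    w1, w2 = params.omega1, params.omega2
    num = -_P_x(w1, w2, lam, x)
    den = _P_lam(w1, w2, lam, x)
    if den == 0.0 or not math.isfinite(den):
        raise ArithmeticError(
            f"degenerate denominator in binding density at lambda1={lam}, x={x}"
        )
    nu = x * num / (lam * den)
    # clip tiny numerical excursions only
    if nu < -1e-12 or nu > 1.0 + 1e-12:
        raise ArithmeticError(f"nu={nu} out of [0,1] at lambda1={lam}, x={x}")
    return min(max(nu, 0.0), 1.0)


def binding_density(params: BindingParameters, x: float) -> float:
    """Equilibrium fraction of occupied sites at reduced activity x."""
    _check_x(x)
    if x == 0.0:
        return 0.0
    lam = largest_root(params, x)
    return nu_from_lambda_x(params, lam, x)


def lattice_point(params: BindingParameters, x: float) -> LatticePoint:
    """Consistent (x, lambda1, nu) triple at reduced activity x."""
    _check_x(x)
    if x == 0.0:
        return LatticePoint(0.0, 1.0, 0.0)
    lam = largest_root(params, x)
    return LatticePoint(x, lam, nu_from_lambda_x(params, lam, x))


def free_activity_from_lambda(params: BindingParameters, lambda1: float) -> float:
    """Reduced activity x for which lambda1 is the dominant quartic root.

    The characteristic quartic, read as A x^2 + B x + C = 0 with

        A = w1 (w2 - 1)(w2 (lam - 1) + 1)
        B = -lam [ (w1 lam + 1) w2 (lam - 1) + 1 ]
        C = lam^3 (lam - 1)

    has exactly one physically meaningful root x >= 0, evaluated in the
    subtraction-free form x = 2C / (-B + sqrt(B^2 - 4AC)); this form also
    degrades gracefully to the linear case A = 0 at omega2 = 1.
    """
    if lambda1 < 1.0:
        if lambda1 > 1.0 - 1e-12:
            lambda1 = 1.0
        else:
            raise ValueError(f"lambda1 must be >= 1, got {lambda1}")
    w1, w2 = params.omega1, params.omega2
    lam = lambda1
    if lam == 1.0:
        return 0.0
    A = w1 * (w2 - 1.0) * (w2 * (lam - 1.0) + 1.0)
    B = -lam * ((w1 * lam + 1.0) * w2 * (lam - 1.0) + 1.0)
    C = lam**3 * (lam - 1.0)
    disc = B * B - 4.0 * A * C
    if disc < 0:
        if disc > -1e-12 * B * B:
            disc = 0.0
        else:
            raise ArithmeticError(
                f"negative discriminant {disc} at lambda1={lam} (params={params})"
            )
    x = 2.0 * C / (-B + math.sqrt(disc))
    return x


def dx_dlambda(params: BindingParameters, lam: float, x: float) -> float:
    """d x / d lambda along the isotherm, by implicit differentiation."""
    w1, w2 = params.omega1, params.omega2
    return -_P_lam(w1, w2, lam, x) / _P_x(w1, w2, lam, x)


def nu_partials(
    params: BindingParameters, lam: float, x: float
) -> tuple[float, float]:
    """(d nu/d lambda, d nu/d x) at fixed other variable.

    nu(lam, x) = -(x/lam) P_x/P_lam; differentiating the closed form gives
    the partials needed for the titration Newton iteration.
    """
    w1, w2 = params.omega1, params.omega2
    Px = _P_x(w1, w2, lam, x)
    Pl = _P_lam(w1, w2, lam, x)
    Pll = _P_lamlam(w1, w2, lam, x)
    Plx = _P_lamx(w1, w2, lam, x)
    Pxx = _P_xx(w1, w2, lam, x)
    ratio = Px / Pl
    dratio_dlam = (Plx * Pl - Px * Pll) / (Pl * Pl)
    dratio_dx = (Pxx * Pl - Px * Plx) / (Pl * Pl)
    dnu_dlam = -x * dratio_dlam / lam + x * ratio / (lam * lam)
    dnu_dx = -(ratio + x * dratio_dx) / lam
    return dnu_dlam, dnu_dx


def oneD_largest_root(omega: float, x: float) -> float:
    """Larger root of the 1D characteristic quadratic
    lambda^2 - (1 + omega x) lambda + x (omega - 1) = 0."""
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    _check_x(x)
    b = 1.0 + omega * x
    disc = b * b - 4.0 * x * (omega - 1.0)
    return 0.5 * (b + math.sqrt(disc))


def oneD_binding_density(omega: float, x: float) -> float:
    """Binding density for the 1D nearest-neighbor lattice.

    This is the stoichiometry-1 McGhee–von Hippel isotherm; it satisfies
    the Scatchard form nu/x = (1 - nu) ((1 - 2 nu + R)/(2 (1 - nu)))^2
    with R = sqrt((1 - 2 nu)^2 + 4 omega nu (1 - nu)), and equals the 2D
    model at omega2 = 1.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    _check_x(x)
    if x == 0.0:
        return 0.0
    lam = oneD_largest_root(omega, x)
    # nu = (x/lam) dlam/dx from the quadratic: dlam/dx = (omega lam - (omega-1)) / (2 lam - 1 - omega x)
    return x * (omega * lam - (omega - 1.0)) / (lam * (2.0 * lam - 1.0 - omega * x))


def activity_at_density(
    params: BindingParameters, nu_target: float, tol: float = 1e-12
) -> tuple[float, float]:
    """Reduced activity x (and lambda1) at which the isotherm reaches nu_target.

    Inverts the strictly increasing map x -> nu by bracketing in lambda and
    using Brent's method; the result is independent of Kd.
    """
    if not (0.0 < nu_target < 1.0):
        raise ValueError(f"nu_target must lie in (0,1), got {nu_target}")

    def g(lam: float) -> float:
        x = free_activity_from_lambda(params, lam)
        return nu_from_lambda_x(params, lam, x) - nu_target

    lo, hi = 1.0 + 1e-13, 2.0
    while g(hi) < 0.0:
        hi *= 2.0
        if hi > 1e12:
            raise ArithmeticError(f"failed to bracket nu={nu_target} for {params}")
    lam = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    x = free_activity_from_lambda(params, lam)
    if abs(nu_from_lambda_x(params, lam, x) - nu_target) > max(tol, 1e-10):
        raise ArithmeticError(f"density round-trip failed at nu={nu_target}")
    return x, lam


def lambda_sweep(
    params: BindingParameters, lambda_grid: np.ndarray
) -> list[LatticePoint]:
    """Isotherm generated with lambda as the independent variable.

    No root finding is needed: x follows from the quadratic-in-x inversion
    and nu from the closed form.  Preferred for generating smooth curves.
    """
    pts = []
    for lam in np.asarray(lambda_grid, dtype=float):
        x = free_activity_from_lambda(params, float(lam))
        pts.append(LatticePoint(x, float(lam), nu_from_lambda_x(params, lam, x)))
    return pts


def x_sweep(params: BindingParameters, x_grid: np.ndarray) -> list[LatticePoint]:
    """Isotherm at user-specified reduced activities (quartic solved per point)."""
    return [lattice_point(params, float(x)) for x in np.asarray(x_grid, dtype=float)]
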