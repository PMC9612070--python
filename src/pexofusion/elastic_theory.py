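"""Elastic energies of the deformed monolayer: closed forms and a numeric oracle.

The monolayer is described in the Hamm–Kozlov tilt/bending framework by
two axisymmetric fields: the director projection ``n(r)`` and the
neutral-surface height ``h(r)``.  To quadratic order the energy density
(per unit radial coordinate, already including the ``2*pi*r`` measure) is

    w_e(r) = 2*pi*r * [ B/2*(dn/dr + n/r + Js)^2 - B/2*Js^2
                        + K/2*(n - dh/dr)^2 + sigma_tilde/2*(dh/dr)^2 ]

with bending modulus ``B``, tilt modulus ``K``, spontaneous curvature
``Js`` and lateral tension ``sigma_tilde = sigma*K``.

Two deformed configurations are needed along the fusion pathway:

*dimple* — a bulge of radius ``R`` whose apex is lifted by ``H``.  The
  membrane consists of a regular interior solution on ``[0, R]`` stitched
  (continuously in ``n`` and ``h``) to a decaying exterior solution on
  ``[R, inf)``.  Solving the Euler–Lagrange equations in both regions and
  eliminating the constants gives the closed form

      W_e = pi*K*H^2*(R/l)*sigma^(3/2)*sqrt(1+sigma)
            * I1*K1*(I1*K0 + I0*K1) / (I1*K0 + (I0-1)*K1)^2

  where every Bessel function is evaluated at the scaled radius
  ``R_sigma = (R/l)*sqrt(sigma/(1+sigma))`` and ``l = sqrt(B/K)``.
  W_e is exactly proportional to H^2 and carries no Js dependence (the
  linear spontaneous-curvature terms of the two regions cancel at the
  stitch point because ``n`` is continuous there).

*hydrophobic defect* — the membrane is absent for ``r < rho``; only the
  decaying exterior solution remains, held at height ``h(rho) = H``.
  The rim term linear in Js survives, giving

      W_e2 = pi*K*H*(rho/l)*sqrt(sigma*(1+sigma))
             * (2*Js*l^2 + H*sigma) * K1(rho_sigma)/K0(rho_sigma).

  For Js < 0 this is negative: a defect rim relaxes curvature frustration,
  which is what eventually makes the defect branch drop below the dimple
  branch.  The stalk energy is W_e2 evaluated at the contact height.

``numeric_shape_solver`` and ``numeric_defect_solver`` re-solve the same
Euler–Lagrange boundary-value problems with a generic collocation method
(``scipy.integrate.solve_bvp``; no Bessel functions anywhere on that
path) and integrate the energy density by quadrature.  They are the
independent oracle used to validate the closed-form transcriptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson, solve_bvp
from scipy.special import i0e, i1e, k0e, k1e

from .membrane_params import MonolayerParams

__all__ = [
    "SIGMA_MIN",
    "DimpleState",
    "ShapeSolution",
    "dimple_elastic_energy",
    "defect_elastic_energy",
    "functional_energy_density",
    "numeric_shape_solver",
    "numeric_defect_solver",
]

#: Below this dimensionless tension the Bessel arguments degenerate and the
#: closed forms lose numerical meaning; evaluation raises instead of
#: silently switching to asymptotics.
SIGMA_MIN = 1e-6


@dataclass(frozen=True)
class DimpleState:
    """Dimple radius R (nm) and apex height H (nm) — the reaction coordinate."""

    R: float
    H: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"dimple radius must be positive, got {self.R}")
        if self.H < 0:
            raise ValueError(f"dimple height must be >= 0, got {self.H}")


@dataclass(frozen=True)
class ShapeSolution:
    """Numerically solved membrane profile and its elastic energy.

    Attributes
    ----------
    r : ndarray
        Radial grid, nm.
    n : ndarray
        Director projection on the radial axis (dimensionless).
    h : ndarray
        Neutral-surface height, nm; decays to 0 far from the axis.
    energy : float
        Total elastic energy of the profile, k_BT.
    """

    r: np.ndarray
    n: np.ndarray
    h: np.ndarray
    energy: float

    def to_csv(self, path) -> None:
        """Write the profile as a three-column CSV (r_nm, n, h_nm)."""
        import pandas as pd

        pd.DataFrame({"r_nm": self.r, "n": self.n, "h_nm": self.h}).to_csv(
            path, index=False
        )


def _check_sigma(mono: MonolayerParams) -> None:
    if mono.sigma < SIGMA_MIN:
        raise ValueError(
            f"dimensionless tension sigma={mono.sigma} is below {SIGMA_MIN}; "
            "the tension-stabilised closed forms degenerate in this limit"
        )


def _scaled_radius(r: float, mono: MonolayerParams) -> float:
    """Bessel argument r_sigma = (r/l)*sqrt(sigma/(1+sigma))."""
    return (r / mono.l) * np.sqrt(mono.sigma / (1.0 + mono.sigma))


def dimple_elastic_energy(state: DimpleState, mono: MonolayerParams) -> float:
    """Elastic energy W_e of a dimple of radius R and height H, in k_BT.

    Exactly proportional to H^2 at fixed R; positive for H > 0; independent
    of the spontaneous curvature (see module docstring).
    """
    _check_sigma(mono)
    x = _scaled_radius(state.R, mono)
    # scaled Bessel products: I_m(x)*K_n(x) = i_me(x)*k_ne(x) exactly, so the
    # expression stays finite at arbitrarily large radii; the lone K1 term
    # carries the explicit exp(-x) and underflows harmlessly to 0
    I1K1 = i1e(x) * k1e(x)
    I1K0 = i1e(x) * k0e(x)
    I0K1 = i0e(x) * k1e(x)
    K1 = k1e(x) * np.exp(-x)
    sig = mono.sigma
    pref = (
        np.pi
        * mono.K
        * state.H**2
        * (state.R / mono.l)
        * sig**1.5
        * np.sqrt(1.0 + sig)
    )
    return float(pref * I1K1 * (I1K0 + I0K1) / (I1K0 + I0K1 - K1) ** 2)


def defect_elastic_energy(rho: float, H: float, mono: MonolayerParams) -> float:
    """Elastic energy W_e2 of the membrane around a hydrophobic defect, k_BT.

    ``rho`` is the defect radius (nm) and ``H`` the rim height (nm).  Linear
    in H at leading order, with a Js-dependent term that makes the energy
    negative for sufficiently negative spontaneous curvature.  Evaluated at
    the contact height this is the stalk energy.
    """
    if rho <= 0:
        raise ValueError(f"defect radius must be positive, got {rho}")
    if H < 0:
        raise ValueError(f"height must be >= 0, got {H}")
    _check_sigma(mono)
    x = _scaled_radius(rho, mono)
    sig = mono.sigma
    pref = np.pi * mono.K * H * (rho / mono.l) * np.sqrt(sig * (1.0 + sig))
    # K1/K0 via exponentially scaled Bessels: well-defined at any radius
    return float(pref * (2.0 * mono.Js * mono.l**2 + H * sig) * k1e(x) / k0e(x))


def functional_energy_density(
    r: float,
    n: float,
    dn_dr: float,
    dh_dr: float,
    mono: MonolayerParams,
) -> float:
    """Elastic energy density per unit radial coordinate, k_BT/nm.

    The integrand ``2*pi*r*w_e`` of the tilt/bending functional; the axis
    r = 0 is never evaluated (the solver grids start at a small positive
    radius where the regular solution behaves as ``n ~ r``).
    """
    if r <= 0:
        raise ValueError(f"radial coordinate must be positive, got {r}")
    B, K, Js = mono.B, mono.K, mono.Js
    sigma_tilde = mono.sigma_tilde
    div_n = dn_dr + n / r
    w = (
        0.5 * B * (div_n + Js) ** 2
        - 0.5 * B * Js**2
        + 0.5 * K * (n - dh_dr) ** 2
        + 0.5 * sigma_tilde * dh_dr**2
    )
    return float(2.0 * np.pi * r * w)


# --------------------------------------------------------------------------
# numeric Euler-Lagrange oracle
# --------------------------------------------------------------------------
#
# Varying the functional and using the first integral of the h-equation
# (zero vertical ring force in each force-free region) reduces the problem
# to, per region,
#
#   n'' = -n'/r + n/r^2 + sigma/((1+sigma)*l^2) * n,      h' = n/(1+sigma).
#
# The solver never forms Bessel functions: each region is handed to a
# generic collocation BVP solver and the energy is a quadrature of
# `functional_energy_density` over the solved profiles.


def _rhs(mono: MonolayerParams):
    c = mono.sigma / ((1.0 + mono.sigma) * mono.l**2)
    s1 = 1.0 + mono.sigma

    def rhs(r, y):
        # y = (n, n', h)
        return np.vstack([y[1], -y[1] / r + y[0] / r**2 + c * y[0], y[0] / s1])

    return rhs


def _solve_region(mono, r_grid, bc, y_guess, tol):
    sol = solve_bvp(_rhs(mono), bc, r_grid, y_guess, tol=tol, max_nodes=500_000)
    if not sol.success:
        raise RuntimeError(
            f"Euler-Lagrange BVP solve failed: {sol.message} "
            f"(max residual {np.max(sol.rms_residuals):.3e})"
        )
    return sol


def _region_energy(sol, a, b, mono, n_quad, scale=1.0):
    r = np.linspace(a, b, n_quad)
    y = sol.sol(r)
    n = scale * y[0]
    dn = scale * y[1]
    dh = n / (1.0 + mono.sigma)
    dens = np.array(
        [functional_energy_density(ri, ni, dni, dhi, mono)
         for ri, ni, dni, dhi in zip(r, n, dn, dh)]
    )
    return float(simpson(dens, x=r))


def _default_rmax(mono: MonolayerParams) -> float:
    # must cover several lateral decay lengths lambda = l*sqrt((1+sigma)/sigma)
    lam = mono.l * np.sqrt((1.0 + mono.sigma) / mono.sigma)
    return max(50.0 * mono.l, 6.0 * lam)


def numeric_shape_solver(
    R: float,
    H: float,
    H0: float,
    mono: MonolayerParams,
    *,
    r_min: float = 1e-3,
    r_max: float | None = None,
    grid: int = 300,
    tol: float = 1e-10,
    n_quad: int = 6000,
) -> ShapeSolution:
    """Solve the dimple boundary-value problem numerically; oracle for W_e.

    A regular interior solution on ``[r_min, R]`` (``n ~ r`` at the axis,
    apex height ``h = H``) is stitched continuously to a decaying exterior
    solution on ``[R, r_max]``.  Both regions are solved by generic
    collocation; the shared boundary value ``n(R)`` follows from height
    continuity by linearity.  Returns the stitched profile and the
    quadrature energy.
    """
    if R <= 0:
        raise ValueError(f"dimple radius must be positive, got {R}")
    if not 0 <= H <= H0:
        raise ValueError(f"height H={H} outside [0, H0={H0}]")
    _check_sigma(mono)
    if r_max is None:
        r_max = _default_rmax(mono)
    if H == 0.0:
        r = np.geomspace(r_min, r_max, grid)
        z = np.zeros_like(r)
        return ShapeSolution(r=r, n=z, h=z.copy(), energy=0.0)

    # interior, unit boundary director: n(R) = 1, regular at the axis,
    # height referenced to the apex (h(r_min) = 0)
    ri = np.geomspace(r_min, R, grid)
    yi = np.vstack([ri / R, np.ones_like(ri) / R, np.zeros_like(ri)])

    def bc_in(ya, yb):
        return np.array([ya[1] - ya[0] / r_min, yb[0] - 1.0, ya[2]])

    sol_in = _solve_region(mono, ri, bc_in, yi, tol)
    g = float(sol_in.sol(R)[2])  # apex-to-rim height drop per unit n(R)

    # exterior, unit boundary director: n(R) = 1, decay at r_max
    ro = np.geomspace(R, r_max, 2 * grid)
    yo = np.vstack(
        [np.exp(-(ro - R) / max(R, 1.0)), np.zeros_like(ro), np.zeros_like(ro)]
    )

    def bc_out(ya, yb):
        return np.array([ya[0] - 1.0, yb[0], yb[2]])

    sol_out = _solve_region(mono, ro, bc_out, yo, tol)
    q = float(sol_out.sol(R)[2])  # rim height per unit n(R)

    # height continuity: H + nu*g = nu*q  =>  amplitude of the unit solutions
    nu = H / (q - g)

    energy = _region_energy(sol_in, r_min, R, mono, n_quad, scale=nu) + _region_energy(
        sol_out, R, r_max, mono, n_quad, scale=nu
    )

    r_i = np.geomspace(r_min, R, grid)
    r_o = np.geomspace(R, r_max, 2 * grid)
    y_i = sol_in.sol(r_i)
    y_o = sol_out.sol(r_o)
    r_all = np.concatenate([r_i, r_o[1:]])
    n_all = nu * np.concatenate([y_i[0], y_o[0][1:]])
    # interior h is apex-referenced; shift so that the profile is continuous
    # and decays to 0 far away (h(apex) = H)
    h_i = H + nu * y_i[2]
    h_o = nu * y_o[2]
    h_all = np.concatenate([h_i, h_o[1:]])
    return ShapeSolution(r=r_all, n=n_all, h=h_all, energy=energy)


def numeric_defect_solver(
    rho: float,
    H: float,
    mono: MonolayerParams,
    *,
    r_max: float | None = None,
    grid: int = 600,
    tol: float = 1e-10,
    n_quad: int = 6000,
) -> ShapeSolution:
    """Solve the defect-rim boundary-value problem; oracle for W_e2.

    Only the exterior region exists (the membrane is removed for
    ``r < rho``); the rim is held at height ``h(rho) = H`` with a free
    director, and the profile decays at ``r_max``.  The quadrature energy
    includes the spontaneous-curvature rim term, so it is linear + quadratic
    in H exactly like the closed form.
    """
    if rho <= 0:
        raise ValueError(f"defect radius must be positive, got {rho}")
    if H < 0:
        raise ValueError(f"height must be >= 0, got {H}")
    _check_sigma(mono)
    if r_max is None:
        r_max = _default_rmax(mono)
    if H == 0.0:
        r = np.geomspace(rho, r_max, grid)
        z = np.zeros_like(r)
        return ShapeSolution(r=r, n=z, h=z.copy(), energy=0.0)

    ro = np.geomspace(rho, r_max, grid)
    yo = np.vstack(
        [np.zeros_like(ro), np.zeros_like(ro), H * np.exp(-(ro - rho) / max(rho, 1.0))]
    )

    def bc(ya, yb):
        return np.array([ya[2] - H, yb[0], yb[2]])

    sol = _solve_region(mono, ro, bc, yo, tol)
    energy = _region_energy(sol, rho, r_max, mono, n_quad)
    r = np.geomspace(rho, r_max, grid)
    y = sol.sol(r)
    return ShapeSolution(r=r, n=y[0], h=y[2], energy=energy)
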