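"""Forward models of amyloid fibril formation kinetics.

The model follows the standard nucleation/elongation/secondary-nucleation
moment equations for the fibril number concentration ``P`` and fibril mass
concentration ``M`` (in monomer equivalents)::

    dP/dt = k_n m^n_c + k_2 M m^n_2
    dM/dt = 2 k_plus m P
    m(t)  = m0 + M0 - M(t)

where ``m`` is the free monomer concentration, ``k_n``, ``k_plus`` and
``k_2`` are the primary-nucleation, elongation and secondary-nucleation rate
constants and ``n_c``, ``n_2`` the corresponding reaction orders.  The
factor 2 encodes growth at both fibril ends.  Monomer consumption by
nucleation events is neglected in the mass balance (only elongation consumes
monomer), the standard approximation of this framework.

For unseeded reactions the mass trajectory admits the closed-form integrated
rate law used for global fitting, expressed through the combined rates

    lambda = sqrt(2 k_plus k_n m0^n_c)        (primary pathway)
    kappa  = sqrt(2 k_plus k_2 m0^(n_2 + 1))  (secondary pathway)

and derived coefficients C±, B±, k_inf, k_inf_tilde (see
:func:`derived_coefficients`).

Units: concentrations in mol/L, time in seconds throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "DerivedCoefficients",
    "MassTrajectory",
    "derived_coefficients",
    "fibril_mass_closed_form",
    "integrate_moment_odes",
    "nucleation_rate",
    "total_nucleation_units",
    "oligomer_fold_change",
]


@dataclass(frozen=True)
class KineticParameters:
    """Microscopic rate constants and reaction orders of the aggregation model.

    Parameters
    ----------
    k_n : float
        Primary nucleation rate constant, concentration^(1-n_c) s^-1.
    k_plus : float
        Elongation rate constant, M^-1 s^-1.
    k_2 : float
        Secondary nucleation rate constant, concentration^(-n_2) s^-1.
    n_c, n_2 : float
        Reaction orders of primary and secondary nucleation.  Default 2,
        the standard values for the 42-residue amyloid-beta peptide.
    m0 : float
        Initial free monomer concentration, mol/L.
    M0 : float
        Initial seed fibril mass in monomer equivalents, mol/L (0 = unseeded).
    L_seed : float
        Mean number of monomers per seed fibril; sets the seed number
        concentration P(0) = M0 / L_seed.  Only used when M0 > 0.
    """

    k_n: float
    k_plus: float
    k_2: float
    m0: float
    n_c: float = 2.0
    n_2: float = 2.0
    M0: float = 0.0
    L_seed: float = 100.0

    def __post_init__(self) -> None:
        if self.k_n < 0 or self.k_plus < 0 or self.k_2 < 0:
            raise ValueError("rate constants must be non-negative")
        if self.n_c < 1:
            raise ValueError("primary nucleation order n_c must be >= 1")
        if self.n_2 < 0:
            raise ValueError("secondary nucleation order n_2 must be >= 0")
        if self.m0 <= 0:
            raise ValueError("initial monomer concentration m0 must be > 0")
        if self.M0 < 0:
            raise ValueError("seed mass M0 must be >= 0")
        if self.M0 > 0 and self.L_seed < 2:
            raise ValueError("seed length L_seed must be >= 2 when seeded")

    @property
    def m_total(self) -> float:
        """Total aggregating mass m0 + M0 (mol/L)."""
        return self.m0 + self.M0

    def scaled(self, **factors: float) -> "KineticParameters":
        """Return a copy with rate constants multiplied by the given factors.

        Keys are among ``k_n``, ``k_plus``, ``k_2``; e.g.
        ``params.scaled(k_2=0.5)`` halves secondary nucleation.
        """
        updates = {}
        for name, fac in factors.items():
            if name not in ("k_n", "k_plus", "k_2"):
                raise KeyError(f"cannot scale {name!r}")
            if fac < 0:
                raise ValueError("scaling factors must be non-negative")
            updates[name] = getattr(self, name) * fac
        return replace(self, **updates)


@dataclass(frozen=True)
class DerivedCoefficients:
    """Combined rates and coefficients of the integrated rate law.

    ``lam`` and ``kappa`` (both s^-1) combine the microscopic constants for
    the primary and secondary pathway; C±, B± are dimensionless, and
    ``k_inf``, ``k_inf_tilde`` (s^-1) are the asymptotic rates.
    """

    lam: float
    kappa: float
    C_plus: float
    C_minus: float
    B_plus: float
    B_minus: float
    k_inf: float
    k_inf_tilde: float


@dataclass
class MassTrajectory:
    """Numerical trajectory of the moment equations.

    Attributes
    ----------
    t : ndarray
        Time grid (s).
    M : ndarray
        Fibril mass concentration in monomer equivalents (mol/L).
    m : ndarray
        Free monomer concentration (mol/L).
    P : ndarray
        Fibril number concentration (mol/L).
    params : KineticParameters
        Parameters the trajectory was integrated with.
    """

    t: np.ndarray
    M: np.ndarray
    m: np.ndarray
    P: np.ndarray
    params: KineticParameters = field(repr=False)

    @property
    def normalized_mass(self) -> np.ndarray:
        """M(t) scaled to [0, 1] between M0 and full conversion."""
        p = self.params
        return (self.M - p.M0) / (p.m_total - p.M0)

    @property
    def completion(self) -> float:
        """Fraction of the initially free monomer converted at the last point."""
        return float((self.M[-1] - self.params.M0) / self.params.m0)

    def half_time(self) -> float:
        """Time at which half of the free monomer has been converted."""
        y = self.normalized_mass
        if y[-1] < 0.5:
            raise ValueError("trajectory does not reach half-completion")
        return float(np.interp(0.5, y, self.t))


def derived_coefficients(params: KineticParameters) -> DerivedCoefficients:
    """Compute the combined rates and coefficients of the integrated rate law.

    lambda = sqrt(2 k+ k_n m0^n_c), kappa = sqrt(2 k+ k_2 m0^(n_2+1)),
    C± = ±lambda²/(2 kappa²), k_inf = sqrt(2 kappa²/(n_2(n_2+1)) + 2 lambda²/n_c),
    k_inf_tilde = sqrt(k_inf² − 4 C₊ C₋ kappa²), B± = (k_inf ± k_inf_tilde)/(2 kappa).

    Requires an active secondary pathway (k_plus > 0 and k_2 > 0); the
    closed form degenerates otherwise and the ODE path must be used.
    """
    if params.k_plus <= 0 or params.k_2 <= 0:
        raise ValueError(
            "derived coefficients require k_plus > 0 and k_2 > 0; "
            "use integrate_moment_odes for pathways without secondary nucleation"
        )
    m0, n_c, n_2 = params.m0, params.n_c, params.n_2
    lam = math.sqrt(2.0 * params.k_plus * params.k_n * m0**n_c)
    kappa = math.sqrt(2.0 * params.k_plus * params.k_2 * m0 ** (n_2 + 1.0))
    C_plus = lam**2 / (2.0 * kappa**2)
    C_minus = -C_plus
    k_inf = math.sqrt(2.0 * kappa**2 / (n_2 * (n_2 + 1.0)) + 2.0 * lam**2 / n_c)
    k_inf_tilde = math.sqrt(k_inf**2 - 4.0 * C_plus * C_minus * kappa**2)
    B_plus = (k_inf + k_inf_tilde) / (2.0 * kappa)
    # stable equivalent of (k_inf - k_inf_tilde)/2/kappa: avoids cancellation
    # when the primary pathway is weak (k_inf_tilde ~ k_inf)
    B_minus = (
        2.0 * C_plus * C_minus * kappa / (k_inf + k_inf_tilde)
        if (k_inf + k_inf_tilde) > 0
        else 0.0
    )
    return DerivedCoefficients(
        lam=lam,
        kappa=kappa,
        C_plus=C_plus,
        C_minus=C_minus,
        B_plus=B_plus,
        B_minus=B_minus,
        k_inf=k_inf,
        k_inf_tilde=k_inf_tilde,
    )


def _log_b_plus_cu(B: float, C: float, kt: np.ndarray) -> np.ndarray:
    # log(B + C e^{kt}) computed stably for large kt; the argument is
    # guaranteed positive for the coefficient combinations that occur here.
    # Written as log(C) + kt + log1p((B/C) e^{-kt}).
    ratio = (B / C) * np.exp(-kt)
    return math.log(C) + kt + np.log1p(ratio)


def fibril_mass_closed_form(
    params: KineticParameters, t: np.ndarray
) -> np.ndarray:
    """Normalized fibril mass M(t)/M(inf) from the integrated rate law.

    Implements the unseeded closed-form solution

        M(t)/M(inf) = 1 - [ (B+ + C+)(B- + C+ e^{kt})
                          / ((B+ + C+ e^{kt})(B- + C+)) ]^{k_inf²/(k k~inf)}
                        · e^{-k_inf t}

    with k = kappa.  Valid for unseeded reactions only (M0 = 0); seeded
    reactions must use :func:`integrate_moment_odes`.
    """
    if params.M0 > 0:
        raise ValueError("closed form is for unseeded reactions (M0 = 0)")
    if params.k_n <= 0:
        raise ValueError("closed form requires k_n > 0 (no nucleation source otherwise)")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    c = derived_coefficients(params)
    kt = c.kappa * t
    # log of the bracketed fraction, stable at large kappa*t
    log_frac = (
        math.log(c.B_plus + c.C_plus)
        + _log_b_plus_cu(c.B_minus, c.C_plus, kt)
        - math.log(c.B_minus + c.C_plus)
        - _log_b_plus_cu(c.B_plus, c.C_plus, kt)
    )
    exponent = c.k_inf**2 / (c.kappa * c.k_inf_tilde)
    log_decay = exponent * log_frac - c.k_inf * t
    y = 1.0 - np.exp(log_decay)
    # guard against roundoff just below 0 at t=0
    return np.clip(y, 0.0, 1.0)


def _moment_rhs(t, y, p: KineticParameters):
    P, M = y
    m = max(p.m_total - M, 0.0)
    dP = p.k_n * m**p.n_c + p.k_2 * M * m**p.n_2
    dM = 2.0 * p.k_plus * m * P
    return [dP, dM]


def integrate_moment_odes(
    params: KineticParameters,
    t: np.ndarray,
    rtol: float = 1e-8,
    atol_scale: float = 1e-12,
) -> MassTrajectory:
    """Integrate the moment equations on the given time grid.

    Works for seeded and unseeded reactions.  Initial conditions are
    P(0) = M0/L_seed, M(0) = M0.  Uses a stiff-capable solver (LSODA)
    with relative tolerance 1e-8 by default.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")
    P0 = params.M0 / params.L_seed if params.M0 > 0 else 0.0
    y0 = [P0, params.M0]
    atol = [atol_scale * max(params.m_total, 1e-30)] * 2
    t0 = float(t[0])
    sol = solve_ivp(
        _moment_rhs,
        (t0, float(t[-1])),
        y0,
        t_eval=t,
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"moment-equation integration failed: {sol.message}; "
            "the system may be stiff at these parameters — try a tighter "
            "tolerance or the 'Radau' method"
        )
    P, M = sol.y
    M = np.minimum(np.maximum.accumulate(np.maximum(M, params.M0)), params.m_total)
    m = params.m_total - M
    return MassTrajectory(t=t, M=M, m=m, P=P, params=params)


def nucleation_rate(
    params: KineticParameters, trajectory: MassTrajectory
) -> np.ndarray:
    """Instantaneous nucleation rate r_n(t) = k_n m^n_c + k_2 M m^n_2 (mol/L/s)."""
    m = np.asarray(trajectory.m, dtype=float)
    M = np.asarray(trajectory.M, dtype=float)
    return params.k_n * m**params.n_c + params.k_2 * M * m**params.n_2


def _default_horizon(params: KineticParameters) -> float:
    # rough timescale guess from the combined rates; refined by auto-extension
    try:
        c = derived_coefficients(params)
        rate = max(c.kappa, c.lam)
    except ValueError:
        rate = math.sqrt(
            max(2.0 * params.k_plus * params.k_n * params.m0**params.n_c, 1e-300)
        )
        if params.M0 > 0:
            rate = max(rate, 2.0 * params.k_plus * (params.M0 / params.L_seed))
    return 30.0 / rate if rate > 0 else 1e7


def total_nucleation_units(
    params: KineticParameters,
    horizon: float | None = None,
    n_points: int = 2000,
    rel_tol: float = 1e-3,
) -> float:
    """Total nucleation units over the reaction: integral of r_n(t) dt (mol/L).

    The horizon is auto-extended until >= 99.9% of the free monomer is
    converted, and the trapezoid quadrature grid is refined until the
    integral is stable to ``rel_tol`` (0.1% by default).
    """
    if params.k_plus <= 0:
        raise ValueError(
            "total nucleation units diverge without elongation (monomer is never consumed)"
        )
    T = float(horizon) if horizon is not None else _default_horizon(params)
    total = None
    for _ in range(60):
        t = np.linspace(0.0, T, n_points)
        traj = integrate_moment_odes(params, t)
        if traj.completion < 0.999:
            T *= 2.0
            continue
        r = nucleation_rate(params, traj)
        total = float(np.trapezoid(r, t))
        # refine the grid until the quadrature is converged
        for _ in range(8):
            n_points *= 2
            t = np.linspace(0.0, T, n_points)
            traj = integrate_moment_odes(params, t)
            refined = float(np.trapezoid(nucleation_rate(params, traj), t))
            if abs(refined - total) <= rel_tol * abs(refined):
                return refined
            total = refined
        return total
    warnings.warn(
        "reaction did not reach 99.9% conversion within the extended horizon; "
        "nucleation-unit total may be truncated",
        RuntimeWarning,
    )
    t = np.linspace(0.0, T, n_points)
    traj = integrate_moment_odes(params, t)
    return float(np.trapezoid(nucleation_rate(params, traj), t))


def oligomer_fold_change(
    params_control: KineticParameters,
    params_inhibited: KineticParameters,
) -> float:
    """Fold change in total nucleation units, inhibited relative to control.

    Both parameter sets must share the initial monomer concentration and
    reaction orders; only the rate constants may differ (e.g. through an
    inhibitor acting on k_2 and/or k_plus).
    """
    pc, pi = params_control, params_inhibited
    if (pc.m0, pc.n_c, pc.n_2) != (pi.m0, pi.n_c, pi.n_2):
        raise ValueError("control and inhibited conditions must share m0, n_c, n_2")
    if pc == pi:
        return 1.0
    return total_nucleation_units(pi) / total_nucleation_units(pc)
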