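"""Activator–inhibitor kinetics and linear stability analysis.

The patterning stage of cranial-vault ossification is modelled with a
Gierer–Meinhardt-type activator–inhibitor system

    dCa/dt = sigma_a - mu_a*Ca + rho_a*Ca^2/Ch + D_a * lap(Ca)
    dCh/dt = sigma_h - mu_h*Ch + rho_h*Ca^2   + D_h * lap(Ch)

where the activator autocatalyses (Ca^2), promotes the inhibitor, and is
suppressed by it (division by Ch). Diffusion-driven (Turing) instability of
the homogeneous steady state requires the inhibitor to diffuse much faster
than the activator; the admissible parameter window is expressed as a
two-sided bound on the depletion ratio mu_h/mu_a.

This module provides the reaction terms, the closed-form homogeneous steady
state, the pattern-formation bounds, and the dispersion relation omega(q)
giving the linear growth rate of a perturbation mode of angular wavenumber q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

#: Concentration floor applied inside the Ca^2/Ch quotient only, guarding
#: against transient inhibitor undershoot in explicit stepping (ng/mm^3).
CH_FLOOR = 1.0e-12


@dataclass
class TuringParams:
    """Reaction–diffusion parameters of the activator–inhibitor system.

    Defaults are the baseline set for mouse cranial-vault patterning
    (production/depletion in ng mm^-3 s^-1 and s^-1, diffusion in mm^2 s^-1).
    """

    sigma_a: float = 1.0e-5   # activator production, ng/(mm^3 s)
    sigma_h: float = 1.0e-5   # inhibitor production, ng/(mm^3 s)
    mu_a: float = 5.0e-5      # activator depletion, 1/s
    mu_h: float = 1.0e-4      # inhibitor depletion, 1/s
    rho_a: float = 5.0e-5     # activator coupling, 1/s
    rho_h: float = 1.0e-4     # inhibitor coupling, mm^3/(ng s)
    D_a: float = 2.5e-6       # activator diffusion, mm^2/s
    D_h: float = 2.5e-4       # inhibitor diffusion, mm^2/s

    def validate(self) -> None:
        for name in ("sigma_a", "sigma_h", "mu_a", "mu_h", "rho_a", "rho_h",
                     "D_a", "D_h"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in ("D_a", "D_h"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be strictly positive")

    def require_nonzero(self, *names: str) -> None:
        """Raise if any named parameter is zero (denominator guards)."""
        for name in names:
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be nonzero here (denominator)")


@dataclass
class SteadyState:
    """Homogeneous fixed point of the reaction kinetics (ng/mm^3)."""

    Ca0: float
    Ch0: float


@dataclass
class StabilityReport:
    """Result of the linear stability analysis.

    ``turing_unstable`` holds iff the depletion ratio mu_h/mu_a lies inside
    [lower_bound, upper_bound) and some finite-wavelength mode grows
    (omega_max > 0). ``k_max`` is the angular wavenumber (rad/mm) of the
    fastest-growing mode and ``wavelength`` = 2*pi/k_max its spacing.
    """

    lower_bound: float
    ratio: float
    upper_bound: float
    turing_unstable: bool
    k_max: float
    omega_max: float

    @property
    def wavelength(self) -> float:
        return 2.0 * np.pi / self.k_max if self.k_max > 0 else np.inf


def steady_state(p: TuringParams) -> SteadyState:
    """Closed-form homogeneous steady state.

    Setting time derivatives and diffusion to zero gives
    ``Ca0 = mu_h*rho_a/(mu_a*rho_h) + sigma_a/mu_a`` and
    ``Ch0 = (rho_h/mu_h) * Ca0**2``. With the default parameters this is
    (1.20, 1.44) ng/mm^3.
    """
    p.validate()
    p.require_nonzero("mu_a", "mu_h", "rho_h")
    ca0 = p.mu_h * p.rho_a / (p.mu_a * p.rho_h) + p.sigma_a / p.mu_a
    ch0 = p.rho_h / p.mu_h * ca0**2
    return SteadyState(Ca0=ca0, Ch0=ch0)


def reaction_rates(
    Ca: np.ndarray | float, Ch: np.ndarray | float, p: TuringParams
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Reaction parts of the activator/inhibitor equations (no diffusion).

    Returns ``(sigma_a - mu_a*Ca + rho_a*Ca^2/Ch, sigma_h - mu_h*Ch + rho_h*Ca^2)``
    in ng mm^-3 s^-1. The quotient divides by ``max(Ch, CH_FLOOR)``.
    """
    Ca = np.asarray(Ca, dtype=float)
    Ch = np.asarray(Ch, dtype=float)
    ch_safe = np.maximum(Ch, CH_FLOOR)
    ca2 = Ca * Ca
    dca = p.sigma_a - p.mu_a * Ca + p.rho_a * ca2 / ch_safe
    dch = p.sigma_h - p.mu_h * Ch + p.rho_h * ca2
    if dca.ndim == 0:
        return float(dca), float(dch)
    return dca, dch


def jacobian(p: TuringParams, ss: SteadyState | None = None) -> np.ndarray:
    """Analytic Jacobian of the reaction terms at the homogeneous steady state."""
    if ss is None:
        ss = steady_state(p)
    ca, ch = ss.Ca0, ss.Ch0
    return np.array(
        [
            [-p.mu_a + 2.0 * p.rho_a * ca / ch, -p.rho_a * ca**2 / ch**2],
            [2.0 * p.rho_h * ca, -p.mu_h],
        ]
    )


def dispersion_relation(
    p: TuringParams, k: float | np.ndarray
) -> float | np.ndarray:
    """Linear growth rate omega(k) of a perturbation mode (max real eigenvalue).

    ``k`` is the *angular* wavenumber (perturbation ~ cos(k*x), rad/mm), so a
    cosine with m periods over a length L has k = 2*pi*m/L. omega is the
    largest real part of the eigenvalues of ``J - k^2 diag(D_a, D_h)`` with J
    the reaction Jacobian at the steady state. A positive omega means the
    mode grows and patterning can occur at that wavelength.
    """
    J = jacobian(p)
    karr = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(karr < 0):
        raise ValueError("wavenumber k must be >= 0")
    out = np.empty_like(karr)
    for i, ki in enumerate(karr):
        M = J - ki**2 * np.diag([p.D_a, p.D_h])
        # closed form for a 2x2: eigs = (tr +- sqrt(tr^2 - 4 det))/2
        tr = M[0, 0] + M[1, 1]
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        disc = tr * tr - 4.0 * det
        if disc >= 0:
            out[i] = 0.5 * (tr + np.sqrt(disc))
        else:
            out[i] = 0.5 * tr  # complex pair: real part
    return float(out[0]) if np.isscalar(k) or np.ndim(k) == 0 else out


def _find_k_max(p: TuringParams, k_hi: float = 50.0) -> tuple[float, float]:
    """Angular wavenumber and growth rate of the fastest-growing mode."""
    ks = np.linspace(0.0, k_hi, 2001)
    om = dispersion_relation(p, ks)
    i = int(np.argmax(om))
    if i == 0:
        return 0.0, float(om[0])
    lo, hi = ks[max(i - 1, 0)], ks[min(i + 1, len(ks) - 1)]
    res = minimize_scalar(
        lambda k: -dispersion_relation(p, float(k)), bounds=(lo, hi),
        method="bounded", options={"xatol": 1e-8},
    )
    return float(res.x), float(-res.fun)


def stability_bounds(p: TuringParams) -> StabilityReport:
    """Pattern-formation window for the activator–inhibitor system.

    The homogeneous state is Turing-unstable when

        2*mu_h*rho_a/(mu_h*rho_a + sigma_a*rho_h) - 1
            <= mu_h/mu_a <
        (D_h/D_a) * (sqrt(2*mu_h*rho_a/(mu_h*rho_a + sigma_a*rho_h)) - 1)^2

    With the default parameter set this evaluates to 0.667 < 2.0 < 8.468.
    The report also carries the fastest-growing wavenumber and its rate.
    """
    p.validate()
    p.require_nonzero("mu_a", "mu_h", "rho_h")
    if p.mu_h * p.rho_a + p.sigma_a * p.rho_h == 0:
        raise ValueError("mu_h*rho_a + sigma_a*rho_h must be nonzero")
    a = 2.0 * p.mu_h * p.rho_a / (p.mu_h * p.rho_a + p.sigma_a * p.rho_h)
    lower = a - 1.0
    ratio = p.mu_h / p.mu_a
    upper = (p.D_h / p.D_a) * (np.sqrt(a) - 1.0) ** 2
    k_max, omega_max = _find_k_max(p)
    unstable = bool(lower <= ratio < upper and omega_max > 0)
    return StabilityReport(
        lower_bound=float(lower),
        ratio=float(ratio),
        upper_bound=float(upper),
        turing_unstable=unstable,
        k_max=k_max,
        omega_max=omega_max,
    )
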