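"""Independent numerical oracles used only by the test suite.

These deliberately avoid the closed-form production code paths: the
two-compartment system is integrated as an ODE with a stiff solver, marginal
likelihoods are computed by adaptive quadrature, and matrix eigenvalues come
from a generic eigensolver.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp

from meropk import DosingRegimen, StructuralParams


def ode_concentrations(
    p: StructuralParams,
    doses: list[tuple[float, float, float]],
    t_eval: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Central concentrations from stiff ODE integration.

    ``doses`` is a list of (start time, amount mg, infusion duration h).
    Integration is piecewise between infusion switch points so the solver
    never steps across a rate discontinuity.
    """
    k10, k12, k21 = p.CL / p.Vc, p.Q / p.Vc, p.Q / p.Vp
    events = sorted({0.0, *[d[0] for d in doses], *[d[0] + d[2] for d in doses],
                     float(np.max(t_eval)) + 1e-9})

    def rate_in(t):
        return sum(amt / tinf for (t0, amt, tinf) in doses if t0 <= t < t0 + tinf)

    def rhs(t, a):
        return [rate_in(t) - (k10 + k12) * a[0] + k21 * a[1],
                k12 * a[0] - k21 * a[1],
                k10 * a[0]]  # a[2]: cumulative eliminated amount

    sols = []
    state = [0.0, 0.0, 0.0]
    for t0, t1 in zip(events, events[1:]):
        sol = solve_ivp(rhs, (t0, t1), state, method="LSODA",
                        rtol=rtol, atol=atol, dense_output=True)
        sols.append((t0, t1, sol.sol))
        state = sol.y[:, -1]

    out = np.zeros_like(np.asarray(t_eval, float))
    for i, t in enumerate(np.asarray(t_eval, float)):
        if t <= 0:
            continue
        for t0, t1, interp in sols:
            if t0 <= t <= t1 + 1e-12:
                out[i] = interp(min(t, t1))[0] / p.Vc
                break
    return out


def ode_mass_balance_error(p: StructuralParams, r: DosingRegimen, t_end: float) -> float:
    """Relative mass-balance error of the ODE solution at ``t_end``.

    Administered = central + peripheral + eliminated (+ any drug still in the
    un-infused remainder, zero for t_end > t_inf).
    """
    k10, k12, k21 = p.CL / p.Vc, p.Q / p.Vc, p.Q / p.Vp

    def rhs(t, a):
        rin = r.dose / r.t_inf if t < r.t_inf else 0.0
        return [rin - (k10 + k12) * a[0] + k21 * a[1],
                k12 * a[0] - k21 * a[1],
                k10 * a[0]]

    sol1 = solve_ivp(rhs, (0, r.t_inf), [0, 0, 0], method="LSODA", rtol=1e-11, atol=1e-13)
    sol2 = solve_ivp(rhs, (r.t_inf, t_end), sol1.y[:, -1], method="LSODA",
                     rtol=1e-11, atol=1e-13)
    a = sol2.y[:, -1]
    administered = r.dose
    return abs(a.sum() - administered) / administered


def eigen_half_lives(p: StructuralParams) -> tuple[float, float]:
    """Half-lives from the eigenvalues of the 2x2 disposition rate matrix."""
    k10, k12, k21 = p.CL / p.Vc, p.Q / p.Vc, p.Q / p.Vp
    M = np.array([[-(k10 + k12), k21], [k12, -k21]])
    lams = np.sort(np.linalg.eigvals(M).real)  # most negative first
    alpha, beta = -lams[0], -lams[1]
    return np.log(2) / alpha, np.log(2) / beta


def quadrature_ofv_1subject(
    y: np.ndarray,
    times: np.ndarray,
    conc_of_eta,
    omega: float,
    sigma_add: float,
    sigma_prop: float = 0.0,
) -> float:
    """-2 log marginal likelihood for one subject with one random effect.

    ``conc_of_eta(eta) -> predictions`` at ``times``; the eta integral is done
    by adaptive quadrature, no Laplace/FOCE approximation involved.
    """
    y = np.asarray(y, float)

    def integrand(eta):
        f = conc_of_eta(eta)
        R = sigma_add ** 2 + (sigma_prop * f) ** 2
        loglik = -0.5 * np.sum(np.log(2 * np.pi * R) + (y - f) ** 2 / R)
        logprior = -0.5 * (np.log(2 * np.pi * omega ** 2) + eta ** 2 / omega ** 2)
        return np.exp(loglik + logprior)

    val, _ = quad(integrand, -10 * omega, 10 * omega, limit=400, epsabs=1e-13, epsrel=1e-11)
    return -2.0 * np.log(val)


def wls_deviance(y: np.ndarray, f: np.ndarray, sigma_add: float, sigma_prop: float) -> float:
    """Fixed-effects-only -2 log likelihood (the omega -> 0 limit of FOCE)."""
    R = sigma_add ** 2 + (sigma_prop * f) ** 2
    return float(np.sum(np.log(2 * np.pi * R) + (y - f) ** 2 / R))
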