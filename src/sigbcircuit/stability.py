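"""Deterministic steady states and linear stability of the core circuit.

Steady states of the post-stress reaction-rate equations are located by
warm-started root finding, and classified by the eigenvalues of the drift
Jacobian.  The total phosphatase [P] + [PVP] is exactly conserved, so the
full Jacobian always carries one structural zero eigenvalue; all analysis
is therefore done in the reduced space with [P] eliminated through the
conservation law ([P] = p_stress - [PVP] post-stress).

Instability of the unique steady state in this dissipative system implies
a limit cycle in practice; :func:`oscillation_check` confirms it by
simulation rather than asserting it from the spectrum alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import _kernels
from .network import ParameterSet, ReactionNetwork, build_core_network

__all__ = [
    "StabilityBranch",
    "find_steady_state",
    "stability_at",
    "branch_scan",
    "oscillation_check",
]

RESIDUAL_TOL = 1e-9
#: eigenvalue real parts within this band of zero are flagged marginal
MARGINAL_BAND = 1e-8

_P_INDEX = 8     # index of P in the core species order
_PVP_INDEX = 9


def _args(network: ReactionNetwork):
    return (network.stoich_f, network.kinds, network.rates, network.idx1,
            network.idx2, network.prod_params[0], network.prod_params[1],
            network.prod_params[2], network.production_flag)


def _expand(y: np.ndarray, p_tot: float) -> np.ndarray:
    """Reduced (P eliminated) -> full 10-species state."""
    x = np.empty(10)
    x[:_P_INDEX] = y[:_P_INDEX]
    x[_P_INDEX] = p_tot - y[-1]
    x[_PVP_INDEX] = y[-1]
    return x


def _reduce(x: np.ndarray) -> np.ndarray:
    return np.concatenate([x[:_P_INDEX], x[_PVP_INDEX:]])


def reduced_drift(y: np.ndarray, network: ReactionNetwork, p_tot: float) -> np.ndarray:
    x = _expand(y, p_tot)
    f = _kernels.drift(x, *_args(network))
    return _reduce(f)


def reduced_jacobian(y: np.ndarray, network: ReactionNetwork, p_tot: float) -> np.ndarray:
    x = _expand(y, p_tot)
    J = _kernels.drift_jacobian(x, *_args(network))
    # substitute dP = -dPVP, then drop the P row/column
    J = J.copy()
    J[:, _PVP_INDEX] -= J[:, _P_INDEX]
    keep = [i for i in range(10) if i != _P_INDEX]
    return J[np.ix_(keep, keep)]


def _relaxation_state(network: ReactionNetwork, t_relax: float = 500.0) -> np.ndarray:
    """Long post-stress ODE relaxation used as a steady-state initial guess."""
    p_tot = network.params.p_stress
    x0 = np.zeros(10)
    x0[_P_INDEX] = p_tot
    y0 = _reduce(x0)
    sol = solve_ivp(
        lambda t, y: reduced_drift(y, network, p_tot),
        (0.0, t_relax), y0, method="LSODA",
        jac=lambda t, y: reduced_jacobian(y, network, p_tot),
        rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"relaxation solve failed: {sol.message}")
    return sol.y[:, -1]


def find_steady_state(params: ParameterSet,
                      initial_guess: np.ndarray | None = None
                      ) -> tuple[np.ndarray, float]:
    """Locate a steady state of the post-stress core drift.

    Returns (state, residual_norm) with the state in the full 10-species
    order (satisfying [P] + [PVP] = p_stress exactly).  ``initial_guess``
    (full 10-species) is tried first, then a long ODE relaxation; failure
    of both raises.
    """
    network = build_core_network(params)
    p_tot = params.p_stress
    guesses = []
    if initial_guess is not None:
        guesses.append(_reduce(np.asarray(initial_guess, dtype=float)))
    guesses.append(None)  # placeholder: relaxation, computed lazily
    for guess in guesses:
        if guess is None:
            guess = _relaxation_state(network)
        sol = root(
            lambda y: reduced_drift(y, network, p_tot), guess,
            jac=lambda y: reduced_jacobian(y, network, p_tot),
            method="hybr", tol=1e-12,
        )
        res = float(np.max(np.abs(reduced_drift(sol.x, network, p_tot))))
        if res < RESIDUAL_TOL:
            return _expand(sol.x, p_tot), res
    raise RuntimeError(
        f"steady-state search did not converge below {RESIDUAL_TOL} "
        f"(best residual {res:.3g})"
    )


def stability_at(params: ParameterSet, steady_state: np.ndarray) -> dict:
    """Leading eigenvalue (reduced Jacobian) and stability flag at a steady state."""
    network = build_core_network(params)
    y = _reduce(np.asarray(steady_state, dtype=float))
    res = float(np.max(np.abs(reduced_drift(y, network, params.p_stress))))
    if res > RESIDUAL_TOL:
        raise ValueError(f"state is not a steady state (residual {res:.3g})")
    J = reduced_jacobian(y, network, params.p_stress)
    eig = np.linalg.eigvals(J)
    lead = float(eig.real.max())
    if lead < -MARGINAL_BAND:
        flag = "stable"
    elif lead > MARGINAL_BAND:
        flag = "unstable"
    else:
        flag = "marginal"
    return {"leading_real": lead, "eigenvalues": eig, "flag": flag,
            "residual": res}


@dataclass
class StabilityBranch:
    """Steady-state branch along one swept parameter."""

    parameter: str
    values: np.ndarray
    states: np.ndarray          # (n_points, 10); NaN rows where missing
    leading_real: np.ndarray
    flags: list[str]            # stable / unstable / marginal / missing
    residuals: np.ndarray

    @property
    def unstable_intervals(self) -> list[tuple[float, float]]:
        """Contiguous swept-parameter sub-ranges with an unstable steady state."""
        out = []
        start = None
        for v, flag in zip(self.values, self.flags):
            if flag == "unstable":
                if start is None:
                    start = v
                end = v
            else:
                if start is not None:
                    out.append((float(start), float(end)))
                    start = None
        if start is not None:
            out.append((float(start), float(end)))
        return out

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            self.parameter: self.values,
            "sigB_steady": self.states[:, 0],
            "leading_real": self.leading_real,
            "flag": self.flags,
            "residual": self.residuals,
        })


def _set_parameter(params: ParameterSet, name: str, value: float) -> ParameterSet:
    if name == "p_prod":
        return params.with_substitution(value, params.p_frac)
    if name == "p_frac":
        return params.with_substitution(params.p_prod, value)
    return params.replace(**{name: value})


def branch_scan(parameter: str, values: np.ndarray,
                params: ParameterSet | None = None,
                warm_start: bool = True) -> StabilityBranch:
    """Steady-state and stability scan along one parameter.

    ``values`` may come from ``np.geomspace(p0/10, 10*p0, n)`` for the
    conventional tenfold-down/up scan.  The previous point's solution
    seeds the next (continuation-style warm start); per-point failures
    are flagged "missing" and the scan continues.
    """
    params = params or ParameterSet()
    values = np.asarray(values, dtype=float)
    n = values.size
    states = np.full((n, 10), np.nan)
    leading = np.full(n, np.nan)
    residuals = np.full(n, np.nan)
    flags: list[str] = []
    prev_state = None
    for i, v in enumerate(values):
        p_i = _set_parameter(params, parameter, float(v))
        try:
            guess = prev_state if warm_start else None
            if guess is not None and parameter in ("p_stress", "p_prod"):
                # keep the conservation level consistent with the new p_stress
                guess = guess.copy()
                guess[_P_INDEX] = max(p_i.p_stress - guess[_PVP_INDEX], 0.0)
            state, res = find_steady_state(p_i, guess)
            info = stability_at(p_i, state)
        except (RuntimeError, ValueError):
            flags.append("missing")
            continue
        states[i] = state
        leading[i] = info["leading_real"]
        residuals[i] = res
        flags.append(info["flag"])
        prev_state = state
    return StabilityBranch(parameter, values, states, leading, flags, residuals)


def oscillation_check(params: ParameterSet, t_end: float = 300.0,
                      settle: float = 150.0) -> bool:
    """Simulation-based confirmation that the deterministic system oscillates.

    Integrates the post-stress ODE and reports True when, after the
    settling time, sigma-B still shows bounded swings exceeding 10% of its
    mean (a relaxed steady state shows essentially none).
    """
    network = build_core_network(params)
    p_tot = params.p_stress
    x0 = np.zeros(10)
    x0[_P_INDEX] = p_tot
    y0 = _reduce(x0)
    t_eval = np.linspace(settle, t_end, 2000)
    sol = solve_ivp(
        lambda t, y: reduced_drift(y, network, p_tot),
        (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
        jac=lambda t, y: reduced_jacobian(y, network, p_tot),
        rtol=1e-9, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"oscillation-check solve failed: {sol.message}")
    sig = sol.y[0]
    mean = sig.mean()
    if mean <= 0:
        return False
    return bool((sig.max() - sig.min()) > 0.1 * mean)
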