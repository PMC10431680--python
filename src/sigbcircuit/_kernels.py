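"""Numba-compiled numeric kernels shared by the ODE, CLE and SSA engines.

The reaction network is passed in as flat arrays (propensity kind codes,
rate constants, reactant indices, stoichiometry) compiled by
:class:`~sigbcircuit.network.ReactionNetwork`.  Everything here is pure
numerics; validation and bookkeeping live in the public modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Propensity kind codes (mirrors network.py).
PROD, UNI, BI, DIM = 0, 1, 2, 3


@njit(cache=True)
def propensities(x, kinds, rates, idx1, idx2, v0, F, K, form):
    m = kinds.shape[0]
    a = np.empty(m)
    s = x[0]  # sigB is species 0 by construction
    if form == 0:
        f = v0 * (1.0 + F * s / (K + s))
    else:
        f = v0 * (1.0 + F * s) / (K + s)
    for j in range(m):
        k = kinds[j]
        if k == PROD:
            a[j] = rates[j] * f
        elif k == UNI:
            a[j] = rates[j] * x[idx1[j]]
        elif k == BI:
            a[j] = rates[j] * x[idx1[j]] * x[idx2[j]]
        else:
            a[j] = rates[j] * x[idx1[j]] * x[idx1[j]] * 0.5
    return a


@njit(cache=True)
def drift(x, S, kinds, rates, idx1, idx2, v0, F, K, form):
    a = propensities(x, kinds, rates, idx1, idx2, v0, F, K, form)
    return S @ a


@njit(cache=True)
def drift_jacobian(x, S, kinds, rates, idx1, idx2, v0, F, K, form):
    """Analytic Jacobian of the drift vector field."""
    n = S.shape[0]
    m = kinds.shape[0]
    J = np.zeros((n, n))
    s = x[0]
    if form == 0:
        dfds = v0 * F * K / ((K + s) * (K + s))
    else:
        dfds = v0 * (F * K - 1.0) / ((K + s) * (K + s))
    for j in range(m):
        k = kinds[j]
        if k == PROD:
            g = rates[j] * dfds
            for i in range(n):
                J[i, 0] += S[i, j] * g
        elif k == UNI:
            g = rates[j]
            c = idx1[j]
            for i in range(n):
                J[i, c] += S[i, j] * g
        elif k == BI:
            c1 = idx1[j]
            c2 = idx2[j]
            g1 = rates[j] * x[c2]
            g2 = rates[j] * x[c1]
            for i in range(n):
                J[i, c1] += S[i, j] * g1
                J[i, c2] += S[i, j] * g2
        else:
            c = idx1[j]
            g = rates[j] * x[c]
            for i in range(n):
                J[i, c] += S[i, j] * g
    return J


@njit(cache=True)
def _newton_step(x, dt, b, S, kinds, rates, idx1, idx2, v0, F, K, form,
                 tol, max_iter):
    """Solve y = x + dt*f(y) + b by damped Newton.  Returns (y, ok)."""
    n = x.shape[0]
    # Start from the current state: for stiff steps an explicit predictor
    # can land far outside the Newton basin.
    y = x + b
    r = y - x - dt * drift(y, S, kinds, rates, idx1, idx2, v0, F, K, form) - b
    rnorm = np.max(np.abs(r))
    for _ in range(max_iter):
        if rnorm < tol:
            return y, True
        J = drift_jacobian(y, S, kinds, rates, idx1, idx2, v0, F, K, form)
        A = -dt * J
        for i in range(n):
            A[i, i] += 1.0
        delta = np.linalg.solve(A, -r)
        lam = 1.0
        improved = False
        for _damp in range(10):
            y_new = y + lam * delta
            r_new = (y_new - x - b
                     - dt * drift(y_new, S, kinds, rates, idx1, idx2, v0, F, K, form))
            rn = np.max(np.abs(r_new))
            if rn < rnorm or rn < tol:
                y = y_new
                r = r_new
                rnorm = rn
                improved = True
                break
            lam *= 0.5
        if not improved:
            return y, False
    return y, rnorm < tol


@njit(cache=True)
def _implicit_advance(x, dt, b, S, kinds, rates, idx1, idx2, v0, F, K, form,
                      tol, max_iter, neg_floor):
    """One drift-implicit step with step-halving fallback.

    The explicit noise increment ``b`` is split evenly across sub-steps so
    the total injected noise per step is preserved exactly.  Sub-stepping
    is triggered both by Newton non-convergence and by the step landing
    below ``-neg_floor``: finer steps let the drift relax between noise
    kicks, which keeps the negative dips of the chemical-Langevin
    convention small.  Any component still below the floor after the
    deepest sub-stepping is clamped to ``-neg_floor``: mass action at
    sufficiently negative amounts (notably the quadratic dimerisation
    term) is a finite-time-blowup vector field with no backward-Euler
    root, so a lower barrier is required for stability; dips smaller than
    the floor are left untouched.  Returns (y, ok).
    """
    n = x.shape[0]
    nsub = 1
    y = x.copy()
    while nsub <= 1024:
        y = x.copy()
        sub_ok = True
        for _ in range(nsub):
            y, ok = _newton_step(y, dt / nsub, b / nsub, S, kinds, rates,
                                 idx1, idx2, v0, F, K, form, tol, max_iter)
            if not ok:
                sub_ok = False
                break
        if sub_ok:
            ymin = y[0]
            for i in range(n):
                if y[i] < ymin:
                    ymin = y[i]
            if ymin >= -neg_floor:
                return y, True
            if nsub >= 32:
                # dips persist at fine resolution: apply the barrier
                for i in range(n):
                    if y[i] < -neg_floor:
                        y[i] = -neg_floor
                return y, True
        nsub *= 2
    return y, False


@njit(cache=True)
def integrate_cle(x0, n_steps, dt, record_every, noise_scales, seed,
                  S, kinds, rates, idx1, idx2, v0, F, K, form,
                  tol, max_iter, neg_floor):
    """Fixed-step drift-implicit Euler-Maruyama path over n_steps.

    One independent Wiener increment per reaction per step; diffusion
    amplitude ``scale_j * sqrt(|a_j(x_n)|)`` evaluated explicitly at the
    start of the step, with the absolute value guarding transiently
    negative propensity arguments.  Records the state every
    ``record_every`` steps (including step 0 and the final step).

    Returns (path, status): path has shape (n_records, n_species);
    status 0 = ok, 1 = Newton failure, 2 = non-finite state (the failing
    step index is returned as the third element).
    """
    n = x0.shape[0]
    m = kinds.shape[0]
    n_rec = n_steps // record_every + 1
    path = np.empty((n_rec, n))
    x = x0.copy()
    path[0] = x
    np.random.seed(seed)
    noisy = False
    for j in range(m):
        if noise_scales[j] != 0.0:
            noisy = True
    sqrt_dt = np.sqrt(dt)
    rec = 1
    status = 0
    fail_step = -1
    for step in range(n_steps):
        b = np.zeros(n)
        if noisy:
            a = propensities(x, kinds, rates, idx1, idx2, v0, F, K, form)
            z = np.random.standard_normal(m)
            for j in range(m):
                sj = noise_scales[j]
                if sj != 0.0:
                    amp = sj * np.sqrt(np.abs(a[j])) * sqrt_dt * z[j]
                    for i in range(n):
                        b[i] += S[i, j] * amp
        x, ok = _implicit_advance(x, dt, b, S, kinds, rates, idx1, idx2,
                                  v0, F, K, form, tol, max_iter, neg_floor)
        if not ok:
            status = 1
            fail_step = step
            break
        finite = True
        for i in range(n):
            if not np.isfinite(x[i]):
                finite = False
        if not finite:
            status = 2
            fail_step = step
            break
        if (step + 1) % record_every == 0:
            path[rec] = x
            rec += 1
    return path, status, fail_step


@njit(cache=True)
def integrate_ssa(x0, t0, sample_times, seed,
                  S, kinds, rates, idx1, idx2, v0, F, K, form):
    """Gillespie direct-method path sampled onto ``sample_times``.

    Exponential waiting time with the total propensity; the reaction
    channel is chosen proportionally to its propensity.  When the total
    propensity reaches zero the state is held constant to the end.
    """
    n = x0.shape[0]
    m = kinds.shape[0]
    n_rec = sample_times.shape[0]
    path = np.empty((n_rec, n))
    x = x0.copy()
    t = t0
    np.random.seed(seed)
    rec = 0
    while rec < n_rec:
        a = propensities(x, kinds, rates, idx1, idx2, v0, F, K, form)
        a_tot = 0.0
        for j in range(m):
            a_tot += a[j]
        if a_tot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / a_tot)
        while rec < n_rec and sample_times[rec] < t_next:
            path[rec] = x
            rec += 1
        if rec >= n_rec:
            break
        # fire one reaction
        u = np.random.random() * a_tot
        acc = 0.0
        jsel = m - 1
        for j in range(m):
            acc += a[j]
            if u < acc:
                jsel = j
                break
        for i in range(n):
            x[i] += S[i, jsel]
            if x[i] < 0.0:
                x[i] = 0.0
        t = t_next
    return path
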