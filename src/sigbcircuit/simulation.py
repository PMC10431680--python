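"""Simulation engines: deterministic ODE, chemical Langevin, and Gillespie SSA.

All engines share a fixed output grid spanning a burn-in before stress and
the post-stress observation window (by default 10 h + 200 h, sampled every
0.01 h).  The chemical Langevin engine integrates

    dx_i = sum_j v_ij a_j(x) dt + sum_j s_j v_ij sqrt(|a_j(x)|) dW_j

with a drift-implicit, diffusion-explicit Euler-Maruyama scheme at a fixed
step.  The per-reaction noise scale ``s_j`` is ``eta`` for core reactions
and ``eta_amp`` for the upstream phosphatase-switching reactions of the
modified model; absolute values inside the square roots tolerate the
transiently negative concentrations such schemes can produce.  The SSA
engine is Gillespie's direct method on integer molecule counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from .network import (
    ParameterSet,
    ReactionNetwork,
    StressProtocol,
    apply_stress,
    build_core_network,
    build_modified_network,
)

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "Ensemble",
    "simulate_ode",
    "simulate_cle",
    "simulate_ssa",
    "simulate_ensemble",
    "ensemble_mean",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings shared by the fixed-step engines.

    ``dt`` is the Euler-Maruyama step (hours); ``sample_dt`` the output
    grid spacing and must be an integer multiple of ``dt``.  ``newton_tol``
    and ``newton_max_iter`` control the damped-Newton solve of the
    implicit drift step.  ``ode_method`` selects the deterministic engine:
    "implicit" shares the fixed-step scheme with the CLE (so the zero-noise
    CLE path and the ODE path coincide), "adaptive" uses a high-accuracy
    variable-step integrator.
    """

    dt: float = 0.005
    sample_dt: float = 0.01
    newton_tol: float = 1e-10
    newton_max_iter: int = 20
    negative_floor: float = 0.02
    ode_method: str = "implicit"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        ratio = self.sample_dt / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("sample_dt must be a positive integer multiple of dt")
        if self.ode_method not in ("implicit", "adaptive"):
            raise ValueError("ode_method must be 'implicit' or 'adaptive'")

    @property
    def record_every(self) -> int:
        return int(round(self.sample_dt / self.dt))


@dataclass
class Trajectory:
    """A single seeded time course of all species on a fixed grid."""

    times: np.ndarray            # hours, strictly increasing
    values: np.ndarray           # (n_times, n_species)
    species: tuple[str, ...]
    engine: str
    seed: int | None
    params: ParameterSet
    protocol: StressProtocol

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def activity(self, source: str = "free") -> np.ndarray:
        """Sigma-B activity trace: free [sigB] (default) or total
        sigma-B ([sigB] + [W2sigB])."""
        if source == "free":
            return self.series("sigB")
        if source == "total":
            return self.series("sigB") + self.series("W2sigB")
        raise ValueError(f"activity source must be 'free' or 'total', got {source!r}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.species))
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 params: ParameterSet | None = None,
                 protocol: StressProtocol | None = None,
                 engine: str = "file", seed: int | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        if "time_h" not in df.columns:
            raise ValueError(f"{path}: missing 'time_h' column")
        species = tuple(c for c in df.columns if c != "time_h")
        return cls(
            times=df["time_h"].to_numpy(float),
            values=df[list(species)].to_numpy(float),
            species=species,
            engine=engine,
            seed=seed,
            params=params or ParameterSet(),
            protocol=protocol or StressProtocol(),
        )


@dataclass
class Ensemble:
    """Trajectories sharing parameters, protocol and time grid, with
    member-specific seeds."""

    members: list[Trajectory]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        t0 = self.members[0].times
        for m in self.members[1:]:
            if m.times.shape != t0.shape or not np.allclose(m.times, t0):
                raise ValueError("ensemble members must share the time grid")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def times(self) -> np.ndarray:
        return self.members[0].times


def _segment_counts(t_a: float, t_b: float, settings: SimulationSettings) -> int:
    n = (t_b - t_a) / settings.dt
    n_int = int(round(n))
    if abs(n - n_int) > 1e-6:
        raise ValueError(
            f"segment ({t_a}, {t_b}) is not an integer number of dt={settings.dt} steps"
        )
    rec = settings.record_every
    if n_int % rec != 0:
        raise ValueError("segment length must be a multiple of sample_dt")
    return n_int


def _kernel_args(network: ReactionNetwork):
    return (network.stoich_f, network.kinds, network.rates, network.idx1,
            network.idx2, network.prod_params[0], network.prod_params[1],
            network.prod_params[2], network.production_flag)


def _run_fixed_step(network: ReactionNetwork, protocol: StressProtocol,
                    settings: SimulationSettings, noise_scales: np.ndarray,
                    seed: int, x0: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate burn-in and post-stress segments; returns (times, values).

    The grid point at the stress time carries the post-stress state (the
    step is applied at that instant)."""
    ss = np.random.SeedSequence(seed)
    seg_seeds = ss.generate_state(2)
    rec = settings.record_every
    args = _kernel_args(network)
    tol, mx, nf = settings.newton_tol, settings.newton_max_iter, settings.negative_floor

    n1 = _segment_counts(protocol.t_burnin_start, protocol.t_stress, settings)
    if x0 is None:
        x0 = network.initial_state()
    x0 = np.asarray(x0, dtype=float)
    path1, status, step = _kernels.integrate_cle(
        x0, n1, settings.dt, rec, noise_scales, seg_seeds[0], *args, tol, mx, nf)
    if status:
        _raise_engine_error(status, step, protocol.t_burnin_start, settings, path1)
    x_stress = apply_stress(path1[-1], network)

    n2 = _segment_counts(protocol.t_stress, protocol.t_end, settings)
    path2, status, step = _kernels.integrate_cle(
        x_stress, n2, settings.dt, rec, noise_scales, seg_seeds[1], *args, tol, mx, nf)
    if status:
        _raise_engine_error(status, step, protocol.t_stress, settings, path2)

    t1 = protocol.t_burnin_start + settings.sample_dt * np.arange(n1 // rec + 1)
    t2 = protocol.t_stress + settings.sample_dt * np.arange(n2 // rec + 1)
    times = np.concatenate([t1[:-1], t2])
    values = np.concatenate([path1[:-1], path2], axis=0)
    return times, values


def _raise_engine_error(status: int, step: int, t_start: float,
                        settings: SimulationSettings, path: np.ndarray) -> None:
    t_fail = t_start + step * settings.dt
    if status == 2:
        raise FloatingPointError(
            f"non-finite state at step {step} (t = {t_fail:.4f} h)"
        )
    raise RuntimeError(
        f"implicit Newton solve failed to converge at step {step} "
        f"(t = {t_fail:.4f} h) despite step-halving"
    )


def simulate_ode(network: ReactionNetwork,
                 protocol: StressProtocol | None = None,
                 settings: SimulationSettings | None = None,
                 x0: np.ndarray | None = None) -> Trajectory:
    """Deterministic reaction-rate trajectory with the stress step applied.

    The default method is the same fixed-step implicit Euler scheme as the
    CLE with the noise switched off; ``settings.ode_method="adaptive"``
    instead uses LSODA with tight tolerances (useful as an accuracy
    reference, e.g. for steady-state relaxation).
    """
    protocol = protocol or StressProtocol()
    settings = settings or SimulationSettings()
    if settings.ode_method == "implicit":
        zero = np.zeros(network.n_reactions)
        times, values = _run_fixed_step(network, protocol, settings, zero, 0, x0)
    else:
        times, values = _run_adaptive(network, protocol, settings, x0)
    return Trajectory(times, values, network.species, "ode", None,
                      network.params, protocol)


def _run_adaptive(network: ReactionNetwork, protocol: StressProtocol,
                  settings: SimulationSettings,
                  x0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    args = _kernel_args(network)

    def rhs(t, x):
        return _kernels.drift(x, *args)

    def jac(t, x):
        return _kernels.drift_jacobian(x, *args)

    n1 = _segment_counts(protocol.t_burnin_start, protocol.t_stress, settings)
    n2 = _segment_counts(protocol.t_stress, protocol.t_end, settings)
    rec = settings.record_every
    t1 = protocol.t_burnin_start + settings.sample_dt * np.arange(n1 // rec + 1)
    t2 = protocol.t_stress + settings.sample_dt * np.arange(n2 // rec + 1)
    if x0 is None:
        x0 = network.initial_state()
    sol1 = solve_ivp(rhs, (t1[0], t1[-1]), np.asarray(x0, dtype=float), t_eval=t1,
                     method="LSODA", jac=jac, rtol=1e-10, atol=1e-12)
    if not sol1.success:
        raise RuntimeError(f"adaptive ODE solve failed in burn-in: {sol1.message}")
    x_stress = apply_stress(sol1.y[:, -1], network)
    sol2 = solve_ivp(rhs, (t2[0], t2[-1]), x_stress, t_eval=t2,
                     method="LSODA", jac=jac, rtol=1e-10, atol=1e-12)
    if not sol2.success:
        raise RuntimeError(f"adaptive ODE solve failed post-stress: {sol2.message}")
    times = np.concatenate([t1[:-1], t2])
    values = np.concatenate([sol1.y.T[:-1], sol2.y.T], axis=0)
    return times, values


def simulate_cle(network: ReactionNetwork, seed: int,
                 protocol: StressProtocol | None = None,
                 settings: SimulationSettings | None = None,
                 eta: float | None = None,
                 eta_amp: float | None = None,
                 x0: np.ndarray | None = None) -> Trajectory:
    """Chemical-Langevin trajectory (drift-implicit Euler-Maruyama).

    ``eta``/``eta_amp`` override the noise scales in the parameter set
    without rebuilding the network.  Identical seed and settings give a
    bit-identical trajectory.
    """
    protocol = protocol or StressProtocol()
    settings = settings or SimulationSettings()
    scales = network.noise_scales(eta=eta, eta_amp=eta_amp)
    times, values = _run_fixed_step(network, protocol, settings, scales, int(seed), x0)
    return Trajectory(times, values, network.species, "cle", int(seed),
                      network.params, protocol)


def simulate_ssa(network: ReactionNetwork, seed: int,
                 protocol: StressProtocol | None = None,
                 settings: SimulationSettings | None = None,
                 x0: np.ndarray | None = None) -> Trajectory:
    """Gillespie direct-method trajectory on integer molecule counts.

    The initial state and the stress increment are rounded to integer
    counts; rate constants are used as-is (molecule-count units, matching
    the micromolar numbers by convention of the source model).
    """
    protocol = protocol or StressProtocol()
    settings = settings or SimulationSettings()
    ss = np.random.SeedSequence(int(seed))
    seg_seeds = ss.generate_state(2)
    args = _kernel_args(network)

    x0 = np.round(network.initial_state() if x0 is None else np.asarray(x0, dtype=float))
    rec = settings.record_every
    n1 = _segment_counts(protocol.t_burnin_start, protocol.t_stress, settings)
    n2 = _segment_counts(protocol.t_stress, protocol.t_end, settings)
    t1 = protocol.t_burnin_start + settings.sample_dt * np.arange(n1 // rec + 1)
    t2 = protocol.t_stress + settings.sample_dt * np.arange(n2 // rec + 1)
    path1 = _kernels.integrate_ssa(x0, t1[0], t1, seg_seeds[0], *args)
    delta = int(round(network.params.p_stress - network.params.p_init))
    x_stress = path1[-1].copy()
    x_stress[network.species.index("P")] += delta
    if "PI" in network.species:
        x_stress[network.species.index("PI")] += delta
    path2 = _kernels.integrate_ssa(x_stress, t2[0], t2, seg_seeds[1], *args)
    times = np.concatenate([t1[:-1], t2])
    values = np.concatenate([path1[:-1], path2], axis=0)
    return Trajectory(times, values, network.species, "ssa", int(seed),
                      network.params, protocol)


def simulate_ensemble(network: ReactionNetwork, n: int, base_seed: int,
                      protocol: StressProtocol | None = None,
                      settings: SimulationSettings | None = None,
                      engine: str = "cle") -> Ensemble:
    """n independent trajectories with seeds base_seed .. base_seed+n-1."""
    if n < 1:
        raise ValueError("ensemble size n must be >= 1")
    sim = {"cle": simulate_cle, "ssa": simulate_ssa}.get(engine)
    if sim is None:
        raise ValueError(f"ensemble engine must be 'cle' or 'ssa', got {engine!r}")
    members = []
    for k in range(n):
        seed = int(base_seed) + k
        try:
            members.append(sim(network, seed, protocol, settings))
        except Exception as exc:
            raise RuntimeError(f"ensemble member with seed {seed} failed: {exc}") from exc
    return Ensemble(members)


def ensemble_mean(ensemble: Ensemble, species: str = "sigB") -> np.ndarray:
    """Pointwise arithmetic mean of one species across the ensemble."""
    stack = np.stack([m.series(species) for m in ensemble.members])
    return stack.mean(axis=0)
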