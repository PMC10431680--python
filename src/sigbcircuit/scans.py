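"""Ensemble parameter sweeps and the reductions used for heatmap figures.

A sweep evaluates the behaviour magnitudes on a full grid over one or
more parameters, with an ensemble of seeded stochastic simulations per
cell.  Cells are independent and deterministically seeded from
(base_seed, cell index), so any sub-scan can be reproduced in isolation
and results do not depend on evaluation order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .measures import (
    BehaviourScores,
    MeasureProfile,
    behaviour_magnitudes,
    dual_distinctness,
    single_distinctness,
)
from .network import ParameterSet, StressProtocol, build_core_network, build_modified_network
from .simulation import Ensemble, SimulationSettings, simulate_ensemble

__all__ = ["ScanResult", "sweep", "max_over_parameter", "distinctness_profile",
           "locate_optimum"]

#: spacing between per-cell seed blocks; must exceed any per-cell n
SEED_STRIDE = 10_000


def _set_parameter(params: ParameterSet, name: str, value: float) -> ParameterSet:
    if name == "p_prod":
        return params.with_substitution(value, params.p_frac)
    if name == "p_frac":
        return params.with_substitution(params.p_prod, value)
    return params.replace(**{name: value})


@dataclass
class ScanResult:
    """Grid of ensemble-mean behaviour scores over 1-3 swept parameters."""

    axes: list[str]
    grids: list[np.ndarray]
    M_srp: np.ndarray               # shape = tuple(len(g) for g in grids)
    M_sp: np.ndarray
    seeds: np.ndarray               # per-cell base seed (same shape)
    n: int
    params: ParameterSet
    errors: dict = field(default_factory=dict)   # flat cell index -> message
    argmax_info: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.grids)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per cell with axis values and both scores."""
        rows = []
        for idx in itertools.product(*map(range, self.shape)):
            row = {ax: self.grids[d][i] for d, (ax, i) in enumerate(zip(self.axes, idx))}
            row["M_srp"] = self.M_srp[idx]
            row["M_sp"] = self.M_sp[idx]
            row["seed"] = self.seeds[idx]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "axes": self.axes,
            "grids": [g.tolist() for g in self.grids],
            "M_srp": self.M_srp.tolist(),
            "M_sp": self.M_sp.tolist(),
            "seeds": self.seeds.tolist(),
            "n": self.n,
            "params": self.params.to_dict(),
            "errors": self.errors,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def sweep(axes: Sequence[tuple[str, Sequence[float]]],
          base_params: ParameterSet | None = None,
          n: int = 50,
          base_seed: int = 0,
          model: str = "core",
          protocol: StressProtocol | None = None,
          settings: SimulationSettings | None = None,
          evaluator: Callable[[Ensemble], BehaviourScores] | None = None,
          activity_source: str = "free") -> ScanResult:
    """Evaluate behaviour magnitudes on the product grid of ``axes``.

    ``axes`` is a sequence of (parameter name, grid values); "p_prod" and
    "p_frac" are accepted and mapped through the substitution.  Per-cell
    failures are recorded in ``errors`` and the scan continues.
    """
    base_params = base_params or ParameterSet()
    evaluator = evaluator or (lambda ens: behaviour_magnitudes(ens, activity_source))
    build = build_core_network if model == "core" else build_modified_network
    names = [a[0] for a in axes]
    grids = [np.asarray(a[1], dtype=float) for a in axes]
    shape = tuple(len(g) for g in grids)
    M_srp = np.full(shape, np.nan)
    M_sp = np.full(shape, np.nan)
    seeds = np.zeros(shape, dtype=np.int64)
    errors: dict = {}
    for flat, idx in enumerate(itertools.product(*map(range, shape))):
        cell_seed = int(base_seed) + flat * SEED_STRIDE
        seeds[idx] = cell_seed
        try:
            p = base_params
            for d, i in enumerate(idx):
                p = _set_parameter(p, names[d], float(grids[d][i]))
            net = build(p)
            ens = simulate_ensemble(net, n=n, base_seed=cell_seed,
                                    protocol=protocol, settings=settings)
            scores = evaluator(ens)
            M_srp[idx] = scores.M_srp
            M_sp[idx] = scores.M_sp
        except Exception as exc:   # per-cell failure: record and continue
            errors[flat] = f"{type(exc).__name__}: {exc}"
    return ScanResult(names, grids, M_srp, M_sp, seeds, n, base_params, errors)


def max_over_parameter(scan: ScanResult, parameter: str) -> ScanResult:
    """Reduce one axis by taking the per-cell maximum score over it.

    Used for "best achievable over p_stress" style maps.  The argmax
    parameter values for both scores are kept in ``argmax_info``.
    """
    if parameter not in scan.axes:
        raise ValueError(f"{parameter!r} is not a scanned axis {scan.axes}")
    d = scan.axes.index(parameter)
    grid = scan.grids[d]

    def _reduce(arr):
        filled = np.where(np.isnan(arr), -np.inf, arr)
        k = filled.argmax(axis=d)
        mx = np.take_along_axis(filled, np.expand_dims(k, d), axis=d).squeeze(axis=d)
        mx = np.where(np.isinf(mx), np.nan, mx)
        return mx, grid[k]

    srp_max, srp_arg = _reduce(scan.M_srp)
    sp_max, sp_arg = _reduce(scan.M_sp)
    out = ScanResult(
        axes=[a for a in scan.axes if a != parameter],
        grids=[g for i, g in enumerate(scan.grids) if i != d],
        M_srp=srp_max, M_sp=sp_max,
        seeds=scan.seeds.max(axis=d),
        n=scan.n, params=scan.params, errors=dict(scan.errors),
    )
    out.argmax_info = {
        "reduced_parameter": parameter,
        "argmax_M_srp": srp_arg,
        "argmax_M_sp": sp_arg,
    }
    return out


def distinctness_profile(parameter: str, values: Sequence[float],
                         base_params: ParameterSet | None = None,
                         n: int = 50, base_seed: int = 0,
                         model: str = "core",
                         protocol: StressProtocol | None = None,
                         settings: SimulationSettings | None = None,
                         activity_source: str = "free") -> dict:
    """1-D magnitude profile along ``parameter`` plus its distinctness values.

    Returns a dict with the :class:`MeasureProfile` and the dual
    (D_srp_sp) and single (D_srp, D_sp) distinctness statistics.
    """
    scan = sweep([(parameter, values)], base_params, n, base_seed, model,
                 protocol, settings, activity_source=activity_source)
    profile = MeasureProfile(parameter, scan.grids[0], scan.M_srp, scan.M_sp)
    dual = dual_distinctness(profile)
    single = single_distinctness(profile)
    return {"profile": profile, "dual": dual, "single": single, "scan": scan}


def locate_optimum(scan: ScanResult, score: str = "M_sp") -> dict:
    """Argmax cell of one score; ties broken to the lowest flat index."""
    arr = getattr(scan, score)
    filled = np.where(np.isnan(arr), -np.inf, arr)
    flat = int(filled.argmax())          # first occurrence on ties
    idx = np.unravel_index(flat, scan.shape)
    best = filled.flat[flat]
    tie = int(np.sum(filled == best)) > 1
    return {
        "indices": tuple(int(i) for i in idx),
        "parameters": {ax: float(scan.grids[d][i])
                       for d, (ax, i) in enumerate(zip(scan.axes, idx))},
        "score": float(arr.flat[flat]),
        "tie": tie,
    }
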