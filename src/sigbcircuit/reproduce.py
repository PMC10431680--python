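"""Seeded reproduction bundles for the headline simulation experiments.

Each named experiment writes trajectory CSVs, scan/branch tables and a
JSON manifest (seeds, parameters, config hash) to an output directory.
Two presets are provided: "desk" (reduced ensemble sizes and grid
densities, minutes on one CPU) and "paper" (publication-scale n and
grids, hours).  Presets reduce only n and grid density — never the model
or the measures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .measures import behaviour_magnitudes, classify_response
from .network import ParameterSet, build_core_network
from .scans import distinctness_profile, locate_optimum, max_over_parameter, sweep
from .simulation import SimulationSettings, ensemble_mean, simulate_cle, simulate_ensemble, simulate_ssa
from .stability import branch_scan

__all__ = ["SUPPORTED", "reproduce"]

# Figure-level parameter conventions: the per-figure tables default to
# eta = 0.05 and p_stress = 0.4 uM unless the experiment varies them.
_FIG_DEFAULTS = dict(eta=0.05, p_stress=0.4)
# Base set for the effective-dephosphorylation-rate transition
# (k_K2, eta) at the both-behaviours optimum; p_frac fixed at an
# intermediate value (see methods note on its units).
_TRANSITION_BASE = dict(kK2=7.0, eta=0.025)
_TRANSITION_P_FRAC = 0.1


def _noise_step_response(out: Path, preset: str, seed: int) -> dict:
    """Mean sigma-B response for a ladder of noise amplitudes (step stress)."""
    etas = [0.01, 0.04, 0.07, 0.1] if preset == "desk" else \
        [0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.1]
    n = 20 if preset == "desk" else 150
    peaks = {}
    for eta in etas:
        net = build_core_network(ParameterSet(p_stress=0.4, eta=eta))
        ens = simulate_ensemble(net, n=n, base_seed=seed)
        mean = ensemble_mean(ens, "sigB")
        t = ens.times
        np.savetxt(out / f"mean_sigB_eta_{eta}.csv",
                   np.column_stack([t, mean]), delimiter=",",
                   header="time_h,mean_sigB", comments="")
        peaks[eta] = float(mean[(t >= 0) & (t <= 5)].max())
    return {"etas": etas, "n": n, "transient_peak_of_mean": peaks}


def _behaviour_maps(out: Path, preset: str, seed: int) -> dict:
    """Max-over-stress maps of both behaviours across (k_K2, eta)."""
    if preset == "desk":
        kk2 = np.geomspace(5.0, 40.0, 4)
        eta = np.linspace(0.02, 0.1, 4)
        p_stress = np.geomspace(0.1, 2.0, 5)
        n = 10
    else:
        kk2 = np.geomspace(3.6, 72.0, 10)
        eta = np.linspace(0.01, 0.12, 10)
        p_stress = np.geomspace(0.1, 2.0, 10)
        n = 100
    scan = sweep([("kK2", kk2), ("eta", eta), ("p_stress", p_stress)],
                 ParameterSet(), n=n, base_seed=seed)
    reduced = max_over_parameter(scan, "p_stress")
    (out / "behaviour_maps.json").write_text(reduced.to_json())
    reduced.to_frame().to_csv(out / "behaviour_maps.csv", index=False)
    return {
        "optimum_single_pulse": locate_optimum(reduced, "M_srp"),
        "optimum_stochastic_pulsing": locate_optimum(reduced, "M_sp"),
        "n": n,
    }


def _pulsing_samples(out: Path, preset: str, seed: int) -> dict:
    """Sample trajectories at the stochastic-pulsing optimum (k_K2, eta) = (9, 0.06)."""
    net = build_core_network(ParameterSet(kK2=9.0, eta=0.06, p_stress=0.15))
    n = 4
    for k in range(n):
        simulate_cle(net, seed=seed + k).to_csv(out / f"pulsing_sample_{k}.csv")
    ens = simulate_ensemble(net, n=20 if preset == "desk" else 100, base_seed=seed)
    scores = behaviour_magnitudes(ens)
    return {"M_srp": scores.M_srp, "M_sp": scores.M_sp, "n": scores.n,
            "max_member_M_sp": float(scores.per_member_M_sp.max())}


def _transition(out: Path, preset: str, seed: int) -> dict:
    """Response classification ladder along p_prod at the transition base set."""
    p_prods = [5.0, 18.0, 29.0, 60.0, 150.0, 400.0] if preset == "desk" else \
        [2.0, 5.0, 12.0, 18.0, 24.0, 29.0, 35.0, 60.0, 100.0, 150.0, 400.0, 1500.0]
    n = 20 if preset == "desk" else 100
    labels = {}
    for pp in p_prods:
        params = ParameterSet(**_TRANSITION_BASE).with_substitution(pp, _TRANSITION_P_FRAC)
        net = build_core_network(params)
        ens = simulate_ensemble(net, n=n, base_seed=seed)
        result = classify_response(ens)
        labels[pp] = result["label"]
        simulate_cle(net, seed=seed).to_csv(out / f"transition_p_prod_{pp:g}.csv")
    return {"p_prods": p_prods, "labels": labels, "n": n}


def _transition_ssa(out: Path, preset: str, seed: int) -> dict:
    """The p_prod transition re-created with Gillespie simulations over p_stress."""
    p_stresses = [1, 3, 6, 10, 30, 100] if preset == "desk" else \
        [1, 2, 3, 4, 6, 8, 10, 15, 30, 60, 100, 300]
    rows = {}
    for k, ps in enumerate(p_stresses):
        params = ParameterSet(kK2=7.0, kP=1.0, p_init=0.001, p_stress=float(ps))
        net = build_core_network(params)
        traj = simulate_ssa(net, seed=seed + k)
        traj.to_csv(out / f"ssa_p_stress_{ps}.csv")
        sig = traj.activity()
        t = traj.times
        rows[ps] = {
            "transient_max": float(sig[(t >= 0) & (t <= 5)].max()),
            "asymptotic_max": float(sig[t >= 5].max()),
            "asymptotic_mean": float(sig[t >= 5].mean()),
        }
    return {"p_stresses": p_stresses, "stats": rows}


def _stability_bifurcations(out: Path, preset: str, seed: int) -> dict:
    """Eigenvalue stability branches for the parameters the figures sweep."""
    pts = 15 if preset == "desk" else 61
    results = {}
    p = ParameterSet()
    b = branch_scan("p_stress", np.geomspace(0.1, 10.0, pts), p)
    b.to_frame().to_csv(out / "branch_p_stress.csv", index=False)
    results["p_stress"] = {"unstable_intervals": b.unstable_intervals}
    for ps in (0.05, 0.20, 0.80):
        b = branch_scan("kK2", np.geomspace(3.6, 360.0, pts), p.replace(p_stress=ps))
        b.to_frame().to_csv(out / f"branch_kK2_pstress_{ps}.csv", index=False)
        results[f"kK2@p_stress={ps}"] = {"unstable_intervals": b.unstable_intervals}
    base = ParameterSet(**_TRANSITION_BASE).with_substitution(50.0, _TRANSITION_P_FRAC)
    b = branch_scan("p_prod", np.geomspace(5.0, 2000.0, max(pts, 30)), base)
    b.to_frame().to_csv(out / "branch_p_prod.csv", index=False)
    results["p_prod"] = {"unstable_intervals": b.unstable_intervals}
    return results


def _stress_contrast(out: Path, preset: str, seed: int) -> dict:
    """Both behaviours from one parameter set by a small change in stress level."""
    n = 50 if preset == "desk" else 100
    results = {}
    for ps in (0.24, 0.28):
        net = build_core_network(ParameterSet(kK2=7.0, eta=0.025, p_stress=ps))
        ens = simulate_ensemble(net, n=n, base_seed=seed)
        scores = behaviour_magnitudes(ens)
        results[ps] = {"M_srp": scores.M_srp, "M_sp": scores.M_sp}
        for k in range(4):
            simulate_cle(net, seed=seed + k).to_csv(out / f"contrast_{ps}_sample_{k}.csv")
    return {"n": n, "scores": results}


def _upstream_distinctness(out: Path, preset: str, seed: int) -> dict:
    """Distinctness of each behaviour along p_prod for the modified model."""
    n = 10 if preset == "desk" else 50
    grid = np.geomspace(20.0, 200.0, 6 if preset == "desk" else 20)
    base = ParameterSet(**_TRANSITION_BASE, eta_amp=0.05, eta_freq=1.0
                        ).with_substitution(50.0, _TRANSITION_P_FRAC)
    res = distinctness_profile("p_prod", grid, base, n=n, base_seed=seed,
                               model="modified")
    res["scan"].to_frame().to_csv(out / "upstream_profile.csv", index=False)
    return {"n": n, "dual": {k: v for k, v in res["dual"].items() if k != "eigenvalues"},
            "single": res["single"]}


SUPPORTED = {
    "noise-step-response": _noise_step_response,
    "behaviour-maps": _behaviour_maps,
    "pulsing-samples": _pulsing_samples,
    "transition": _transition,
    "transition-ssa": _transition_ssa,
    "stability-bifurcations": _stability_bifurcations,
    "stress-contrast": _stress_contrast,
    "upstream-distinctness": _upstream_distinctness,
}


def reproduce(name: str, out_dir: str | Path, preset: str = "desk",
              seed: int = 0) -> dict:
    """Run one named experiment and write its output bundle + manifest."""
    if name not in SUPPORTED:
        raise ValueError(
            f"unsupported experiment {name!r}; available: {sorted(SUPPORTED)}"
        )
    if preset not in ("desk", "paper"):
        raise ValueError("preset must be 'desk' or 'paper'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = SUPPORTED[name](out, preset, int(seed))
    manifest = {
        "experiment": name,
        "preset": preset,
        "seed": int(seed),
        "config_hash": RunConfig(seed=int(seed)).config_hash(),
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                                  default=float))
    return manifest
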