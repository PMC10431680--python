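"""Chemical reaction network of the B. subtilis sigma-B stress-response circuit.

The core circuit couples the alternative sigma factor sigma-B to its
anti-sigma factor RsbW (``W``) and anti-anti-sigma factor RsbV (``V``)
through a partner-switching mechanism.  RsbW dimers sequester sigma-B;
dephosphorylated RsbV displaces sigma-B from the W2-sigmaB complex, and
RsbW's kinase activity re-phosphorylates RsbV.  An upstream,
stress-activated phosphatase ``P`` dephosphorylates RsbV-P and thereby
encodes the stress level.  Free sigma-B drives production of itself, W and
V from a shared operon, closing a mixed positive/negative feedback loop.

Two fixed networks are provided:

* the *core* model — 10 species, 27 mass-action/operon reactions;
* the *modified* model — the core model plus an inactive phosphatase
  species ``PI`` and three activation/deactivation reactions that carry a
  separate "upstream" noise group, used to study how noise in the input
  pathway biases the circuit's output.

Concentrations are in micromolar and time in hours throughout; the
Gillespie engine reuses the same rate numbers on integer molecule counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CORE_SPECIES",
    "MODIFIED_SPECIES",
    "PARAMETER_NAMES",
    "ParameterSet",
    "StressProtocol",
    "Reaction",
    "ReactionNetwork",
    "build_core_network",
    "build_modified_network",
    "evaluate_propensities",
    "apply_stress",
    "operon_rate",
]

# Species order is fixed; all engines and the stoichiometry matrix use it.
CORE_SPECIES: tuple[str, ...] = (
    "sigB", "W", "W2", "W2sigB", "W2V", "W2V2", "V", "VP", "P", "PVP",
)
MODIFIED_SPECIES: tuple[str, ...] = CORE_SPECIES + ("PI",)

# The 24 parameters of the core model, in table order.
PARAMETER_NAMES: tuple[str, ...] = (
    "v0", "F", "K", "lambda_W", "lambda_V",
    "kBw", "kDw",
    "kB1", "kB2", "kB3", "kB4", "kB5",
    "kD1", "kD2", "kD3", "kD4", "kD5",
    "kK1", "kK2", "kP", "kdeg",
    "p_init", "p_stress", "eta",
)
MODIFIED_PARAMETER_NAMES: tuple[str, ...] = PARAMETER_NAMES + ("eta_amp", "eta_freq")

# Propensity kinds used by the numeric kernels.
PROD, UNI, BI, DIM = 0, 1, 2, 3


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and noise/stress parameters of the circuit.

    Units: ``v0`` uM/hr; ``K``, ``p_init``, ``p_stress`` uM; bimolecular
    rates (``kBw``, ``kB1``–``kB5``, ``kD4``) 1/(uM hr); unimolecular rates
    1/hr; ``F``, ``lambda_W``, ``lambda_V``, ``eta``, ``eta_amp``
    dimensionless; ``eta_freq`` 1/hr.

    ``eta`` scales the intrinsic (chemical-Langevin) noise of every core
    reaction; ``eta_amp`` scales only the three upstream
    phosphatase-switching reactions of the modified model, whose rate is
    ``eta_freq``.

    The upstream input can equivalently be parameterised by the substituted
    pair ``p_prod = p_stress * kP`` (total RsbV dephosphorylation
    efficiency) and ``p_frac = p_stress / kP``; :meth:`with_substitution`
    converts back.
    """

    v0: float = 0.4
    F: float = 30.0
    K: float = 0.2
    lambda_W: float = 4.0
    lambda_V: float = 4.5
    kBw: float = 3600.0
    kDw: float = 18.0
    kB1: float = 3600.0
    kB2: float = 3600.0
    kB3: float = 3600.0
    kB4: float = 1800.0
    kB5: float = 3600.0
    kD1: float = 18.0
    kD2: float = 18.0
    kD3: float = 18.0
    kD4: float = 1800.0
    kD5: float = 18.0
    kK1: float = 36.0
    kK2: float = 36.0
    kP: float = 180.0
    kdeg: float = 0.7
    p_init: float = 0.001
    p_stress: float = 0.4
    eta: float = 0.025
    eta_amp: float | None = None
    eta_freq: float | None = None
    # Operon production parse: "affine" -> v0*(1 + F*s/(K+s));
    # "shared" -> v0*(1 + F*s)/(K+s).  See `operon_rate`.
    production_form: str = "affine"

    def __post_init__(self) -> None:
        positive = (
            "v0", "K", "lambda_W", "lambda_V", "kBw", "kDw",
            "kB1", "kB2", "kB3", "kB4", "kB5",
            "kD1", "kD2", "kD3", "kD4", "kD5",
            "kK1", "kK2", "kP", "kdeg",
        )
        for name in positive:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        for name in ("F", "p_init", "p_stress", "eta"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"parameter {name!r} must be non-negative, got {value!r}")
        for name in ("eta_amp", "eta_freq"):
            value = getattr(self, name)
            if value is not None and not (math.isfinite(value) and value >= 0):
                raise ValueError(f"parameter {name!r} must be non-negative, got {value!r}")
        if self.production_form not in ("affine", "shared"):
            raise ValueError(
                f"production_form must be 'affine' or 'shared', got {self.production_form!r}"
            )

    # -- substituted upstream parameters ---------------------------------

    @property
    def p_prod(self) -> float:
        """Total RsbV dephosphorylation efficiency, p_stress * kP (uM/hr scale)."""
        return self.p_stress * self.kP

    @property
    def p_frac(self) -> float:
        """Substituted ratio p_stress / kP (uM hr scale)."""
        return self.p_stress / self.kP

    def with_substitution(self, p_prod: float, p_frac: float) -> "ParameterSet":
        """Return a copy with (p_stress, kP) set from the substituted pair.

        Inverts p_prod = p_stress*kP, p_frac = p_stress/kP:
        p_stress = sqrt(p_prod*p_frac), kP = sqrt(p_prod/p_frac).
        """
        if p_prod <= 0 or p_frac <= 0:
            raise ValueError("p_prod and p_frac must be strictly positive")
        return replace(
            self,
            p_stress=math.sqrt(p_prod * p_frac),
            kP=math.sqrt(p_prod / p_frac),
        )

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        out = {name: getattr(self, name) for name in PARAMETER_NAMES}
        if self.eta_amp is not None:
            out["eta_amp"] = self.eta_amp
        if self.eta_freq is not None:
            out["eta_freq"] = self.eta_freq
        if self.production_form != "affine":
            out["production_form"] = self.production_form
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        """Build a parameter set from plain key/value data.

        Accepts either (p_stress, kP) or the substituted pair
        (p_prod, p_frac); specifying both pairs inconsistently (beyond
        1e-9 relative) is rejected as over-determined.  Unknown keys are
        rejected by name.
        """
        data = dict(data)
        p_prod = data.pop("p_prod", None)
        p_frac = data.pop("p_frac", None)
        known = set(MODIFIED_PARAMETER_NAMES) | {"production_form"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        params = cls(**data)
        if (p_prod is None) != (p_frac is None):
            raise ValueError("p_prod and p_frac must be given together")
        if p_prod is not None:
            substituted = params.with_substitution(p_prod, p_frac)
            explicit = ("p_stress" in data) or ("kP" in data)
            if explicit and not (
                math.isclose(substituted.p_stress, params.p_stress, rel_tol=1e-9)
                and math.isclose(substituted.kP, params.kP, rel_tol=1e-9)
            ):
                raise ValueError(
                    "inconsistent over-determination: (p_stress, kP) and "
                    "(p_prod, p_frac) were both given and disagree"
                )
            params = substituted
        return params


@dataclass(frozen=True)
class StressProtocol:
    """Timing and semantics of the stress step.

    The simulation runs from ``t_burnin_start`` (default -10 h) to
    ``t_end`` (default 200 h); at ``t_stress`` (default 0 h) the free
    phosphatase is raised from its pre-stress level ``p_init`` to
    ``p_stress``.  In the modified model both the active (P) and inactive
    (PI) pools are raised, so total phosphatase becomes 2*p_stress.
    """

    t_burnin_start: float = -10.0
    t_stress: float = 0.0
    t_end: float = 200.0

    def __post_init__(self) -> None:
        if not (self.t_burnin_start < self.t_stress < self.t_end):
            raise ValueError(
                "require t_burnin_start < t_stress < t_end, got "
                f"({self.t_burnin_start}, {self.t_stress}, {self.t_end})"
            )


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry plus a propensity description.

    ``kind`` is one of the module constants PROD (operon production,
    propensity ``prefactor * f([sigB])``), UNI (``rate * x[i1]``),
    BI (``rate * x[i1] * x[i2]``) or DIM (``rate * x[i1]**2 / 2``).
    """

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    kind: int
    rate_name: str          # parameter supplying the rate constant / prefactor
    noise_group: str = "core"   # "core" (scaled by eta) or "upstream" (eta_amp)

    def net_change(self, species: Sequence[str]) -> np.ndarray:
        v = np.zeros(len(species))
        for name, n in self.products.items():
            v[species.index(name)] += n
        for name, n in self.reactants.items():
            v[species.index(name)] -= n
        return v


class ReactionNetwork:
    """A fixed reaction network with compiled numeric tables.

    Attributes
    ----------
    species : tuple of str
    reactions : tuple of Reaction
    stoichiometry : (n_species, n_reactions) int array of net changes
    """

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction],
                 params: ParameterSet, variant: str):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.params = params
        self.variant = variant
        n_s, n_r = len(self.species), len(self.reactions)
        S = np.zeros((n_s, n_r), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            S[:, j] = rxn.net_change(self.species)
        self.stoichiometry = S
        self._compile_tables()

    # Numeric tables consumed by the numba kernels.
    def _compile_tables(self) -> None:
        p = self.params
        n_r = len(self.reactions)
        self.kinds = np.empty(n_r, dtype=np.int64)
        self.rates = np.empty(n_r, dtype=np.float64)
        self.idx1 = np.zeros(n_r, dtype=np.int64)
        self.idx2 = np.zeros(n_r, dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            self.kinds[j] = rxn.kind
            self.rates[j] = getattr(p, rxn.rate_name) if rxn.kind != PROD else {
                "sigB": 1.0, "W": p.lambda_W, "V": p.lambda_V
            }[next(iter(rxn.products))]
            reactant_names = [n for n, c in rxn.reactants.items() for _ in range(c)]
            if rxn.kind == UNI:
                self.idx1[j] = self.species.index(reactant_names[0])
            elif rxn.kind == BI:
                self.idx1[j] = self.species.index(reactant_names[0])
                self.idx2[j] = self.species.index(reactant_names[1])
            elif rxn.kind == DIM:
                self.idx1[j] = self.species.index(reactant_names[0])
        self.noise_groups = np.array(
            [0 if r.noise_group == "core" else 1 for r in self.reactions],
            dtype=np.int64,
        )
        self.prod_params = np.array([p.v0, p.F, p.K], dtype=np.float64)
        self.production_flag = 0 if p.production_form == "affine" else 1
        self.stoich_f = self.stoichiometry.astype(np.float64)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def noise_scales(self, eta: float | None = None,
                     eta_amp: float | None = None) -> np.ndarray:
        """Per-reaction Langevin noise scale: eta for the core group,
        eta_amp for the upstream group."""
        p = self.params
        eta = p.eta if eta is None else eta
        if eta_amp is None:
            eta_amp = p.eta_amp if p.eta_amp is not None else 0.0
        return np.where(self.noise_groups == 0, eta, eta_amp).astype(np.float64)

    def initial_state(self) -> np.ndarray:
        """Pre-burn-in state: every species zero except phosphatase at p_init
        (modified model: both P and PI at p_init)."""
        x0 = np.zeros(self.n_species)
        x0[self.species.index("P")] = self.params.p_init
        if "PI" in self.species:
            x0[self.species.index("PI")] = self.params.p_init
        return x0

    def with_params(self, params: ParameterSet) -> "ReactionNetwork":
        if self.variant == "core":
            return build_core_network(params)
        return build_modified_network(params)


def operon_rate(s: float | np.ndarray, v0: float, F: float, K: float,
                form: str = "affine"):
    """Sigma-B operon production rate f([sigB]).

    The default "affine" form is ``v0 * (1 + F*s/(K+s))``: base activity
    exactly v0 at s = 0 and fold change 1+F at saturation.  The
    alternative "shared" parse ``v0 * (1 + F*s)/(K + s)`` is kept
    selectable because the two readings differ only in how the
    Michaelis-type denominator is grouped.
    """
    if form == "affine":
        return v0 * (1.0 + F * s / (K + s))
    return v0 * (1.0 + F * s) / (K + s)


def _core_reactions() -> list[Reaction]:
    r = Reaction
    out = [
        r("production_sigB", {}, {"sigB": 1}, PROD, "v0"),
        r("production_W", {}, {"W": 1}, PROD, "v0"),
        r("production_V", {}, {"V": 1}, PROD, "v0"),
        r("dimerisation", {"W": 2}, {"W2": 1}, DIM, "kBw"),
        r("binding_W2_V", {"W2": 1, "V": 1}, {"W2V": 1}, BI, "kB1"),
        r("binding_W2V_V", {"W2V": 1, "V": 1}, {"W2V2": 1}, BI, "kB2"),
        r("binding_W2_sigB", {"W2": 1, "sigB": 1}, {"W2sigB": 1}, BI, "kB3"),
        r("binding_P_VP", {"P": 1, "VP": 1}, {"PVP": 1}, BI, "kB5"),
        r("switch_release_sigB", {"W2sigB": 1, "V": 1}, {"W2V": 1, "sigB": 1}, BI, "kB4"),
        r("switch_capture_sigB", {"W2V": 1, "sigB": 1}, {"W2sigB": 1, "V": 1}, BI, "kD4"),
        r("dissociation_W2", {"W2": 1}, {"W": 2}, UNI, "kDw"),
        r("dissociation_W2V", {"W2V": 1}, {"W2": 1, "V": 1}, UNI, "kD1"),
        r("dissociation_W2V2", {"W2V2": 1}, {"W2V": 1, "V": 1}, UNI, "kD2"),
        r("dissociation_W2sigB", {"W2sigB": 1}, {"W2": 1, "sigB": 1}, UNI, "kD3"),
        r("dissociation_PVP", {"PVP": 1}, {"P": 1, "VP": 1}, UNI, "kD5"),
        r("phosphorylation_W2V", {"W2V": 1}, {"W2": 1, "VP": 1}, UNI, "kK1"),
        r("phosphorylation_W2V2", {"W2V2": 1}, {"W2V": 1, "VP": 1}, UNI, "kK2"),
        r("dephosphorylation", {"PVP": 1}, {"P": 1, "V": 1}, UNI, "kP"),
    ]
    for sp in ("sigB", "W", "W2", "W2sigB", "W2V", "W2V2", "V", "VP"):
        out.append(r(f"degradation_{sp}", {sp: 1}, {}, UNI, "kdeg"))
    # Degradation of the bound complex releases the phosphatase.
    out.append(r("degradation_PVP", {"PVP": 1}, {"P": 1}, UNI, "kdeg"))
    return out


def build_core_network(params: ParameterSet) -> ReactionNetwork:
    """Build the 10-species, 27-reaction core circuit."""
    return ReactionNetwork(CORE_SPECIES, _core_reactions(), params, "core")


def build_modified_network(params: ParameterSet) -> ReactionNetwork:
    """Build the 11-species, 30-reaction model with upstream phosphatase noise.

    Requires ``eta_amp`` and ``eta_freq``.  The three added reactions
    (phosphatase activation PI->P, deactivation P->PI, and deactivation of
    the bound complex PVP->PI+VP) all proceed at rate ``eta_freq`` and
    carry the "upstream" noise group, whose Langevin noise is scaled by
    ``eta_amp`` instead of ``eta``.
    """
    if params.eta_amp is None or params.eta_freq is None:
        raise ValueError("modified model requires eta_amp and eta_freq")
    r = Reaction
    extra = [
        r("phosphatase_activation", {"PI": 1}, {"P": 1}, UNI, "eta_freq", "upstream"),
        r("phosphatase_deactivation", {"P": 1}, {"PI": 1}, UNI, "eta_freq", "upstream"),
        r("phosphatase_deactivation_bound", {"PVP": 1}, {"PI": 1, "VP": 1}, UNI,
          "eta_freq", "upstream"),
    ]
    return ReactionNetwork(MODIFIED_SPECIES, _core_reactions() + extra, params, "modified")


def evaluate_propensities(network: ReactionNetwork, state: np.ndarray,
                          strict: bool = False) -> np.ndarray:
    """Per-reaction propensity vector at ``state``.

    Mass action in the reactant amounts with a 1/2 combinatorial factor
    for the RsbW dimerisation; production reactions use the operon rate
    ``f([sigB])``.  With ``strict=True`` negative amounts are rejected;
    otherwise (the chemical-Langevin convention) they are passed through
    and the caller absolute-values noise arguments.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError(
            f"state must have shape ({network.n_species},), got {state.shape}"
        )
    if strict and np.any(state < 0):
        bad = [network.species[i] for i in np.where(state < 0)[0]]
        raise ValueError(f"negative amounts for species {bad} in strict mode")
    p = network.params
    f = operon_rate(state[0], p.v0, p.F, p.K, p.production_form)
    a = np.empty(network.n_reactions)
    for j in range(network.n_reactions):
        kind = network.kinds[j]
        if kind == PROD:
            a[j] = network.rates[j] * f
        elif kind == UNI:
            a[j] = network.rates[j] * state[network.idx1[j]]
        elif kind == BI:
            a[j] = network.rates[j] * state[network.idx1[j]] * state[network.idx2[j]]
        else:  # DIM
            a[j] = network.rates[j] * state[network.idx1[j]] ** 2 / 2.0
    return a


def apply_stress(state: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Apply the stress step: raise free phosphatase by p_stress - p_init.

    Core model: only [P]; modified model: both [P] and [PI], so the total
    amount of phosphatase becomes 2*p_stress (plus any pre-existing bound
    fraction imbalance).  A negative increment (stress removal) is allowed.
    """
    state = np.array(state, dtype=float, copy=True)
    delta = network.params.p_stress - network.params.p_init
    state[network.species.index("P")] += delta
    if "PI" in network.species:
        state[network.species.index("PI")] += delta
    return state
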