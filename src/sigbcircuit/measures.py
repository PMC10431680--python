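"""Automated quantification of the circuit's two response behaviours.

A stress-response trajectory is split at five hours post-stress into a
*transient* phase (t in [0, 5] h, containing the synchronised response
pulse if any) and an *asymptotic* phase (t in [5, 200] h).  From the
maximum transient activity, maximum asymptotic activity and mean
asymptotic activity two dimensionless magnitudes are formed:

* single response pulse  M_srp = transient max / asymptotic max;
* stochastic pulsing     M_sp  = asymptotic max / asymptotic mean.

Dividing the transient pulse by the asymptotic *maximum* penalises M_srp
for late pulses, so the two measures cannot both be large on the same
trajectory.  In practice both are reported as means over an ensemble
(n > 50 recommended).

On top of per-parameter profiles M(p) the module builds the excess
magnitudes M* (the positive part of each measure's lead over the other),
the dual and single distinctness measures D (integral statistics asking
whether sweeping p elicits one behaviour without the other), and the
squared-successive-difference sensitivity C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulation import Ensemble, Trajectory

__all__ = [
    "PhaseStatistics",
    "BehaviourScores",
    "MeasureProfile",
    "ClassifierThresholds",
    "phase_statistics",
    "behaviour_magnitudes",
    "excess_magnitudes",
    "dual_distinctness",
    "single_distinctness",
    "magnitude_sensitivity",
    "classify_response",
]

TRANSIENT_WINDOW = (0.0, 5.0)
ASYMPTOTIC_END = 200.0
#: below this, a phase denominator is treated as "no activity" and the
#: corresponding magnitude defined as 1 (no behaviour).
DENOMINATOR_GUARD = 1e-12


@dataclass(frozen=True)
class PhaseStatistics:
    """Window statistics of one activity trace (pre-stress samples excluded)."""

    transient_max: float
    asymptotic_max: float
    asymptotic_mean: float
    activity_source: str = "free"


@dataclass(frozen=True)
class BehaviourScores:
    """Per-member and ensemble-mean behaviour magnitudes."""

    M_srp: float                    # ensemble mean
    M_sp: float                     # ensemble mean
    per_member_M_srp: np.ndarray
    per_member_M_sp: np.ndarray
    n: int


@dataclass
class MeasureProfile:
    """Behaviour magnitudes along a swept parameter grid."""

    parameter: str
    grid: np.ndarray
    M_srp: np.ndarray
    M_sp: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.M_srp = np.asarray(self.M_srp, dtype=float)
        self.M_sp = np.asarray(self.M_sp, dtype=float)
        if not (self.grid.shape == self.M_srp.shape == self.M_sp.shape):
            raise ValueError("grid, M_srp, M_sp must have equal shapes")
        if self.grid.size >= 2 and np.any(np.diff(self.grid) <= 0):
            raise ValueError("parameter grid must be strictly increasing")

    @property
    def excess(self) -> tuple[np.ndarray, np.ndarray]:
        return excess_magnitudes(self.M_srp, self.M_sp)


def phase_statistics(trajectory: Trajectory,
                     activity_source: str = "free") -> PhaseStatistics:
    """Transient/asymptotic window statistics of a single trajectory.

    The trajectory should cover [0, 200] h post-stress; if it ends early
    the asymptotic statistics are computed on the available window.
    """
    t = trajectory.times
    x = trajectory.activity(activity_source)
    t_lo, t_hi = TRANSIENT_WINDOW
    tr_mask = (t >= t_lo) & (t <= t_hi)
    as_mask = (t >= t_hi) & (t <= ASYMPTOTIC_END)
    if not tr_mask.any() or not as_mask.any():
        raise ValueError("trajectory does not cover the post-stress windows")
    return PhaseStatistics(
        transient_max=float(x[tr_mask].max()),
        asymptotic_max=float(x[as_mask].max()),
        asymptotic_mean=float(x[as_mask].mean()),
        activity_source=activity_source,
    )


def _member_magnitudes(stats: PhaseStatistics) -> tuple[float, float]:
    if stats.asymptotic_max < DENOMINATOR_GUARD:
        m_srp = 1.0
    else:
        m_srp = stats.transient_max / stats.asymptotic_max
    if stats.asymptotic_mean < DENOMINATOR_GUARD:
        m_sp = 1.0
    else:
        m_sp = stats.asymptotic_max / stats.asymptotic_mean
    return m_srp, m_sp


def behaviour_magnitudes(ensemble: Ensemble,
                         activity_source: str = "free") -> BehaviourScores:
    """Mean-of-ratios behaviour magnitudes over an ensemble."""
    srp, sp = [], []
    for member in ensemble:
        m_srp, m_sp = _member_magnitudes(phase_statistics(member, activity_source))
        srp.append(m_srp)
        sp.append(m_sp)
    srp_arr = np.asarray(srp)
    sp_arr = np.asarray(sp)
    return BehaviourScores(
        M_srp=float(srp_arr.mean()),
        M_sp=float(sp_arr.mean()),
        per_member_M_srp=srp_arr,
        per_member_M_sp=sp_arr,
        n=len(ensemble),
    )


def excess_magnitudes(M_srp, M_sp):
    """Positive part of each magnitude's lead over the other.

    Returns (M*_srp, M*_sp); their product is zero everywhere, and the
    equality case maps to (0, 0).  Accepts scalars or arrays.
    """
    M_srp = np.asarray(M_srp, dtype=float)
    M_sp = np.asarray(M_sp, dtype=float)
    srp_star = np.where(M_srp > M_sp, M_srp - M_sp, 0.0)
    sp_star = np.where(M_sp > M_srp, M_sp - M_srp, 0.0)
    if srp_star.ndim == 0:
        return float(srp_star), float(sp_star)
    return srp_star, sp_star


def _integrate(y: np.ndarray, x: np.ndarray, rule: str) -> float:
    if rule == "trapezoid":
        return float(np.trapezoid(y, x))
    if rule == "sum":
        # plain grid sums, scaled by mean spacing so units match the integral
        return float(y.sum() * (x[-1] - x[0]) / max(len(x) - 1, 1))
    raise ValueError(f"integration rule must be 'trapezoid' or 'sum', got {rule!r}")


def dual_distinctness(profile: MeasureProfile, rule: str = "trapezoid") -> dict:
    """Ability to elicit *both* behaviours distinctly while sweeping one parameter.

    Two published formulations are evaluated and both returned:

    * ``D_ratio``:  2 * I(M*_srp) * I(M*_sp) / I(max(M*_srp, M*_sp)),
      the integral-ratio form;
    * ``D_area``:   A_srp * A_sp / (A_srp + A_srp_sp + A_sp), where A_srp
      is the area where the single-pulse magnitude exceeds the pulsing
      magnitude, A_sp the converse, and A_srp_sp the area under both
      curves.

    The two are not algebraically identical and neither is guaranteed to
    lie in (0, 1) for unbounded magnitudes; ``in_unit_interval`` reports
    whether the ratio form happens to.  ``D`` aliases ``D_ratio``.
    """
    if profile.grid.size < 2:
        raise ValueError("profile needs at least 2 grid points")
    srp_star, sp_star = profile.excess
    x = profile.grid
    I_srp = _integrate(srp_star, x, rule)
    I_sp = _integrate(sp_star, x, rule)
    I_max = _integrate(np.maximum(srp_star, sp_star), x, rule)
    degenerate = I_max <= 0
    D_ratio = 0.0 if degenerate else 2.0 * I_srp * I_sp / I_max
    # area formulation: A_srp/A_sp are the same excess areas; the shared
    # area is the integral of min(M_srp, M_sp) above zero baseline.
    A_shared = _integrate(np.minimum(profile.M_srp, profile.M_sp), x, rule)
    denom = I_srp + I_sp + A_shared
    D_area = 0.0 if denom <= 0 else I_srp * I_sp / denom
    return {
        "D": D_ratio,
        "D_ratio": D_ratio,
        "D_area": D_area,
        "A_srp": I_srp,
        "A_sp": I_sp,
        "A_srp_sp": A_shared,
        "degenerate": bool(degenerate),
        "in_unit_interval": bool(0.0 < D_ratio < 1.0),
    }


def single_distinctness(profile: MeasureProfile, rule: str = "trapezoid") -> dict:
    """Ability to elicit *one* behaviour distinctly: squared area over total.

    D_srp = I(M*_srp)^2 / I(max(M*_srp, M*_sp)), and symmetrically D_sp.
    Squaring the numerator rewards behaviours that are prominent outright,
    not merely prominent relative to the other one.
    """
    if profile.grid.size < 2:
        raise ValueError("profile needs at least 2 grid points")
    srp_star, sp_star = profile.excess
    x = profile.grid
    I_srp = _integrate(srp_star, x, rule)
    I_sp = _integrate(sp_star, x, rule)
    I_max = _integrate(np.maximum(srp_star, sp_star), x, rule)
    if I_max <= 0:
        return {"D_srp": 0.0, "D_sp": 0.0, "degenerate": True}
    return {
        "D_srp": I_srp ** 2 / I_max,
        "D_sp": I_sp ** 2 / I_max,
        "degenerate": False,
    }


def magnitude_sensitivity(values: np.ndarray, normalise_by: float | None = None) -> float:
    """Squared-successive-difference sensitivity of a magnitude profile.

    C = (n-1) * sum_i (M(p_{i+1}) - M(p_i))^2.  The (n-1) factor removes
    the grid-density bias (a linear rise of c over the grid scores c^2 for
    any n); constants score 0.  ``normalise_by`` optionally rescales, as
    used when comparing parameters on one axis.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D profile with at least 2 points")
    n = values.size
    c = float((n - 1) * np.sum(np.diff(values) ** 2))
    if normalise_by:
        c /= normalise_by
    return c


@dataclass(frozen=True)
class ClassifierThresholds:
    """Heuristic thresholds of :func:`classify_response` (not source-model
    facts; exposed so users can recalibrate).

    ``response_floor``: minimum transient-or-asymptotic activity (uM) for
    the ensemble to count as responding at all.  ``srp_dominance``: mean
    M_srp above this (and exceeding mean M_sp) labels single_pulse.
    ``osc_concentration``: a limit cycle concentrates the asymptotic
    variance in a narrow spectral line; if the fraction of band power
    (periods 0.2-20 h) within +-2 bins of the dominant peak exceeds this
    (and mean M_sp >= ``osc_msp_floor``), the label is oscillation.
    ``sp_floor``: otherwise, mean M_sp above this labels
    stochastic_pulsing (irregular pulses: high max/mean, incoherent
    spectrum); anything left is sustained_activity.
    """

    response_floor: float = 0.05
    srp_dominance: float = 2.0
    sp_floor: float = 8.0
    osc_msp_floor: float = 1.5
    osc_concentration: float = 0.25
    spectral_band: tuple[float, float] = (0.2, 20.0)   # periods in hours


def _spectral_concentration(member: Trajectory, activity_source: str,
                            band: tuple[float, float]) -> float:
    """Fraction of asymptotic band power within +-2 bins of the dominant peak.

    Near 1 for a clean limit cycle, small for irregular pulsing or
    red-noise fluctuations."""
    t = member.times
    x = member.activity(activity_source)
    mask = (t >= TRANSIENT_WINDOW[1]) & (t <= ASYMPTOTIC_END)
    y = x[mask] - x[mask].mean()
    if y.size < 64 or np.allclose(y, 0):
        return 0.0
    d = float(np.median(np.diff(t[mask])))
    freqs = np.fft.rfftfreq(y.size, d=d)
    power = np.abs(np.fft.rfft(y)) ** 2
    sel = (freqs >= 1.0 / band[1]) & (freqs <= 1.0 / band[0])
    pb = power[sel]
    if pb.size == 0 or pb.sum() <= 0:
        return 0.0
    k = int(pb.argmax())
    return float(pb[max(0, k - 2):k + 3].sum() / pb.sum())


def classify_response(ensemble: Ensemble,
                      activity_source: str = "free",
                      thresholds: ClassifierThresholds | None = None) -> dict:
    """Label the ensemble's qualitative response to the stress step.

    Returns a dict with ``label`` in {no_response, single_pulse,
    stochastic_pulsing, oscillation, sustained_activity}, the scores it
    was based on, and a ``confidence`` note for borderline calls.  The
    decision rules are documented heuristics operationalising the
    qualitative response categories; thresholds are configurable.
    """
    th = thresholds or ClassifierThresholds()
    scores = behaviour_magnitudes(ensemble, activity_source)
    stats = [phase_statistics(m, activity_source) for m in ensemble]
    mean_tr_max = float(np.mean([s.transient_max for s in stats]))
    mean_as_max = float(np.mean([s.asymptotic_max for s in stats]))
    mean_as_mean = float(np.mean([s.asymptotic_mean for s in stats]))
    concentration = float(np.median([
        _spectral_concentration(m, activity_source, th.spectral_band)
        for m in ensemble
    ]))

    confidence = "clear"
    if max(mean_tr_max, mean_as_max) < th.response_floor:
        label = "no_response"
    elif scores.M_srp > scores.M_sp and scores.M_srp > th.srp_dominance:
        label = "single_pulse"
        if scores.M_srp < 2 * th.srp_dominance:
            confidence = "borderline: moderate single-pulse dominance"
    elif concentration >= th.osc_concentration and scores.M_sp >= th.osc_msp_floor:
        label = "oscillation"
    elif scores.M_sp >= th.sp_floor:
        label = "stochastic_pulsing"
        if concentration >= 0.5 * th.osc_concentration:
            confidence = "borderline: partially coherent pulsing"
    else:
        label = "sustained_activity"
        if scores.M_sp >= th.osc_msp_floor:
            confidence = "borderline: elevated M_sp without a coherent spectral peak"
    return {
        "label": label,
        "confidence": confidence,
        "M_srp": scores.M_srp,
        "M_sp": scores.M_sp,
        "mean_transient_max": mean_tr_max,
        "mean_asymptotic_max": mean_as_max,
        "mean_asymptotic_mean": mean_as_mean,
        "spectral_concentration": concentration,
        "n": scores.n,
    }
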