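"""Idealised activity traces with analytically known window statistics.

These are used to unit-test the behaviour measures: each generator
returns a noise-free :class:`~sigbcircuit.simulation.Trajectory` on the
standard [-10, 200] h grid whose transient/asymptotic statistics can be
written down in closed form.  The trace is stored in the sigma-B column
of an otherwise-zero species table.
"""

from __future__ import annotations

import numpy as np

from .network import CORE_SPECIES, ParameterSet, StressProtocol
from .simulation import Trajectory

__all__ = ["generate_reference_trace"]


def _grid(sample_dt: float) -> np.ndarray:
    n = int(round(210.0 / sample_dt))
    return -10.0 + sample_dt * np.arange(n + 1)


def generate_reference_trace(kind: str, sample_dt: float = 0.01,
                             **kwargs) -> Trajectory:
    """Build a synthetic activity trace of the named ``kind``.

    Kinds and their parameters:

    * ``constant``: level ``c`` everywhere.
    * ``square_pulse``: baseline ``baseline``, height ``height`` on
      [t_on, t_off] (post-stress hours).
    * ``raised_cosine``: baseline 0, x(t) = (A/2)(1 - cos(2 pi t / T))
      for t >= 0.  With T dividing the asymptotic window the asymptotic
      mean is exactly A/2 and the maximum A, so the stochastic-pulsing
      measure is 2.
    * ``spike_train``: baseline ``baseline`` plus ``k`` single-sample
      spikes of height ``height`` evenly spread over the asymptotic
      phase.
    """
    t = _grid(sample_dt)
    x = np.zeros_like(t)
    if kind == "constant":
        c = float(kwargs.get("c", 1.0))
        x[:] = c
    elif kind == "square_pulse":
        baseline = float(kwargs.get("baseline", 1.0))
        height = float(kwargs.get("height", 10.0))
        t_on = float(kwargs.get("t_on", 1.0))
        t_off = float(kwargs.get("t_off", 2.0))
        x[:] = baseline
        x[(t >= t_on) & (t <= t_off)] = height
    elif kind == "raised_cosine":
        A = float(kwargs.get("A", 2.0))
        T = float(kwargs.get("T", 5.0))
        post = t >= 0
        x[post] = 0.5 * A * (1.0 - np.cos(2.0 * np.pi * t[post] / T))
    elif kind == "spike_train":
        baseline = float(kwargs.get("baseline", 0.5))
        height = float(kwargs.get("height", 10.0))
        k = int(kwargs.get("k", 10))
        x[:] = baseline
        spike_times = np.linspace(10.0, 190.0, k)
        for ts in spike_times:
            x[np.argmin(np.abs(t - ts))] = height
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected one of "
            "constant, square_pulse, raised_cosine, spike_train"
        )
    values = np.zeros((t.size, len(CORE_SPECIES)))
    values[:, 0] = x
    return Trajectory(
        times=t, values=values, species=CORE_SPECIES,
        engine=f"fixture:{kind}", seed=None,
        params=ParameterSet(), protocol=StressProtocol(),
    )
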