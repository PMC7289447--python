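"""Conversion of well-tempered metadynamics bias to free energy.

In the long-time limit of well-tempered metadynamics with bias factor
gamma, the accumulated bias converges to -(1 - 1/gamma) F(s), so

    F(s) = -(gamma / (gamma - 1)) V_bias(s),

re-zeroed at its minimum.  Block averaging of surfaces computed from bias
snapshots (see :func:`~cochap.freenergy.surface.average_fes_blocks`)
damps the residual bias fluctuations.
"""

from __future__ import annotations

import numpy as np

from .surface import BiasGrid, FreeEnergySurface

__all__ = ["metad_bias_to_fes", "project_fes"]


def metad_bias_to_fes(bias: BiasGrid) -> FreeEnergySurface:
    gamma = bias.bias_factor
    if not gamma > 1:
        raise ValueError("bias_factor must be > 1")
    values = -(gamma / (gamma - 1.0)) * bias.values
    return FreeEnergySurface(
        axes=bias.axes, values=values, temperature=bias.temperature
    )


def project_fes(fes: FreeEnergySurface, axis: int = 0) -> FreeEnergySurface:
    """Boltzmann projection of a 2D surface onto one coordinate."""
    if fes.ndim != 2:
        raise ValueError("need a 2D surface")
    finite = np.isfinite(fes.values)
    w = np.where(finite, np.exp(-np.where(finite, fes.values, 0.0) / fes.kT), 0.0)
    marginal = w.sum(axis=1 - axis)
    with np.errstate(divide="ignore"):
        values = np.where(marginal > 0, -fes.kT * np.log(np.maximum(marginal, 1e-300)), np.inf)
    return FreeEnergySurface(
        axes=(fes.axes[axis],), values=values, temperature=fes.temperature
    )
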