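"""Analytic potentials with known free energies.

These drive the Langevin samplers and provide exact references: for a 1D
potential U(x) the potential of mean force is U itself (up to an additive
constant), and for the separable 2D double well the barrier along x is
the hill height A by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Flat1D", "Harmonic1D", "DoubleWell2D", "Harmonic2D"]


@dataclass(frozen=True)
class Flat1D:
    """U(x) = 0."""

    def value(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def grad(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class Harmonic1D:
    """U(x) = 0.5 * kappa * (x - x0)^2, kJ/mol with x in nm."""

    kappa: float
    x0: float = 0.0

    def value(self, x):
        return 0.5 * self.kappa * (np.asarray(x, dtype=float) - self.x0) ** 2

    def grad(self, x):
        return self.kappa * (np.asarray(x, dtype=float) - self.x0)


@dataclass(frozen=True)
class DoubleWell2D:
    """U(x, y) = A ((x/x0)^2 - 1)^2 + 0.5 ky y^2.

    Two minima at (+-x0, 0) separated by a barrier of height exactly
    ``barrier_height`` = A along the x coordinate; the y direction is a
    harmonic channel, so the potential is separable and the projected
    free-energy barrier equals A at any temperature.
    """

    barrier_height: float = 7.5  # kJ/mol
    x0: float = 0.15  # nm
    ky: float = 500.0  # kJ/mol/nm^2

    def value(self, xy):
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        return (
            self.barrier_height * ((x / self.x0) ** 2 - 1.0) ** 2
            + 0.5 * self.ky * y**2
        )

    def grad(self, xy):
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        gx = self.barrier_height * 4.0 * x * ((x / self.x0) ** 2 - 1.0) / self.x0**2
        gy = self.ky * y
        return np.stack([gx, gy], axis=-1)


@dataclass(frozen=True)
class Harmonic2D:
    """U(x, y) = 0.5 kx x^2 + 0.5 ky y^2."""

    kx: float = 100.0
    ky: float = 100.0

    def value(self, xy):
        xy = np.asarray(xy, dtype=float)
        return 0.5 * self.kx * xy[..., 0] ** 2 + 0.5 * self.ky * xy[..., 1] ** 2

    def grad(self, xy):
        xy = np.asarray(xy, dtype=float)
        return np.stack([self.kx * xy[..., 0], self.ky * xy[..., 1]], axis=-1)
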