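"""Free-energy surfaces on regular grids and derived quantities.

A :class:`FreeEnergySurface` stores free energies (kJ/mol) on a uniform
1D or 2D grid of bin centres (nm) together with the temperature; unvisited
bins are ``+inf`` and the finite minimum is zero.  Conversions: Boltzmann
inversion to a probability distribution, quadrant population integration
for the four ion-pair interaction states (bound/bound, bound/unbound,
unbound/bound, unbound/unbound), and gauge-aligned block averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..constants import DEFAULT_TEMPERATURE, KB

__all__ = [
    "FreeEnergySurface",
    "BiasGrid",
    "fes_to_probability",
    "classify_state",
    "integrate_state_populations",
    "average_fes_blocks",
    "STATE_LABELS",
]

STATE_LABELS = ("both-bound", "only-1", "only-2", "both-unbound")


def _check_uniform(axis: np.ndarray, name: str) -> None:
    if len(axis) < 2:
        return
    steps = np.diff(axis)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
        raise ValueError(f"{name} grid must be uniformly spaced")


@dataclass
class FreeEnergySurface:
    axes: tuple  # 1 or 2 arrays of bin centres (nm)
    values: np.ndarray  # kJ/mol, +inf for unvisited bins
    temperature: float = DEFAULT_TEMPERATURE
    sd: Optional[np.ndarray] = None  # per-bin standard deviation / error

    def __post_init__(self):
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.axes) not in (1, 2):
            raise ValueError("only 1D and 2D surfaces supported")
        expected = tuple(len(a) for a in self.axes)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid {expected}")
        for i, a in enumerate(self.axes):
            _check_uniform(a, f"axis {i}")
        self.rezero()

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def bin_volume(self) -> float:
        vol = 1.0
        for a in self.axes:
            vol *= a[1] - a[0] if len(a) > 1 else 1.0
        return vol

    def rezero(self) -> None:
        finite = np.isfinite(self.values)
        if finite.any():
            self.values = self.values - self.values[finite].min()

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.ndim == 1:
            ax.plot(self.axes[0], self.values)
            ax.set_xlabel("coordinate (nm)")
            ax.set_ylabel("free energy (kJ/mol)")
        else:
            masked = np.ma.masked_invalid(self.values)
            im = ax.pcolormesh(self.axes[0], self.axes[1], masked.T, shading="nearest")
            ax.figure.colorbar(im, ax=ax, label="free energy (kJ/mol)")
            ax.set_xlabel("d1 (nm)")
            ax.set_ylabel("d2 (nm)")
        return ax


@dataclass
class BiasGrid:
    """Accumulated metadynamics bias on a regular grid (kJ/mol, >= 0)."""

    axes: tuple
    values: np.ndarray
    bias_factor: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        if not self.bias_factor > 1:
            raise ValueError("bias_factor must be > 1")
        if np.any(self.values < -1e-9):
            raise ValueError("bias values must be non-negative")


def fes_to_probability(fes: FreeEnergySurface) -> np.ndarray:
    """Normalized Boltzmann probability per bin, p ~ exp(-F/kT) * volume."""
    finite = np.isfinite(fes.values)
    if not finite.any():
        raise ValueError("all bins are +inf")
    p = np.zeros_like(fes.values)
    p[finite] = np.exp(-fes.values[finite] / fes.kT)
    p /= p.sum()  # uniform grid: bin volume cancels
    return p


def mean_coordinate(fes: FreeEnergySurface, axis: int = 0) -> float:
    """Probability-weighted mean of one coordinate."""
    p = fes_to_probability(fes)
    if fes.ndim == 1:
        return float(np.sum(p * fes.axes[0]))
    marginal = p.sum(axis=1 - axis)
    return float(np.sum(marginal * fes.axes[axis]))


def classify_state(d1: float, d2: float, cutoff: float = 0.5) -> str:
    """Four-way ion-pair interaction state; bound means d < cutoff (strict)."""
    if not (d1 > 0 and d2 > 0):
        raise ValueError("distances must be positive")
    b1, b2 = d1 < cutoff, d2 < cutoff
    if b1 and b2:
        return "both-bound"
    if b1:
        return "only-1"
    if b2:
        return "only-2"
    return "both-unbound"


def integrate_state_populations(
    fes2d: FreeEnergySurface, cutoff: float = 0.5
) -> dict[str, float]:
    """Boltzmann populations of the four quadrants of a 2D surface.

    Bins are assigned to quadrants by their centres (strict < at the
    cutoff), matching :func:`classify_state`.
    """
    if fes2d.ndim != 2:
        raise ValueError("need a 2D surface")
    for a in fes2d.axes:
        if not (a.min() <= cutoff <= a.max()):
            raise ValueError("cutoff lies outside the grid")
    p = fes_to_probability(fes2d)
    b1 = fes2d.axes[0] < cutoff
    b2 = fes2d.axes[1] < cutoff
    pops = {
        "both-bound": float(p[np.ix_(b1, b2)].sum()),
        "only-1": float(p[np.ix_(b1, ~b2)].sum()),
        "only-2": float(p[np.ix_(~b1, b2)].sum()),
        "both-unbound": float(p[np.ix_(~b1, ~b2)].sum()),
    }
    total = sum(pops.values())
    return {k: v / total for k, v in pops.items()}


def average_fes_blocks(fes_list: Sequence[FreeEnergySurface]) -> FreeEnergySurface:
    """Mean surface over blocks after aligning each block to its own minimum.

    Per-bin SD is reported in ``sd``; bins finite in no block stay +inf.
    """
    fes_list = list(fes_list)
    if not fes_list:
        raise ValueError("need at least one surface")
    ref_axes = fes_list[0].axes
    for fes in fes_list[1:]:
        if len(fes.axes) != len(ref_axes) or any(
            len(a) != len(b) or not np.allclose(a, b)
            for a, b in zip(fes.axes, ref_axes)
        ):
            raise ValueError("mismatched grids")
    stack = np.stack([f.values for f in fes_list])  # already min-aligned
    finite = np.isfinite(stack)
    count = finite.sum(axis=0)
    safe = np.where(finite, stack, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, safe.sum(axis=0) / np.maximum(count, 1), np.inf)
        sq = np.where(finite, (stack - np.where(np.isfinite(mean), mean, 0.0)) ** 2, 0.0)
        sd = np.where(count > 0, np.sqrt(sq.sum(axis=0) / np.maximum(count, 1)), np.nan)
    return FreeEnergySurface(
        axes=ref_axes,
        values=mean,
        temperature=fes_list[0].temperature,
        sd=sd,
    )
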