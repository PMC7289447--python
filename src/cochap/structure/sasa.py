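"""Shrake-Rupley solvent-accessible surface area.

Each atom is surrounded by a deterministic golden-spiral point grid on a
sphere of radius (vdW radius + probe); a point is accessible if it lies
outside the probe-inflated sphere of every neighbouring atom.  The
per-atom area is the accessible fraction of the full sphere area.  The
quadrature resolution is 4*pi*(r+probe)^2 / n_points per atom, which sets
the tolerance for equality-style comparisons of areas.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from ..constants import (
    DEFAULT_VDW_RADIUS_NM,
    HYDROPHOBIC_RESIDUES,
    PROBE_RADIUS_NM,
    VDW_RADII_NM,
)
from .core import Structure
from .geometry import selection_mask

__all__ = [
    "sphere_points",
    "shrake_rupley_sasa",
    "buried_hydrophobic_area",
    "sasa_quadrature_tolerance",
]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * k
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radii(s: Structure, radii: Optional[dict] = None) -> np.ndarray:
    table = VDW_RADII_NM if radii is None else radii
    out = np.empty(s.n_atoms)
    for i, element in enumerate(s.elements):
        key = str(element).upper()
        if key not in table:
            warnings.warn(
                f"unknown element {key!r}: using default radius "
                f"{DEFAULT_VDW_RADIUS_NM} nm"
            )
        out[i] = table.get(key, DEFAULT_VDW_RADIUS_NM)
    return out


def shrake_rupley_sasa(
    s: Structure,
    probe: float = PROBE_RADIUS_NM,
    n_points: int = 960,
    radii: Optional[dict] = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas in nm^2."""
    if s.n_atoms == 0:
        return np.zeros(0)
    r = atom_radii(s, radii)
    inflated = r + probe
    grid = sphere_points(n_points)
    coords = s.coords
    areas = np.empty(s.n_atoms)
    # neighbour prefilter: atoms whose inflated spheres can intersect
    max_reach = inflated.max()
    for i in range(s.n_atoms):
        delta = coords - coords[i]
        d2 = np.einsum("ij,ij->i", delta, delta)
        cut = (inflated[i] + max_reach) ** 2
        neigh = np.where((d2 < cut) & (d2 > 0.0))[0]
        neigh = neigh[
            np.linalg.norm(coords[neigh] - coords[i], axis=1)
            < inflated[i] + inflated[neigh]
        ]
        pts = coords[i] + inflated[i] * grid
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            dist2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= dist2 >= inflated[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * inflated[i] ** 2
    return areas


def sasa_quadrature_tolerance(
    s: Structure, probe: float = PROBE_RADIUS_NM, n_points: int = 960,
    radii: Optional[dict] = None,
) -> float:
    """Total-area resolution of the point grid (nm^2)."""
    r = atom_radii(s, radii) + probe
    return float(np.sum(4.0 * np.pi * r**2) / n_points)


def buried_hydrophobic_area(
    bound: Structure,
    chain_a: str,
    chain_b: str,
    probe: float = PROBE_RADIUS_NM,
    n_points: int = 960,
    hydrophobic: Optional[set] = None,
) -> float:
    """Hydrophobic surface buried at the A/B interface (nm^2).

    Computed as the hydrophobic-residue SASA of each chain in isolation
    minus the same atoms' SASA in the complex.
    """
    hydrophobic = HYDROPHOBIC_RESIDUES if hydrophobic is None else set(hydrophobic)
    for chain in (chain_a, chain_b):
        if chain not in bound.chains():
            raise ValueError(f"chain {chain!r} not present")

    def hydrophobic_total(structure: Structure, areas: np.ndarray, chain: str) -> float:
        m = (structure.chain_ids == chain) & np.isin(
            structure.res_names, sorted(hydrophobic)
        )
        return float(areas[m].sum())

    areas_bound = shrake_rupley_sasa(bound, probe, n_points)
    total = 0.0
    for chain in (chain_a, chain_b):
        alone = bound.subset(bound.chain_ids == chain)
        areas_alone = shrake_rupley_sasa(alone, probe, n_points)
        total += hydrophobic_total(alone, areas_alone, chain)
        total -= hydrophobic_total(bound, areas_bound, chain)
    return total
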