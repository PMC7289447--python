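"""Toy two-chain complexes with planted interface geometry.

The generator builds a pair of parallel pseudo-peptide chains separated by
a 1.2 nm gap — far beyond every detector cutoff — then bridges the gap
with three planted features whose geometry is exact by construction:

* an Arg-Asp ion pair with guanidine/carboxylate centres of mass 0.45 nm
  apart,
* a Ser OG-H ... O hydrogen bond at 0.30 nm donor-acceptor distance and a
  10 degree hydrogen-donor-acceptor angle,
* a Leu-Leu hydrophobic stack with side-chain carbons within contact
  range.

Generic residues carry a small seeded jitter so different seeds give
different structures, with margins that keep accidental features
impossible.  The returned :class:`GroundTruth` lists every cross-chain
atom contact (by exhaustive double loop over the final coordinates), the
ion pair and the hydrogen bond.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .._rng import stream
from ..constants import ATOMIC_MASSES, CHARGED_GROUPS
from ..structure.core import Structure

__all__ = ["GroundTruth", "generate_toy_complex"]

_GAP = 1.2  # nm between the chain backbones
_SPACING = 0.6  # nm between consecutive residues along x
_JITTER = 0.02  # nm, generic-atom jitter amplitude


@dataclass
class GroundTruth:
    """Planted features of a synthetic complex, exact by construction."""

    planted_contacts: list = field(default_factory=list)
    planted_ion_pairs: list = field(default_factory=list)
    planted_hbonds: list = field(default_factory=list)
    analytic_potential: Optional[str] = None

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, (list, tuple)):
                return [clean(x) for x in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return json.dumps(
            {
                "planted_contacts": clean(self.planted_contacts),
                "planted_ion_pairs": clean(self.planted_ion_pairs),
                "planted_hbonds": clean(self.planted_hbonds),
                "analytic_potential": self.analytic_potential,
            },
            indent=2,
            sort_keys=True,
        )


def _backbone(x: float, y: float, z: float, jitter) -> list[tuple[str, str, np.ndarray]]:
    """Minimal backbone atom set around a residue centre."""
    template = [
        ("N", "N", np.array([-0.12, 0.0, 0.05])),
        ("CA", "C", np.array([0.0, 0.0, 0.0])),
        ("C", "C", np.array([0.12, 0.0, -0.05])),
        ("O", "O", np.array([0.14, 0.0, -0.17])),
    ]
    centre = np.array([x, y, z])
    return [(name, el, centre + off + jitter(off)) for name, el, off in template]


def generate_toy_complex(
    n_residues_per_chain: int, seed: int, separation: float = 0.0
) -> tuple[Structure, GroundTruth]:
    """Two-chain toy complex and the exact list of its planted features.

    ``separation`` adds an extra rigid translation (nm) to chain B along
    the inter-chain axis; at 10 nm every cross-chain feature vanishes and
    the ground-truth lists are empty accordingly.
    """
    n = int(n_residues_per_chain)
    if n < 2:
        raise ValueError("n_residues_per_chain must be >= 2")
    rng = stream(seed, "toy-complex")

    def jitter(_off):
        return rng.uniform(-_JITTER, _JITTER, size=3)

    def no_jitter(_off):
        return np.zeros(3)

    atoms: list[tuple[str, int, str, str, str, np.ndarray]] = []

    def add_residue(chain, res_id, res_name, atom_list):
        for atom_name, element, pos in atom_list:
            atoms.append((chain, res_id, res_name, atom_name, element, pos))

    y_b = _GAP + separation
    feature_names_a = {0: "ARG", 1: "SER"}
    feature_names_b = {0: "ASP", 1: "GLY"}
    if n >= 3:
        feature_names_a[2] = "LEU"
        feature_names_b[2] = "LEU"

    for chain, y0, names in (("A", 0.0, feature_names_a), ("B", y_b, feature_names_b)):
        for i in range(n):
            x = i * _SPACING
            res_name = names.get(i, "GLY")
            jit = no_jitter if i in names else jitter
            add_residue(chain, i + 1, res_name, _backbone(x, y0, 0.0, jit))

    # --- ion pair: Arg (A, res 1) guanidine vs Asp (B, res 1) carboxylate
    # group COMs exactly 0.45 nm apart along the inter-chain axis
    gua_com = np.array([0.0, 0.40, 0.0])
    add_residue("A", 1, "ARG", [
        ("CZ", "C", gua_com),
        ("NE", "N", gua_com + np.array([-0.12, 0.0, 0.0])),
        ("NH1", "N", gua_com + np.array([0.06, 0.0, 0.104])),
        ("NH2", "N", gua_com + np.array([0.06, 0.0, -0.104])),
    ])
    # NE/NH1/NH2 form a symmetric triangle about CZ at equal y, so the
    # mass-weighted COM coincides with gua_com exactly
    carb_com = gua_com + np.array([0.0, 0.45, 0.0]) + np.array([0.0, separation, 0.0])
    add_residue("B", 1, "ASP", [
        ("CG", "C", carb_com),
        ("OD1", "O", carb_com + np.array([0.0, 0.0, 0.09])),
        ("OD2", "O", carb_com + np.array([0.0, 0.0, -0.09])),
        ("CB", "C", carb_com + np.array([0.10, 0.0, 0.0])),
    ])

    # --- hydrogen bond: Ser OG-HG (A, res 2) to carbonyl O' (B, res 2)
    og = np.array([_SPACING, 0.45, 0.0])
    direction = np.array([0.0, 1.0, 0.0])  # towards the acceptor
    hg = og + 0.10 * np.array([np.sin(np.radians(10.0)), np.cos(np.radians(10.0)), 0.0])
    acceptor = og + 0.30 * direction + np.array([0.0, separation, 0.0])
    add_residue("A", 2, "SER", [("OG", "O", og), ("HG", "H", hg)])
    add_residue("B", 2, "GLY", [("OXT", "O", acceptor)])

    # --- hydrophobic Leu-Leu stack
    if n >= 3:
        x = 2 * _SPACING
        add_residue("A", 3, "LEU", [
            ("CB", "C", np.array([x, 0.30, 0.0])),
            ("CD1", "C", np.array([x - 0.08, 0.42, 0.0])),
            ("CD2", "C", np.array([x + 0.08, 0.42, 0.0])),
        ])
        add_residue("B", 3, "LEU", [
            ("CB", "C", np.array([x, 0.90 + separation, 0.0])),
            ("CD1", "C", np.array([x - 0.08, 0.78 + separation, 0.0])),
            ("CD2", "C", np.array([x + 0.08, 0.78 + separation, 0.0])),
        ])

    structure = Structure(
        chain_ids=np.array([a[0] for a in atoms]),
        res_ids=np.array([a[1] for a in atoms]),
        res_names=np.array([a[2] for a in atoms]),
        atom_names=np.array([a[3] for a in atoms]),
        elements=np.array([a[4] for a in atoms]),
        coords=np.array([a[5] for a in atoms]),
    )

    truth = GroundTruth(analytic_potential=None)

    # cross-chain heavy-atom contacts by exhaustive double loop
    contact_counts: dict = {}
    for ci, ri, ni, ai, ei, pi in atoms:
        if ci != "A" or ei == "H":
            continue
        for cj, rj, nj, aj, ej, pj in atoms:
            if cj != "B" or ej == "H":
                continue
            if float(np.linalg.norm(pi - pj)) < 0.5:
                key = (("A", ri, ni), ("B", rj, nj))
                contact_counts[key] = contact_counts.get(key, 0) + 1
    truth.planted_contacts = [
        (ra, rb, c) for (ra, rb), c in sorted(contact_counts.items())
    ]

    # the single candidate ion pair, listed iff its COM criterion holds
    com_dist = float(np.linalg.norm(carb_com - gua_com))
    if com_dist < 0.5:
        truth.planted_ion_pairs = [(("A", 1, "ARG"), ("B", 1, "ASP"), com_dist)]

    # the single candidate hydrogen bond
    da = float(np.linalg.norm(acceptor - og))
    v_da, v_dh = acceptor - og, hg - og
    angle = float(np.degrees(np.arccos(np.clip(
        np.dot(v_da, v_dh) / (np.linalg.norm(v_da) * np.linalg.norm(v_dh)),
        -1.0, 1.0,
    ))))
    if da < 0.35 and angle < 30.0:
        truth.planted_hbonds = [
            (("A", 2, "SER", "OG"), ("B", 2, "GLY", "OXT"), da, angle)
        ]

    return structure, truth
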