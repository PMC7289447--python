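"""Geometric interface detectors: contacts, ion pairs, hydrogen bonds.

All cutoffs are strict (<), distances in nm.  Contacts count heavy-atom
pairs across two disjoint residue selections within 0.5 nm; ion pairs use
the mass-weighted centre of the charged side-chain group (Arg guanidine,
Lys NZ, Asp/Glu carboxylate) with the same 0.5 nm cutoff; hydrogen bonds
use a 0.35 nm donor-acceptor cutoff and a 30 degree hydrogen-donor-acceptor
angle cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from ..constants import (
    ATOMIC_MASSES,
    CHARGED_GROUPS,
    NEGATIVE_RESIDUES,
    POSITIVE_RESIDUES,
)
from .core import Structure

__all__ = [
    "ContactReport",
    "IonPair",
    "HydrogenBond",
    "selection_mask",
    "interface_contacts",
    "detect_ion_pairs",
    "detect_hbonds",
    "pair_probability",
    "charged_fraction",
]

Selection = Union[str, Iterable[tuple[str, int]]]

ResidueKey = tuple[str, int, str]  # chain, residue number, residue name


@dataclass
class ContactReport:
    atom_contact_count: int
    residue_pairs: list  # of (ResidueKey, ResidueKey, n_atom_contacts)
    interface_residues_a: set
    interface_residues_b: set


@dataclass(frozen=True)
class IonPair:
    positive: ResidueKey
    negative: ResidueKey
    distance: float  # nm between group centres of mass

    @property
    def key(self) -> frozenset:
        return frozenset(((*self.positive[:2],), (*self.negative[:2],)))


@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple  # (chain, res_id, res_name, atom_name)
    acceptor: tuple
    distance: float
    angle: Optional[float]  # degrees; None when hydrogens were unavailable

    @property
    def key(self) -> frozenset:
        return frozenset((self.donor[:2], self.acceptor[:2]))


def selection_mask(s: Structure, sel: Selection) -> np.ndarray:
    """Boolean atom mask for a selection: a chain id, or (chain, resid) pairs."""
    if isinstance(sel, str):
        return s.chain_ids == sel
    pairs = {(str(c), int(r)) for c, r in sel}
    return np.asarray(
        [(str(c), int(r)) in pairs for c, r in zip(s.chain_ids, s.res_ids)]
    )


def interface_contacts(
    s: Structure, sel_a: Selection, sel_b: Selection, cutoff: float = 0.5
) -> ContactReport:
    """Count heavy-atom pairs across two disjoint selections within cutoff."""
    mask_a = selection_mask(s, sel_a) & s.heavy_mask
    mask_b = selection_mask(s, sel_b) & s.heavy_mask
    if np.any(mask_a & mask_b):
        raise ValueError("selections overlap")
    ia, ib = np.where(mask_a)[0], np.where(mask_b)[0]
    pairs: dict = {}
    if len(ia) and len(ib):
        dist = cdist(s.coords[ia], s.coords[ib])
        hits = np.argwhere(dist < cutoff)
        for i, j in hits:
            gi, gj = ia[i], ib[j]
            ra = (str(s.chain_ids[gi]), int(s.res_ids[gi]), str(s.res_names[gi]))
            rb = (str(s.chain_ids[gj]), int(s.res_ids[gj]), str(s.res_names[gj]))
            pairs[(ra, rb)] = pairs.get((ra, rb), 0) + 1
    residue_pairs = [(ra, rb, n) for (ra, rb), n in sorted(pairs.items())]
    return ContactReport(
        atom_contact_count=int(sum(pairs.values())),
        residue_pairs=residue_pairs,
        interface_residues_a={ra for ra, _, _ in residue_pairs},
        interface_residues_b={rb for _, rb, _ in residue_pairs},
    )


def _charge_groups(s: Structure):
    """Yield (sign, ResidueKey, COM) for every complete charged group."""
    for chain, res_id, res_name in s.residues():
        entry = CHARGED_GROUPS.get(res_name)
        if entry is None:
            continue
        sign, atom_names = entry
        m = (s.chain_ids == chain) & (s.res_ids == res_id)
        names = s.atom_names[m]
        idx = {str(n): i for n, i in zip(names, np.where(m)[0])}
        missing = [a for a in atom_names if a not in idx]
        if missing:
            warnings.warn(
                f"{res_name} {chain}{res_id}: missing group atoms {missing}; skipped"
            )
            continue
        rows = [idx[a] for a in atom_names]
        masses = np.array(
            [ATOMIC_MASSES.get(str(s.elements[i]).upper(), 12.011) for i in rows]
        )
        com = (s.coords[rows] * masses[:, None]).sum(axis=0) / masses.sum()
        yield sign, (chain, res_id, res_name), com


def detect_ion_pairs(
    s: Structure, cutoff: float = 0.5, only_cross_chain: bool = False
) -> list[IonPair]:
    """Oppositely charged side-chain groups with COM distance < cutoff."""
    groups = list(_charge_groups(s))
    out = []
    for i, (sign_i, key_i, com_i) in enumerate(groups):
        for sign_j, key_j, com_j in groups[i + 1 :]:
            if sign_i * sign_j >= 0:
                continue
            if only_cross_chain and key_i[0] == key_j[0]:
                continue
            dist = float(np.linalg.norm(com_i - com_j))
            if dist < cutoff:
                pos, neg = (key_i, key_j) if sign_i > 0 else (key_j, key_i)
                out.append(IonPair(pos, neg, dist))
    return sorted(out, key=lambda p: (p.positive, p.negative))


_DONOR_ELEMENTS = {"N", "O", "S"}
_ACCEPTOR_ELEMENTS = {"N", "O"}
_H_BOND_LENGTH = 0.12  # nm, max covalent D-H distance


def detect_hbonds(
    s: Structure,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
    only_cross_chain: bool = False,
) -> list[HydrogenBond]:
    """Donor-acceptor pairs meeting the distance and angle criteria.

    Donors are N/O/S atoms with a covalently attached hydrogen (same
    residue, within 0.12 nm).  If the structure contains no hydrogens the
    angle test is skipped and only the distance criterion applies — the
    downgrade is reported with a warning.
    """
    elements = np.char.upper(s.elements.astype(str))
    h_idx = np.where(elements == "H")[0]
    have_h = len(h_idx) > 0
    if not have_h and s.n_atoms:
        warnings.warn(
            "no hydrogens present: applying donor-acceptor distance criterion only"
        )

    heavy = np.where(elements != "H")[0]
    donors: list[tuple[int, list[int]]] = []
    for i in heavy:
        if str(elements[i]) not in _DONOR_ELEMENTS:
            continue
        if have_h:
            same_res = (
                (s.chain_ids[h_idx] == s.chain_ids[i])
                & (s.res_ids[h_idx] == s.res_ids[i])
            )
            cand = h_idx[same_res]
            if len(cand) == 0:
                continue
            dists = np.linalg.norm(s.coords[cand] - s.coords[i], axis=1)
            attached = [int(h) for h, d in zip(cand, dists) if d < _H_BOND_LENGTH]
            if attached:
                donors.append((int(i), attached))
        else:
            donors.append((int(i), []))

    acceptors = [int(i) for i in heavy if str(elements[i]) in _ACCEPTOR_ELEMENTS]
    out = []
    for d_i, hydrogens in donors:
        for a_i in acceptors:
            same_residue = (
                s.chain_ids[d_i] == s.chain_ids[a_i]
                and s.res_ids[d_i] == s.res_ids[a_i]
            )
            if a_i == d_i or same_residue:
                continue
            # without hydrogens donor/acceptor roles are indistinguishable:
            # report each unordered pair once
            if not hydrogens and not have_h and a_i < d_i:
                continue
            if only_cross_chain and s.chain_ids[d_i] == s.chain_ids[a_i]:
                continue
            dist = float(np.linalg.norm(s.coords[a_i] - s.coords[d_i]))
            if not dist < d_cut:
                continue
            angle = None
            if hydrogens:
                v_da = s.coords[a_i] - s.coords[d_i]
                best = None
                for h in hydrogens:
                    v_dh = s.coords[h] - s.coords[d_i]
                    cosang = np.dot(v_da, v_dh) / (
                        np.linalg.norm(v_da) * np.linalg.norm(v_dh)
                    )
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                    best = ang if best is None else min(best, ang)
                angle = best
                if not angle < angle_cut:
                    continue
            out.append(
                HydrogenBond(
                    donor=(
                        str(s.chain_ids[d_i]), int(s.res_ids[d_i]),
                        str(s.res_names[d_i]), str(s.atom_names[d_i]),
                    ),
                    acceptor=(
                        str(s.chain_ids[a_i]), int(s.res_ids[a_i]),
                        str(s.res_names[a_i]), str(s.atom_names[a_i]),
                    ),
                    distance=dist,
                    angle=angle,
                )
            )
    return sorted(out, key=lambda h: (h.donor, h.acceptor))


def pair_probability(
    frames: Sequence[Structure],
    pair: Iterable[tuple[str, int]],
    detector: Callable[[Structure], list],
) -> float:
    """Fraction of frames in which ``detector`` reports the residue pair.

    ``pair`` is two (chain, residue number) identifiers; detector results
    must expose a ``key`` frozenset of such identifiers (ion pairs and
    hydrogen bonds here do).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    target = frozenset((str(c), int(r)) for c, r in pair)
    if len(target) != 2:
        raise ValueError("pair must name two distinct residues")
    hits = sum(
        1 for frame in frames if any(item.key == target for item in detector(frame))
    )
    return hits / len(frames)


def charged_fraction(
    residue_names: Sequence[str], histidine_positive: bool = False
) -> tuple[float, float]:
    """(fraction positive, fraction negative) of a residue-name list."""
    names = [str(r).upper() for r in residue_names]
    if not names:
        return 0.0, 0.0
    known = POSITIVE_RESIDUES | NEGATIVE_RESIDUES | {
        "ALA", "ASN", "CYS", "GLN", "GLY", "HIS", "ILE", "LEU", "MET",
        "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
    positive = set(POSITIVE_RESIDUES) | ({"HIS"} if histidine_positive else set())
    n_pos = n_neg = 0
    for name in names:
        if name not in known:
            warnings.warn(f"unknown residue name {name!r}: counted as uncharged")
        if name in positive:
            n_pos += 1
        elif name in NEGATIVE_RESIDUES:
            n_neg += 1
    return n_pos / len(names), n_neg / len(names)
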