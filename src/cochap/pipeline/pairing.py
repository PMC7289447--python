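"""Pairing partner-family alignments on a shared species set.

Interface coevolution is tested between two protein families that
interact (cochaperone and chaperone).  Each species contributes one
ortholog per family; the two alignments are concatenated per species into
a :class:`PairedAlignment` whose column provenance records family and
original column.  Column numbers in the public API are 1-based.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Union

from ..phylo.alignment import Alignment, ColumnInfo, GAP

__all__ = ["PairedAlignment", "pair_orthologs", "map_interface_to_columns"]

SpeciesMap = Union[str, Mapping[str, str], Callable[[str], str]]


@dataclass
class PairedAlignment:
    """Concatenated two-family alignment with per-species records."""

    alignment: Alignment
    block_boundary: int  # number of columns of the A-family block
    family_a: str = "A"
    family_b: str = "B"

    @property
    def n_species(self) -> int:
        return self.alignment.n_seqs

    def column_in_paired(self, family: str, column: int) -> int:
        """Map a 1-based family-local column to a 1-based paired column."""
        if family == self.family_a:
            if not 1 <= column <= self.block_boundary:
                raise ValueError("column outside A block")
            return column
        if family == self.family_b:
            out = self.block_boundary + column
            if not self.block_boundary < out <= self.alignment.n_cols:
                raise ValueError("column outside B block")
            return out
        raise ValueError(f"unknown family {family!r}")

    def column(self, paired_column: int) -> dict[str, str]:
        """1-based paired-alignment column as a species -> symbol map."""
        if not 1 <= paired_column <= self.alignment.n_cols:
            raise ValueError("column out of range")
        return self.alignment.column(paired_column - 1)


def _species_fn(species_map: SpeciesMap) -> Callable[[str], str]:
    if callable(species_map):
        return species_map
    if isinstance(species_map, Mapping):
        return lambda rid: species_map[rid]
    pattern = re.compile(species_map)

    def from_regex(rid: str) -> str:
        m = pattern.search(rid)
        if not m:
            raise ValueError(f"species pattern does not match record id {rid!r}")
        return m.group(1) if m.groups() else m.group(0)

    return from_regex


def pair_orthologs(
    msa_a: Alignment,
    msa_b: Alignment,
    species_map: SpeciesMap = r"^([^|_]+)",
) -> PairedAlignment:
    """Concatenate the two family alignments species by species.

    ``species_map`` extracts the species key from a record id (regex with
    an optional capture group, mapping, or callable).  Species present in
    only one family are dropped with a warning; a duplicated species
    within one family is ambiguous and raises.
    """
    fn = _species_fn(species_map)
    by_species = []
    for label, msa in (("A", msa_a), ("B", msa_b)):
        mapping: dict[str, str] = {}
        for rid in msa.ids:
            sp = fn(rid)
            if sp in mapping:
                raise ValueError(
                    f"species {sp!r} appears more than once in family {label}"
                )
            mapping[sp] = rid
        by_species.append(mapping)
    map_a, map_b = by_species
    shared = [sp for sp in map_a if sp in map_b]
    if not shared:
        raise ValueError("no species shared between the two families")
    dropped = (len(map_a) - len(shared)) + (len(map_b) - len(shared))
    if dropped:
        warnings.warn(f"dropped {dropped} records without a partner species")

    ids, seqs = [], []
    for sp in shared:
        ids.append(sp)
        seqs.append(msa_a.sequence(map_a[sp]) + msa_b.sequence(map_b[sp]))
    cols = [ColumnInfo(family="A", original_column=j + 1) for j in range(msa_a.n_cols)]
    cols += [ColumnInfo(family="B", original_column=j + 1) for j in range(msa_b.n_cols)]
    return PairedAlignment(
        alignment=Alignment(ids, seqs, cols), block_boundary=msa_a.n_cols
    )


def map_interface_to_columns(
    residue_numbers,
    reference_id: str,
    msa: Alignment,
) -> tuple[dict[int, int], list[tuple[int, str]]]:
    """Map 1-based residue numbers of a reference sequence to alignment columns.

    Returns (residue -> 1-based column, error list).  Residues beyond the
    reference's ungapped length are listed as unmappable rather than
    raising; a residue can never map onto a reference gap because columns
    are assigned by gap-aware cumulative position.
    """
    seq = msa.sequence(reference_id)
    residue_to_col: dict[int, int] = {}
    resnum = 0
    for j, sym in enumerate(seq, start=1):
        if sym != GAP:
            resnum += 1
            residue_to_col[resnum] = j
    mapping: dict[int, int] = {}
    errors: list[tuple[int, str]] = []
    for r in residue_numbers:
        r = int(r)
        if r in residue_to_col:
            mapping[r] = residue_to_col[r]
        else:
            errors.append((r, "beyond reference sequence length" if r > resnum
                           else "invalid residue number"))
    return mapping, errors
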