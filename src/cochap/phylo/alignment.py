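"""Aligned amino-acid sequences with per-column provenance.

The alphabet is the 20 standard amino acids plus the gap character ``-``.
Column metadata records which partner family a column came from and its
original column index, which is what lets the paired-alignment pipeline
report results in the coordinates of the source alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..constants import AMINO_ACIDS

__all__ = ["ColumnInfo", "Alignment", "read_fasta", "write_fasta"]

GAP = "-"
_VALID = set(AMINO_ACIDS) | {GAP}


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one alignment column."""

    family: Optional[str] = None
    original_column: Optional[int] = None


class Alignment:
    """Immutable multiple sequence alignment over the 20-AA + gap alphabet."""

    def __init__(
        self,
        ids: Sequence[str],
        sequences: Sequence[str],
        columns: Optional[Sequence[ColumnInfo]] = None,
    ):
        ids = list(ids)
        sequences = [str(s).upper() for s in sequences]
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        for sid, seq in zip(ids, sequences):
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"record {sid!r} contains invalid symbols {sorted(bad)}")
        self.ids = ids
        self.sequences = sequences
        self.n_cols = lengths.pop() if lengths else 0
        if columns is None:
            columns = [ColumnInfo() for _ in range(self.n_cols)]
        if len(columns) != self.n_cols:
            raise ValueError("column metadata length must match alignment width")
        self.columns = list(columns)

    # -- access ------------------------------------------------------------
    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    def sequence(self, record_id: str) -> str:
        try:
            return self.sequences[self.ids.index(record_id)]
        except ValueError:
            raise KeyError(f"no record {record_id!r}") from None

    def column(self, j: int) -> dict[str, str]:
        """Column ``j`` (0-based) as a leaf-name -> symbol map."""
        return {sid: seq[j] for sid, seq in zip(self.ids, self.sequences)}

    def subset_columns(self, indices: Iterable[int]) -> "Alignment":
        indices = list(indices)
        seqs = ["".join(s[j] for j in indices) for s in self.sequences]
        cols = [self.columns[j] for j in indices]
        return Alignment(self.ids, seqs, cols)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Alignment n_seqs={self.n_seqs} n_cols={self.n_cols}>"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and self.sequences == other.sequences
        )


def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
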