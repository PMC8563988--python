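"""MSA container and FASTA I/O.

An :class:`MSA` is an ``N x L`` matrix of integer residue codes together with
its :class:`~gpsmcap.alphabet.Alphabet` and per-sequence identifiers.  All
statistics in this package are computed from this representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import PROTEIN, Alphabet
from .errors import AlignmentError, EncodingError


@dataclass
class MSA:
    """Integer-encoded multiple sequence alignment.

    Attributes
    ----------
    data:
        ``N x L`` array of codes in ``[0, q)`` (stored as uint8).
    alphabet:
        The residue alphabet the codes refer to.
    ids:
        ``N`` sequence identifiers.
    """

    data: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: PROTEIN)
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise AlignmentError("MSA data must be a 2-D (N x L) matrix")
        if self.data.size and self.data.max() >= self.alphabet.q:
            raise EncodingError(
                f"code {int(self.data.max())} out of range for q={self.alphabet.q}"
            )
        if self.ids is None:
            self.ids = [f"seq{i}" for i in range(self.data.shape[0])]
        if len(self.ids) != self.data.shape[0]:
            raise AlignmentError("number of ids must match number of sequences")

    @property
    def N(self) -> int:
        """Number of sequences."""
        return self.data.shape[0]

    @property
    def L(self) -> int:
        """Alignment length."""
        return self.data.shape[1]

    def sequences(self) -> list[str]:
        """Decode all rows back to character strings."""
        return [self.alphabet.decode(row) for row in self.data]

    def take(self, indices: np.ndarray) -> "MSA":
        """Row subset (new MSA, ids preserved)."""
        indices = np.asarray(indices)
        return MSA(self.data[indices], self.alphabet, [self.ids[int(i)] for i in indices])

    @classmethod
    def from_sequences(
        cls,
        sequences: list[str],
        alphabet: Alphabet = PROTEIN,
        ids: list[str] | None = None,
    ) -> "MSA":
        """Encode a list of equal-length strings into an MSA."""
        if not sequences:
            raise AlignmentError("cannot build an MSA from zero sequences")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        if ids is None:
            ids = [f"seq{i}" for i in range(len(sequences))]
        rows = [alphabet.encode(s, record=i) for s, i in zip(sequences, ids)]
        return cls(np.vstack(rows), alphabet, list(ids))


def read_msa(path: str | Path, alphabet: Alphabet = PROTEIN) -> MSA:
    """Read an aligned FASTA file into an integer-encoded MSA.

    Record order and ids are preserved; residues are uppercased; ``'.'`` and
    ``'-'`` both map to the gap code.  Ragged records raise
    :class:`AlignmentError`; characters outside the alphabet raise
    :class:`EncodingError` naming the record and column.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(
            f"records in {path} have ragged lengths {sorted(lengths)}; "
            "input must be an alignment"
        )
    ids = [r.id for r in records]
    rows = [alphabet.encode(str(r.seq), record=r.id) for r in records]
    return MSA(np.vstack(rows), alphabet, ids)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write an MSA to FASTA (sequence lines wrapped at 60 columns)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(msa.ids, msa.sequences())
    ]
    SeqIO.write(records, str(path), "fasta")


def save_msa_npz(msa: MSA, path: str | Path) -> None:
    """Serialize an MSA to a compact binary container with alphabet metadata."""
    np.savez_compressed(
        str(path),
        data=msa.data,
        symbols=np.array(msa.alphabet.symbols),
        ids=np.array(msa.ids),
        format_version=np.array(1),
    )


def load_msa_npz(path: str | Path) -> MSA:
    """Load an MSA written by :func:`save_msa_npz`."""
    with np.load(str(path), allow_pickle=False) as f:
        alphabet = Alphabet(str(f["symbols"]))
        return MSA(f["data"], alphabet, [str(s) for s in f["ids"]])
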