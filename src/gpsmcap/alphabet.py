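"""Residue alphabets and integer encoding.

Sequences are handled internally as integer codes in ``[0, q)``.  The default
alphabet is the 20 standard amino acids followed by the alignment gap ``'-'``
(q = 21, gap code 20).  ``'.'`` is treated as an alias of the gap on encoding,
and lowercase input is uppercased, matching common MSA conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EncodingError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet.

    Parameters
    ----------
    symbols:
        Ordered string of unique residue characters.  If a gap character
        ``'-'`` is present its index is fixed by its position in ``symbols``.
    """

    symbols: str = AMINO_ACIDS + GAP

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("alphabet must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def q(self) -> int:
        """Number of symbols (alphabet size)."""
        return len(self.symbols)

    @property
    def gap_index(self) -> int | None:
        """Integer code of the gap character, or ``None`` if the alphabet has no gap."""
        i = self.symbols.find(GAP)
        return None if i < 0 else i

    def _lookup(self) -> dict[str, int]:
        table = {c: i for i, c in enumerate(self.symbols)}
        gi = self.gap_index
        if gi is not None:
            table.setdefault(".", gi)
        return table

    def encode(self, sequence: str, *, record: str | None = None) -> np.ndarray:
        """Encode a character sequence to integer codes.

        Uppercases input; maps ``'.'`` to the gap code when a gap exists.
        Raises :class:`EncodingError` naming the record and column for
        characters outside the alphabet.
        """
        table = self._lookup()
        out = np.empty(len(sequence), dtype=np.uint8)
        for col, ch in enumerate(sequence.upper()):
            code = table.get(ch)
            if code is None:
                where = f"record {record!r}, " if record is not None else ""
                raise EncodingError(
                    f"character {ch!r} at {where}column {col + 1} is not in alphabet "
                    f"{self.symbols!r}"
                )
            out[col] = code
        return out

    def decode(self, codes: np.ndarray) -> str:
        """Decode integer codes back to a character string."""
        codes = np.asarray(codes)
        if codes.size and codes.max() >= self.q:
            raise EncodingError(f"code {int(codes.max())} out of range for q={self.q}")
        return "".join(self.symbols[int(c)] for c in codes)


#: Default 21-letter protein alphabet (20 amino acids + gap).
PROTEIN = Alphabet()


def reduced_alphabet(q: int) -> Alphabet:
    """A q-letter alphabet using the first ``q`` amino-acid characters
    (q = 21 yields the full protein alphabet including the gap).

    Convenient for synthetic targets with small state spaces.
    """
    if not 1 <= q <= len(AMINO_ACIDS) + 1:
        raise ValueError(f"q must be in [1, {len(AMINO_ACIDS) + 1}]")
    return Alphabet((AMINO_ACIDS + GAP)[:q])
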