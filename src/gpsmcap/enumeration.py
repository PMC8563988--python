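"""Exact enumeration of small sequence distributions.

For systems with ``q**L`` up to ten million states the full probability table
``p(S)`` is materialized.  This serves three roles: a brute-force oracle for
the samplers and metrics, the exact marginal estimator inside Potts inference
on small systems, and a fast direct sampler for synthetic targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alphabet import Alphabet, reduced_alphabet
from .errors import SizeError
from .msa import MSA
from .stats import n_pairs, pair_list, word_codes

#: Largest state count that may be enumerated.
MAX_STATES = 10_000_000


def _check_size(L: int, q: int) -> int:
    total = q**L
    if total > MAX_STATES:
        raise SizeError(f"q**L = {total} exceeds enumeration cap {MAX_STATES}")
    return total


def all_sequences(L: int, q: int) -> np.ndarray:
    """All ``q**L`` length-L code sequences, lexicographic, shape (q**L, L)."""
    total = _check_size(L, q)
    idx = np.unravel_index(np.arange(total), (q,) * L)
    return np.stack(idx, axis=1).astype(np.uint8)


@dataclass
class SequenceDistribution:
    """A fully enumerated distribution over length-L sequences.

    ``probs[k]`` is the probability of the k-th sequence in lexicographic
    order; ``log_z`` records the log-normalizer when built from energies so
    exact statistical energies ``E(S) = -log p(S)`` are recoverable.
    """

    probs: np.ndarray
    L: int
    q: int
    alphabet: Alphabet
    seqs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.q**self.L,):
            raise ValueError("probability table has wrong length")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")
        if self.seqs is None:
            self.seqs = all_sequences(self.L, self.q)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_probs(
        cls, probs: np.ndarray, L: int, q: int, alphabet: Alphabet | None = None
    ) -> "SequenceDistribution":
        return cls(probs, L, q, alphabet or reduced_alphabet(q))

    @classmethod
    def from_energies(
        cls, energies: np.ndarray, L: int, q: int, alphabet: Alphabet | None = None
    ) -> "SequenceDistribution":
        logZ = logsumexp(-energies)
        return cls(np.exp(-energies - logZ), L, q, alphabet or reduced_alphabet(q))

    # -- exact statistics ---------------------------------------------------

    def univariate(self) -> np.ndarray:
        """Exact single-site marginals, shape (L, q)."""
        f = np.empty((self.L, self.q))
        for i in range(self.L):
            f[i] = np.bincount(self.seqs[:, i], weights=self.probs, minlength=self.q)
        return f

    def bivariate(self) -> np.ndarray:
        """Exact pair marginals, shape (n_pairs, q, q), pair-major layout."""
        s = self.seqs.astype(np.int64)
        out = np.empty((n_pairs(self.L), self.q, self.q))
        for p, (i, j) in enumerate(pair_list(self.L)):
            code = s[:, i] * self.q + s[:, j]
            out[p] = np.bincount(
                code, weights=self.probs, minlength=self.q**2
            ).reshape(self.q, self.q)
        return out

    def word_table(self, positions: tuple[int, ...]) -> np.ndarray:
        """Exact joint marginal over ``positions`` as a flat table of length q**n."""
        n = len(positions)
        codes = word_codes(self.seqs, tuple(positions), self.q)
        return np.bincount(codes, weights=self.probs, minlength=self.q**n)

    def word_marginal(self, positions: tuple[int, ...], letters: tuple[int, ...]) -> float:
        """Exact probability of observing ``letters`` at ``positions``."""
        if len(positions) != len(letters):
            raise ValueError("positions and letters must have equal length")
        mask = np.ones(len(self.probs), dtype=bool)
        for p, a in zip(positions, letters):
            mask &= self.seqs[:, p] == a
        return float(self.probs[mask].sum())

    def neg_log_prob(self, msa: MSA) -> np.ndarray:
        """Exact statistical energies ``-log p(S)`` of the rows of ``msa``."""
        if msa.L != self.L:
            raise ValueError("sequence length mismatch")
        strides = self.q ** np.arange(self.L - 1, -1, -1, dtype=np.int64)
        codes = msa.data.astype(np.int64) @ strides
        with np.errstate(divide="ignore"):
            return -np.log(self.probs[codes])

    # -- sampling -----------------------------------------------------------

    def sample(self, n_seq: int, seed: int, id_prefix: str = "s") -> MSA:
        """Draw ``n_seq`` i.i.d. sequences exactly from the table."""
        rng = np.random.default_rng(seed)
        # normalize away float round-off for rng.choice
        p = self.probs / self.probs.sum()
        idx = rng.choice(len(p), size=n_seq, p=p)
        return MSA(
            self.seqs[idx], self.alphabet, [f"{id_prefix}{k}" for k in range(n_seq)]
        )
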