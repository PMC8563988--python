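"""Site-independent maximum-entropy sequence model.

The model is constrained to reproduce the univariate marginals of an MSA and
factorizes over positions: ``p(S) = prod_i f_hat^i_{s_i}`` with fields
``h^i_a = -log f_hat^i_a``, so statistical energies ``E(S) = sum_i h^i_{s_i}``
are exact (no unknown normalizer).  Fitting is analytic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import Alphabet
from .enumeration import SequenceDistribution
from .errors import AlignmentError
from .msa import MSA
from .stats import univariate_marginals


@dataclass
class IndepModel:
    """Independent-site model with smoothed marginals ``f_hat`` (L x q)."""

    f: np.ndarray
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2:
            raise ValueError("marginals must be L x q")
        if np.any(self.f <= 0):
            raise ValueError("smoothed marginals must be strictly positive")
        if not np.allclose(self.f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("marginal rows must sum to 1")

    @property
    def L(self) -> int:
        return self.f.shape[0]

    @property
    def q(self) -> int:
        return self.f.shape[1]

    @property
    def h(self) -> np.ndarray:
        """Field parameters ``h^i_a = -log f_hat^i_a``."""
        return -np.log(self.f)

    def enumerate_distribution(self) -> SequenceDistribution:
        """Exact product distribution (small systems only)."""
        from .enumeration import all_sequences

        seqs = all_sequences(self.L, self.q)
        logp = np.zeros(len(seqs))
        for i in range(self.L):
            logp += np.log(self.f[i])[seqs[:, i]]
        return SequenceDistribution(np.exp(logp), self.L, self.q, self.alphabet, seqs)

    def save(self, path: str | Path) -> None:
        np.savez(
            str(path),
            kind=np.array("indep"),
            format_version=np.array(1),
            symbols=np.array(self.alphabet.symbols),
            f=self.f,
        )

    @classmethod
    def load(cls, path: str | Path) -> "IndepModel":
        with np.load(str(path), allow_pickle=False) as z:
            if str(z["kind"]) != "indep":
                raise ValueError(f"{path} is not an independent-model container")
            return cls(z["f"], Alphabet(str(z["symbols"])))


def fit_indep(msa: MSA, pseudocount_weight: float | None = None) -> IndepModel:
    """Analytic maximum-likelihood fit of the independent model.

    ``pseudocount_weight`` defaults to ``1/N``.  A weight of zero is only
    admissible when every residue is observed at every position (otherwise
    ``-log 0`` fields would be infinite).
    """
    w = 1.0 / msa.N if pseudocount_weight is None else pseudocount_weight
    f = univariate_marginals(msa, w).uni
    if np.any(f <= 0):
        raise AlignmentError(
            "zero marginal frequency with pseudocount_weight=0; use w > 0"
        )
    return IndepModel(f, msa.alphabet)


def sample_indep(model: IndepModel, n_seq: int, seed: int) -> MSA:
    """Draw i.i.d. sequences, residues independently per column."""
    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    rng = np.random.default_rng(seed)
    data = np.empty((n_seq, model.L), dtype=np.uint8)
    u = rng.random((n_seq, model.L))
    for i in range(model.L):
        cdf = np.cumsum(model.f[i])
        data[:, i] = np.searchsorted(cdf, u[:, i] * cdf[-1], side="right").clip(
            0, model.q - 1
        )
    return MSA(data, model.alphabet, [f"ind{k}" for k in range(n_seq)])


def indep_energy(model: IndepModel, msa: MSA) -> np.ndarray:
    """Exact per-sequence statistical energy ``E(S) = -log p(S)`` (nats)."""
    if msa.L != model.L:
        raise AlignmentError(f"sequence length {msa.L} != model length {model.L}")
    h = model.h
    cols = np.arange(model.L)
    return h[cols[None, :], msa.data.astype(np.int64)].sum(axis=1)
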