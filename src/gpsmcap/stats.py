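"""MSA summary statistics: marginals, covariances, word frequencies,
Hamming-distance histograms, phylogenetic filtering and position-set sampling.

These are the raw observables the capacity metrics and the model-fitting code
consume.  Frequency smoothing follows the pseudocount convention
``f_hat = (1-w) * f_empirical + w / q`` — a convex mix with the uniform
distribution — so that smoothed frequencies remain normalized; the customary
"pseudocount of 1/N" corresponds to ``w = 1/N``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.spatial.distance import pdist

from .errors import AlignmentError
from .msa import MSA

# ---------------------------------------------------------------------------
# position-pair bookkeeping


def n_pairs(L: int) -> int:
    return L * (L - 1) // 2


def pair_list(L: int) -> np.ndarray:
    """All position pairs (i, j) with i < j, lexicographic, shape (n_pairs, 2)."""
    return np.array([(i, j) for i in range(L) for j in range(i + 1, L)], dtype=np.int64)


def pair_index(i: int, j: int, L: int) -> int:
    """Index of pair (i, j), i < j, in :func:`pair_list` order."""
    if not 0 <= i < j < L:
        raise ValueError(f"need 0 <= i < j < L, got i={i}, j={j}, L={L}")
    return i * L - i * (i + 1) // 2 + (j - i - 1)


# ---------------------------------------------------------------------------
# marginals


@dataclass
class MarginalSet:
    """Univariate (and optionally bivariate) smoothed frequencies of an MSA.

    ``uni[i, a]`` is the frequency of code ``a`` at position ``i``;
    ``bi[p, a, b]`` is the joint frequency at pair ``p`` of :func:`pair_list`.
    Both are smoothed with the same pseudocount weight so marginalization
    consistency holds: ``bi[p].sum(axis=1) == uni[i]``.
    """

    order: int
    uni: np.ndarray
    bi: np.ndarray | None
    pseudocount_weight: float


def _counts_uni(data: np.ndarray, q: int) -> np.ndarray:
    return np.stack([np.bincount(col, minlength=q) for col in data.T]).astype(float)


def univariate_marginals(msa: MSA, pseudocount_weight: float = 0.0) -> MarginalSet:
    """Smoothed single-site frequencies ``f^i_a``; each row sums to 1."""
    if msa.N == 0:
        raise AlignmentError("cannot compute marginals of an empty MSA")
    if not 0.0 <= pseudocount_weight < 1.0:
        raise ValueError("pseudocount_weight must be in [0, 1)")
    q = msa.alphabet.q
    f = _counts_uni(msa.data, q) / msa.N
    w = pseudocount_weight
    f = (1.0 - w) * f + w / q
    return MarginalSet(1, f, None, w)


def bivariate_marginals(msa: MSA, pseudocount_weight: float = 0.0) -> MarginalSet:
    """Smoothed pair frequencies ``f^ij_ab`` for all i < j; blocks sum to 1."""
    if msa.L < 2:
        raise AlignmentError("bivariate marginals require L >= 2")
    uni = univariate_marginals(msa, pseudocount_weight)
    q = msa.alphabet.q
    data = msa.data.astype(np.int64)
    w = pseudocount_weight
    bi = np.empty((n_pairs(msa.L), q, q))
    for p, (i, j) in enumerate(pair_list(msa.L)):
        code = data[:, i] * q + data[:, j]
        f = np.bincount(code, minlength=q * q).astype(float) / msa.N
        bi[p] = ((1.0 - w) * f + w / (q * q)).reshape(q, q)
    return MarginalSet(2, uni.uni, bi, w)


def covariances(msa: MSA) -> np.ndarray:
    """Pairwise covariance blocks ``C^ij_ab = f^ij_ab - f^i_a f^j_b``.

    Computed from unsmoothed frequencies: the covariance metric compares
    observed statistics, so smoothing is reserved for inference.
    Returns shape ``(n_pairs, q, q)``.
    """
    m = bivariate_marginals(msa, 0.0)
    return covariances_from_marginals(m.uni, m.bi, msa.L)


def covariances_from_marginals(uni: np.ndarray, bi: np.ndarray, L: int) -> np.ndarray:
    C = bi.copy()
    for p, (i, j) in enumerate(pair_list(L)):
        C[p] -= np.outer(uni[i], uni[j])
    return C


# ---------------------------------------------------------------------------
# word (higher-order marginal) frequencies


def word_codes(data: np.ndarray, positions: tuple[int, ...], q: int) -> np.ndarray:
    """Encode the subsequence at ``positions`` of every row as one integer.

    The first position is the most significant digit, so ascending code order
    is lexicographic word order.
    """
    n = len(positions)
    strides = q ** np.arange(n - 1, -1, -1, dtype=np.int64)
    return data[:, list(positions)].astype(np.int64) @ strides


def word_frequencies(msa: MSA, positions: tuple[int, ...]) -> dict[str, float]:
    """Frequencies of observed "words" (subsequences) at the given positions.

    Only observed words appear; values sum to 1.  A singleton position set
    reduces to the unsmoothed univariate marginal at that column.
    """
    positions = tuple(int(p) for p in positions)
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate positions in {positions}")
    if any(p < 0 or p >= msa.L for p in positions):
        raise ValueError(f"positions {positions} out of range for L={msa.L}")
    q = msa.alphabet.q
    codes = word_codes(msa.data, positions, q)
    uniq, counts = np.unique(codes, return_counts=True)
    n = len(positions)
    out: dict[str, float] = {}
    for code, cnt in zip(uniq, counts):
        letters = np.array(np.unravel_index(int(code), (q,) * n))
        out[msa.alphabet.decode(letters)] = cnt / msa.N
    return out


# ---------------------------------------------------------------------------
# Hamming distances


def hamming_histogram(
    msa: MSA, max_pairs: int = 20_000_000, seed: int = 0
) -> np.ndarray:
    """Normalized distribution of pairwise Hamming distances (length L + 1).

    All ``N(N-1)/2`` pairs are used when that count does not exceed
    ``max_pairs``; otherwise ``max_pairs`` pairs are drawn uniformly at random
    (with replacement — an unbiased subsample of the quadratic pair set).
    """
    if msa.N < 2:
        raise AlignmentError("hamming_histogram requires N >= 2")
    total = msa.N * (msa.N - 1) // 2
    if total <= max_pairs:
        d = np.rint(pdist(msa.data, metric="hamming") * msa.L).astype(np.int64)
    else:
        rng = np.random.default_rng(seed)
        d = np.empty(max_pairs, dtype=np.int64)
        chunk = 1_000_000
        done = 0
        while done < max_pairs:
            m = min(chunk, max_pairs - done)
            i = rng.integers(0, msa.N, size=m)
            j = rng.integers(0, msa.N - 1, size=m)
            j = np.where(j >= i, j + 1, j)  # j != i, uniform over ordered pairs
            d[done : done + m] = (msa.data[i] != msa.data[j]).sum(axis=1)
            done += m
    hist = np.bincount(d, minlength=msa.L + 1).astype(float)
    return hist / hist.sum()


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between two encoded sequences."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise AlignmentError("sequences must have equal length")
    return int((a != b).sum())


# ---------------------------------------------------------------------------
# phylogenetic filtering


def phylo_filter(msa: MSA, max_identity: float = 0.5, seed: int = 0) -> MSA:
    """Greedy random phylogenetic filtering.

    Repeatedly picks a random remaining sequence, keeps it, and removes all
    sequences whose fractional identity to it exceeds ``max_identity``, until
    none remain.  Identity counts matching columns / L with the gap treated as
    an ordinary character.  The retained set provably contains no pair above
    the threshold.
    """
    if not 0.0 < max_identity <= 1.0:
        raise ValueError("max_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    remaining = np.arange(msa.N)
    kept: list[int] = []
    while remaining.size:
        pick = int(rng.choice(remaining))
        kept.append(pick)
        ident = (msa.data[remaining] == msa.data[pick]).mean(axis=1)
        remaining = remaining[ident <= max_identity]
    return msa.take(np.array(sorted(kept)))


def identity_violations(msa: MSA, max_identity: float) -> list[tuple[int, int]]:
    """Brute-force all-pairs audit; returns pairs exceeding the threshold."""
    sim = 1.0 - pdist(msa.data, metric="hamming")
    out = []
    k = 0
    for i in range(msa.N):
        for j in range(i + 1, msa.N):
            if sim[k] > max_identity:
                out.append((i, j))
            k += 1
    return out


# ---------------------------------------------------------------------------
# position-set sampling


def sample_position_sets(
    L: int, n: int, m: int, seed: int = 0
) -> list[tuple[int, ...]]:
    """``m`` distinct sorted n-subsets of ``{0..L-1}``, uniform over subsets.

    If ``C(L, n) <= m`` all subsets are returned (in lexicographic order).
    Sampling is sort-and-deduplicate rejection, deterministic under ``seed``.
    """
    if not 2 <= n <= L:
        raise ValueError(f"need 2 <= n <= L, got n={n}, L={L}")
    total = comb(L, n)
    if total <= m:
        return [tuple(c) for c in itertools.combinations(range(L), n)]
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < m:
        s = tuple(sorted(int(x) for x in rng.choice(L, size=n, replace=False)))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out
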