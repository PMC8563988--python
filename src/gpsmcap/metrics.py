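"""Generative-capacity metrics.

Four families of statistics compare a model-generated *evaluation* MSA
against a *target* MSA drawn from the reference distribution:

* Pearson correlation of all pairwise covariance entries ``C^ij_ab``;
* ``r20``: the average over random position sets of the Pearson correlation
  between the frequencies of the target MSA's top-20 words and the same
  words' frequencies in the evaluation MSA, as a function of word length n —
  plus the ``cc-r20`` variant on connected correlations;
* the pairwise Hamming-distance distribution with total variation distance
  and a mode-centered log-log rescaling of its tails;
* Pearson correlation of per-sequence statistical energies ``E(S)``.

Pearson on a zero-variance input is undefined; those cases return 0 with a
degenerate flag, matching the convention that a covariance-free model scores
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from sympy.utilities.iterables import multiset_partitions

from .enumeration import SequenceDistribution
from .errors import AlignmentError
from .msa import MSA
from .stats import covariances, sample_position_sets, word_codes

# word tables are kept dense (bincount) up to this size, sparse beyond
_DENSE_TABLE_CAP = 1 << 24


# ---------------------------------------------------------------------------
# Pearson with degeneracy handling


@dataclass
class CorrelationResult:
    """Pearson correlation with slope and a degenerate-input flag."""

    rho: float
    slope: float
    degenerate: bool

    def __float__(self) -> float:
        return self.rho


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return CorrelationResult(0.0, 0.0, True)
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sx))
    return CorrelationResult(r, slope, False)


# ---------------------------------------------------------------------------
# pairwise covariance correlation


def covariance_correlation(eval_msa: MSA, target_msa: MSA) -> CorrelationResult:
    """Pearson rho over all covariance entries of the two MSAs.

    All entries, including near-zero ones, enter the correlation.  The slope
    of the evaluation-vs-target scatter is also reported, since magnitude
    shrinkage is invisible to the (scale-blind) correlation itself.
    """
    if eval_msa.L != target_msa.L or eval_msa.alphabet.q != target_msa.alphabet.q:
        raise AlignmentError("evaluation and target MSAs must share L and q")
    c_eval = covariances(eval_msa).ravel()
    c_target = covariances(target_msa).ravel()
    return _pearson(c_target, c_eval)


# ---------------------------------------------------------------------------
# word-frequency machinery shared by r20 / cc-r20


def _word_table(data: np.ndarray, positions: tuple[int, ...], q: int) -> np.ndarray:
    """Dense word-count table over the q**n words at ``positions``."""
    n = len(positions)
    size = q**n
    if size > _DENSE_TABLE_CAP:
        from .errors import SizeError

        raise SizeError(
            f"q**n = {size} word table exceeds the dense cap {_DENSE_TABLE_CAP}; "
            "reduce the word length or alphabet"
        )
    codes = word_codes(data, positions, q)
    return np.bincount(codes, minlength=size)


def _top_words_dense(table: np.ndarray, top_k: int):
    """Codes of the top-k observed words; ties broken by lexicographic code."""
    observed = np.nonzero(table)[0]
    if observed.size == 0:
        return observed
    # stable sort on descending count keeps ascending-code order among ties
    order = np.argsort(-table[observed], kind="stable")
    return observed[order[:top_k]]


@dataclass
class R20Result:
    """Per-word-length averaged top-k word-frequency correlations."""

    word_lengths: list[int]
    mean_scores: list[float]
    per_set_scores: list[list[float]]
    n_skipped: list[int]
    config: dict = field(default_factory=dict)

    def mean_over(self, lengths: Sequence[int]) -> float:
        sel = [self.mean_scores[self.word_lengths.index(n)] for n in lengths]
        return float(np.mean(sel))

    def to_dict(self) -> dict:
        return {
            "word_lengths": list(self.word_lengths),
            "mean_scores": [float(x) for x in self.mean_scores],
            "per_set_scores": [[float(x) for x in row] for row in self.per_set_scores],
            "n_skipped": list(self.n_skipped),
            "config": self.config,
        }


def _r20_generic(
    target_msa: MSA,
    eval_msa: MSA,
    word_lengths: Sequence[int],
    n_sets: int,
    top_k: int,
    seed: int,
    statistic: str,
) -> R20Result:
    if target_msa.L != eval_msa.L:
        raise AlignmentError("target and evaluation MSAs must share L")
    L, q = target_msa.L, target_msa.alphabet.q
    mean_scores, per_set, skipped = [], [], []
    for n in word_lengths:
        if not 2 <= n <= L:
            raise ValueError(f"word length {n} outside [2, {L}]")
        sets = sample_position_sets(L, n, n_sets, seed)
        scores: list[float] = []
        n_skip = 0
        for positions in sets:
            t_table = _word_table(target_msa.data, positions, q)
            e_table = _word_table(eval_msa.data, positions, q)
            top = _top_words_dense(t_table, top_k)
            if top.size < 3:
                n_skip += 1
                continue
            if statistic == "freq":
                tv = t_table[top] / target_msa.N
                ev = e_table[top] / eval_msa.N
            else:  # connected correlations of the same top words
                shape = (q,) * n
                t_sub = _subset_marginals(t_table.reshape(shape) / target_msa.N)
                e_sub = _subset_marginals(e_table.reshape(shape) / eval_msa.N)
                letters = np.stack(np.unravel_index(top, shape), axis=1)
                tv = np.array([_cc_from_subsets(t_sub, w) for w in letters])
                ev = np.array([_cc_from_subsets(e_sub, w) for w in letters])
            r = _pearson(tv, ev)
            if r.degenerate:
                n_skip += 1
                continue
            scores.append(r.rho)
        mean_scores.append(float(np.mean(scores)) if scores else float("nan"))
        per_set.append(scores)
        skipped.append(n_skip)
    return R20Result(
        list(word_lengths),
        mean_scores,
        per_set,
        skipped,
        config={
            "n_sets": n_sets,
            "top_k": top_k,
            "seed": seed,
            "target_N": target_msa.N,
            "eval_N": eval_msa.N,
            "statistic": statistic,
        },
    )


def r20(
    target_msa: MSA,
    eval_msa: MSA,
    word_lengths: Sequence[int] = (2, 3, 4, 5, 6, 7, 8, 9, 10),
    n_sets: int = 3000,
    top_k: int = 20,
    seed: int = 0,
) -> R20Result:
    """Averaged top-k word-frequency correlation vs word length.

    For each word length n, ``n_sets`` random position sets are drawn (shared
    seed so every model comparison sees the same sets).  At each set the
    ``top_k`` most frequent words of the *target* MSA are selected (ties
    broken lexicographically); their frequencies in the evaluation MSA (zero
    when absent) are correlated against the target frequencies, and the
    correlations are averaged over sets.  Sets whose top-k frequencies are
    degenerate (fewer than 3 observed words, or zero variance) are skipped
    and counted.
    """
    return _r20_generic(target_msa, eval_msa, word_lengths, n_sets, top_k, seed, "freq")


def cc_r20(
    target_msa: MSA,
    eval_msa: MSA,
    word_lengths: Sequence[int] = (2, 3, 4, 5),
    n_sets: int = 3000,
    top_k: int = 20,
    seed: int = 0,
) -> R20Result:
    """r20 pipeline with connected correlations replacing word frequencies.

    The same top-k target words are selected by frequency, but the correlated
    quantities are the n-point connected correlations of those words in each
    MSA.  A site-independent distribution has connected correlations of zero
    at every order >= 2, so this variant isolates statistics that no
    independent model can reproduce.  It is more severely affected by
    estimation error than plain r20, so it is most useful at modest n.
    """
    return _r20_generic(target_msa, eval_msa, word_lengths, n_sets, top_k, seed, "cc")


# ---------------------------------------------------------------------------
# connected correlations (partition cumulant formula)


def _subset_marginals(joint: np.ndarray) -> dict[frozenset, np.ndarray]:
    """All marginal tables of a joint distribution over n axes, keyed by the
    retained axis subset."""
    n = joint.ndim
    out: dict[frozenset, np.ndarray] = {}
    for mask in range(1, 1 << n):
        keep = [i for i in range(n) if mask >> i & 1]
        drop = tuple(i for i in range(n) if not mask >> i & 1)
        out[frozenset(keep)] = joint.sum(axis=drop) if drop else joint
    return out


def _cc_from_subsets(sub: dict[frozenset, np.ndarray], letters: np.ndarray) -> float:
    """Cumulant via the partition Moebius formula:
    sum over set partitions P of (-1)^{|P|-1} (|P|-1)! prod_B f(B)."""
    n = len(letters)
    total = 0.0
    for partition in multiset_partitions(list(range(n))):
        k = len(partition)
        term = (-1.0) ** (k - 1) * float(factorial(k - 1))
        for block in partition:
            table = sub[frozenset(block)]
            term *= float(table[tuple(letters[b] for b in block)])
        total += term
    return total


def connected_correlation(
    source: MSA | SequenceDistribution,
    positions: tuple[int, ...],
    letters: tuple[int, ...],
) -> float:
    """n-point connected correlation of one word.

    ``source`` may be an MSA (empirical frequencies) or an enumerated
    distribution (exact marginals).  Order 2 reduces exactly to the pairwise
    covariance ``C^ij_ab``; any site-independent distribution gives 0 at
    every order >= 2.
    """
    if len(positions) != len(letters):
        raise ValueError("positions and letters must have equal length")
    if len(positions) < 2:
        raise ValueError("connected correlations need order >= 2")
    n = len(positions)
    if isinstance(source, SequenceDistribution):
        q = source.q
        joint = source.word_table(tuple(positions)).reshape((q,) * n)
    else:
        q = source.alphabet.q
        table = np.bincount(
            word_codes(source.data, tuple(positions), q), minlength=q**n
        )
        joint = table.reshape((q,) * n) / source.N
    sub = _subset_marginals(joint)
    return _cc_from_subsets(sub, np.asarray(letters))


# ---------------------------------------------------------------------------
# Hamming histogram comparison


def tvd(hist_a: np.ndarray, hist_b: np.ndarray) -> float:
    """Total variation distance ``1/2 sum |a - b|`` between two normalized
    histograms on the same support; 0 for identical, 1 for disjoint."""
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must have equal support length")
    for name, h in (("first", a), ("second", b)):
        if not np.isclose(h.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} histogram is not normalized (sum={h.sum()})")
    return float(0.5 * np.abs(a - b).sum())


@dataclass
class RescaledTails:
    """Mode-centered, max-normalized histogram tails for log-log plotting."""

    left: tuple[np.ndarray, np.ndarray]
    right: tuple[np.ndarray, np.ndarray]
    mode_distance: float
    max_frequency: float


def loglog_rescale(hist: np.ndarray, distances: np.ndarray | None = None) -> RescaledTails:
    """Rescale a distance histogram by its mode and maximum.

    Returns ``(d / d_mode, f / f_max)`` point sets split into the left
    (d < mode) and right (d > mode) tails; zero-frequency bins are dropped.
    Mode ties resolve to the smallest distance.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.size == 0 or hist.sum() == 0:
        raise ValueError("histogram is empty")
    d = np.arange(hist.size, dtype=float) if distances is None else np.asarray(
        distances, dtype=float
    )
    mode_idx = int(np.argmax(hist))  # argmax takes the first (smallest d) tie
    d_mode, f_max = d[mode_idx], hist[mode_idx]
    if d_mode == 0:
        raise ValueError("mode at distance 0 cannot anchor a ratio rescaling")
    keep = hist > 0
    dr, fr = d[keep] / d_mode, hist[keep] / f_max
    left = (dr[dr < 1.0], fr[dr < 1.0])
    right = (dr[dr > 1.0], fr[dr > 1.0])
    return RescaledTails(left, right, float(d_mode), float(f_max))


def hamming_report(msa: MSA, max_pairs: int = 20_000_000, seed: int = 0) -> dict:
    """Normalized Hamming histogram of an MSA plus its mode distance."""
    from .stats import hamming_histogram

    hist = hamming_histogram(msa, max_pairs=max_pairs, seed=seed)
    return {"hist": [float(x) for x in hist], "mode": int(np.argmax(hist))}


# ---------------------------------------------------------------------------
# statistical energy correlation


def energy_correlation(
    eval_energies: np.ndarray, target_energies: np.ndarray
) -> CorrelationResult:
    """Pearson rho between per-sequence energies of the two models.

    Invariant to affine shifts of either input, so dropping the unknown
    normalizer log Z from either energy is harmless.
    """
    x = np.asarray(eval_energies, float)
    y = np.asarray(target_energies, float)
    if x.size != y.size:
        raise ValueError("energy vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 sequences")
    return _pearson(y, x)


# ---------------------------------------------------------------------------
# estimation-error upper bounds


def estimation_bound(
    sampler: Callable[[int, int], MSA],
    msa_size_a: int,
    msa_size_b: int,
    metric: Callable[[MSA, MSA], object],
    seed_a: int,
    seed_b: int,
):
    """Metric value between two independent draws from the same distribution.

    This self-comparison is the ceiling a perfectly specified model could
    reach at the given MSA sizes: all remaining disagreement is estimation
    error.  ``sampler(n, seed)`` must be deterministic under its seed; using
    the same seed for both draws would compare an MSA with itself, so it is
    rejected.
    """
    if seed_a == seed_b:
        raise ValueError("self-comparison needs independent seeds (seed_a != seed_b)")
    msa_a = sampler(msa_size_a, seed_a)
    msa_b = sampler(msa_size_b, seed_b)
    return metric(msa_a, msa_b)
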