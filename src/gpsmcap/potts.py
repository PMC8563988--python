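"""Pairwise Potts Hamiltonian: energies, MCMC generation, exact enumeration,
and marginal-matching inverse-Ising inference.

The model is ``p(S) = exp(-E(S)) / Z`` with
``E(S) = sum_i h^i_{s_i} + sum_{i<j} J^ij_{s_i s_j}``.
Energies are reported up to the dropped constant ``log Z``, which cancels in
every correlation-based comparison.  Inference matches model bivariate
marginals to (pseudocount-smoothed) data marginals, with an optional SCAD
penalty shrinking weak couplings, and estimates model marginals either by
exact enumeration (small systems) or persistent Gibbs chains (general case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import Alphabet, reduced_alphabet
from .enumeration import SequenceDistribution
from .errors import AlignmentError
from .gibbs import gibbs_run
from .msa import MSA
from .stats import bivariate_marginals, n_pairs, pair_index, pair_list

# ---------------------------------------------------------------------------
# parameter counting


def num_free_params(L: int, q: int) -> int:
    """Gauge-reduced Potts parameter count: L(L-1)/2 (q-1)^2 + L(q-1).

    Equals the number of non-independent bivariate marginals the model is
    constrained to reproduce.
    """
    if L < 1 or q < 1:
        raise ValueError("need L >= 1 and q >= 1")
    return L * (L - 1) // 2 * (q - 1) ** 2 + L * (q - 1)


def indep_param_count(L: int, q: int) -> int:
    """Independent-model field count: L(q-1)."""
    if L < 1 or q < 1:
        raise ValueError("need L >= 1 and q >= 1")
    return L * (q - 1)


# ---------------------------------------------------------------------------
# model containers


@dataclass
class TripletTerm:
    """A single three-site interaction added to the pairwise energy.

    ``K[a, b, c]`` is added to ``E(S)`` when the residues at ``positions``
    are ``(a, b, c)``.  Zero ``K`` leaves the distribution unchanged.
    """

    positions: tuple[int, int, int]
    K: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.positions)) != 3:
            raise ValueError("triplet positions must be three distinct sites")
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 3:
            raise ValueError("K must be a q x q x q tensor")


@dataclass
class McmcSettings:
    """Gibbs sampler controls: independent chains, burn-in and thinning sweeps."""

    n_chains: int = 512
    burn_in_sweeps: int = 500
    thin_sweeps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in_sweeps, self.thin_sweeps) < 1:
            raise ValueError("all MCMC counts must be >= 1")


@dataclass
class FitReport:
    """Outcome of an inverse-Ising fit."""

    converged: bool
    iterations: int
    final_discrepancy: float
    step_final: float
    estimator: str
    history: list[float] = field(default_factory=list)


@dataclass
class PottsModel:
    """Fields ``h`` (L x q) and couplings ``J`` (n_pairs x q x q, pair-major).

    Pair ``p`` corresponds to ``(i, j)`` with ``i < j`` in lexicographic
    order (see :func:`gpsmcap.stats.pair_list`).
    """

    h: np.ndarray
    J: np.ndarray
    alphabet: Alphabet
    fit_report: FitReport | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (n_pairs(L), q, q):
            raise ValueError(
                f"J must have shape ({n_pairs(L)}, {q}, {q}), got {self.J.shape}"
            )
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("Potts parameters must be finite")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def coupling(self, i: int, j: int) -> np.ndarray:
        """q x q coupling block for positions i < j."""
        return self.J[pair_index(i, j, self.L)]

    def dense_couplings(self) -> np.ndarray:
        """Symmetric (L, L, q, q) coupling tensor (zero diagonal)."""
        L, q = self.L, self.q
        full = np.zeros((L, L, q, q))
        for p, (i, j) in enumerate(pair_list(L)):
            full[i, j] = self.J[p]
            full[j, i] = self.J[p].T
        return full

    def to_zero_sum_gauge(self) -> "PottsModel":
        """Equivalent model in the zero-sum (Ising) gauge.

        Row/column means of every coupling block are absorbed into the fields
        and the overall constant is dropped; the distribution is unchanged.
        """
        h = self.h.copy()
        J = self.J.copy()
        for p, (i, j) in enumerate(pair_list(self.L)):
            block = J[p]
            row = block.mean(axis=1, keepdims=True)
            col = block.mean(axis=0, keepdims=True)
            tot = block.mean()
            J[p] = block - row - col + tot
            h[i] += (row[:, 0] - tot)
            h[j] += (col[0, :] - tot)
        h -= h.mean(axis=1, keepdims=True)
        return PottsModel(h, J, self.alphabet, self.fit_report)

    def save(self, path: str | Path) -> None:
        np.savez(
            str(path),
            kind=np.array("potts"),
            format_version=np.array(1),
            symbols=np.array(self.alphabet.symbols),
            h=self.h,
            J=self.J,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PottsModel":
        with np.load(str(path), allow_pickle=False) as z:
            if str(z["kind"]) != "potts":
                raise ValueError(f"{path} is not a Potts-model container")
            return cls(z["h"], z["J"], Alphabet(str(z["symbols"])))

    @classmethod
    def zeros(cls, L: int, q: int, alphabet: Alphabet | None = None) -> "PottsModel":
        return cls(
            np.zeros((L, q)),
            np.zeros((n_pairs(L), q, q)),
            alphabet or reduced_alphabet(q),
        )


# ---------------------------------------------------------------------------
# energies and enumeration


def potts_energy(
    model: PottsModel, msa: MSA, triplet: TripletTerm | None = None
) -> np.ndarray:
    """Per-sequence energy ``E(S)`` (up to the dropped constant log Z)."""
    if msa.L != model.L:
        raise AlignmentError(f"sequence length {msa.L} != model length {model.L}")
    s = msa.data.astype(np.int64)
    cols = np.arange(model.L)
    E = model.h[cols[None, :], s].sum(axis=1)
    for p, (i, j) in enumerate(pair_list(model.L)):
        E += model.J[p, s[:, i], s[:, j]]
    if triplet is not None:
        i, j, k = triplet.positions
        E += triplet.K[s[:, i], s[:, j], s[:, k]]
    return E


def enumerate_distribution(
    model: PottsModel, triplet: TripletTerm | None = None
) -> SequenceDistribution:
    """Exact ``p(S) = exp(-E(S))/Z`` over all ``q**L`` sequences."""
    from .enumeration import all_sequences

    seqs = all_sequences(model.L, model.q)
    E = potts_energy(model, MSA(seqs, model.alphabet), triplet)
    dist = SequenceDistribution.from_energies(E, model.L, model.q, model.alphabet)
    return dist


# ---------------------------------------------------------------------------
# MCMC generation


_NO_TRIPLET_POS = np.zeros(3, dtype=np.int64)


def _triplet_args(model: PottsModel, triplet: TripletTerm | None):
    if triplet is None:
        return _NO_TRIPLET_POS, np.zeros((model.q,) * 3), False
    return np.asarray(triplet.positions, dtype=np.int64), triplet.K, True


def mcmc_sample(
    model: PottsModel,
    n_seq: int,
    settings: McmcSettings,
    triplet: TripletTerm | None = None,
) -> MSA:
    """Generate sequences by single-site Gibbs sweeps in random site order.

    ``settings.n_chains`` independent chains start from uniform-random
    states; after burn-in, states are recorded every ``thin_sweeps`` sweeps
    until at least ``n_seq`` sequences are collected (the excess from the
    final record is truncated).  Deterministic under ``settings.seed``.
    """
    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    rng = np.random.default_rng(settings.seed)
    n_chains = min(settings.n_chains, n_seq)
    states = rng.integers(0, model.q, size=(n_chains, model.L), dtype=np.uint8)
    n_records = -(-n_seq // n_chains)
    tpos, K, has_triplet = _triplet_args(model, triplet)
    recs = gibbs_run(
        states,
        model.h,
        model.dense_couplings(),
        tpos,
        K,
        has_triplet,
        settings.burn_in_sweeps,
        settings.thin_sweeps,
        n_records,
        int(settings.seed) & 0x7FFFFFFF,
    )
    data = recs.reshape(-1, model.L)[:n_seq]
    return MSA(data, model.alphabet, [f"mcmc{k}" for k in range(n_seq)])


# ---------------------------------------------------------------------------
# inverse Ising inference


def _scad_derivative(x: np.ndarray, lam: float, a: float) -> np.ndarray:
    """Derivative of the SCAD penalty: lam for |x|<=lam, linearly decaying to
    zero at a*lam, zero beyond (no bias for large couplings)."""
    ax = np.abs(x)
    mid = np.clip(a * lam - ax, 0.0, None) / (a - 1.0)
    return np.where(ax <= lam, lam, np.minimum(lam, mid))


def _apply_scad(J: np.ndarray, lam: float, a: float, step: float) -> np.ndarray:
    if lam <= 0:
        return J
    shrink = step * _scad_derivative(J, lam, a)
    out = np.sign(J) * np.clip(np.abs(J) - shrink, 0.0, None)
    return out


def fit_potts(
    msa: MSA,
    pseudocount_weight: float | None = None,
    scad_lambda: float = 0.001,
    settings: McmcSettings | None = None,
    max_iters: int = 300,
    tol: float | None = None,
    estimator: str = "auto",
    step: float = 0.5,
    update_rule: str = "log",
    scad_a: float = 3.7,
    sweeps_per_iter: int = 4,
    verbose: bool = False,
) -> PottsModel:
    """Marginal-matching inverse-Ising inference.

    Iteratively estimates model bivariate marginals (exactly by enumeration
    when ``q**L`` is small, otherwise from persistent Gibbs chains) and moves
    parameters so model marginals approach the pseudocount-smoothed data
    marginals, applying the SCAD shrinkage to couplings after each step.

    The default update is the damped log-ratio (iterative-proportional)
    rule ``delta = -step * (log f_data - log f_model)`` applied to ``h`` and
    ``J``; ``update_rule="linear"`` selects the plain marginal-difference
    gradient instead.  The step is halved whenever the marginal discrepancy
    oscillates upward.  Stops when ``max |f_data - f_model| < tol`` (default:
    twice the binomial sampling error of the data marginal estimate); on
    non-convergence the best model found is returned with
    ``fit_report.converged == False``.
    """
    if msa.N < 2:
        raise AlignmentError("fitting requires N >= 2")
    w = 1.0 / msa.N if pseudocount_weight is None else pseudocount_weight
    if w <= 0:
        raise ValueError("inference needs a positive pseudocount weight")
    data_m = bivariate_marginals(msa, w)
    if tol is None and estimator != "mcmc":
        tol = 1.0 / np.sqrt(msa.N)  # 2 x max binomial SE of the data marginals
    return fit_potts_to_marginals(
        data_m.uni,
        data_m.bi,
        msa.alphabet,
        scad_lambda=scad_lambda,
        settings=settings,
        max_iters=max_iters,
        tol=tol,
        estimator=estimator,
        step=step,
        update_rule=update_rule,
        scad_a=scad_a,
        sweeps_per_iter=sweeps_per_iter,
        verbose=verbose,
    )


def fit_potts_to_marginals(
    f_uni: np.ndarray,
    f_bi: np.ndarray,
    alphabet: Alphabet,
    scad_lambda: float = 0.0,
    settings: McmcSettings | None = None,
    max_iters: int = 300,
    tol: float | None = None,
    estimator: str = "auto",
    step: float = 0.5,
    update_rule: str = "log",
    scad_a: float = 3.7,
    sweeps_per_iter: int = 4,
    verbose: bool = False,
) -> PottsModel:
    """Inverse-Ising fit directly to (smoothed) univariate and bivariate
    marginals — the maximum-entropy moment-matching problem itself.

    :func:`fit_potts` delegates here after estimating marginals from an MSA;
    calling this with the *exact* marginals of an enumerable target fits the
    maximum-entropy pairwise model of that target.
    """
    if scad_lambda < 0:
        raise ValueError("scad_lambda must be >= 0")
    L, q = f_uni.shape

    if estimator == "auto":
        estimator = "exact" if q**L <= 2_000_000 else "mcmc"
    settings = settings or McmcSettings()

    model = PottsModel(-np.log(f_uni), np.zeros((n_pairs(L), q, q)), alphabet)

    if estimator == "mcmc":
        rng = np.random.default_rng(settings.seed)
        states = rng.integers(0, q, size=(settings.n_chains, L), dtype=np.uint8)
        m_est = settings.n_chains * sweeps_per_iter
        if tol is None:
            tol = 5.0 * 0.5 / np.sqrt(m_est)
        burn = settings.burn_in_sweeps
    else:
        if tol is None:
            tol = 1e-4

    gamma = step
    best = (np.inf, model.h.copy(), model.J.copy())
    prev_disc = np.inf
    history: list[float] = []
    it = 0
    for it in range(1, max_iters + 1):
        if estimator == "exact":
            dist = enumerate_distribution(model)
            m_uni, m_bi = dist.univariate(), dist.bivariate()
            # guard exact zeros (cannot occur for finite parameters, but be safe)
            m_uni = np.clip(m_uni, 1e-300, None)
            m_bi = np.clip(m_bi, 1e-300, None)
        else:
            recs = gibbs_run(
                states,
                model.h,
                model.dense_couplings(),
                _NO_TRIPLET_POS,
                np.zeros((q, q, q)),
                False,
                burn,
                1,
                sweeps_per_iter,
                int(rng.integers(0, 2**31 - 1)),
            )
            burn = 0  # chains stay warm after the first iteration
            sample = MSA(recs.reshape(-1, L), alphabet)
            est = bivariate_marginals(sample, 1.0 / sample.N)
            m_uni, m_bi = est.uni, est.bi

        disc = float(np.abs(f_bi - m_bi).max())
        history.append(disc)
        if disc < best[0]:
            best = (disc, model.h.copy(), model.J.copy())
        if verbose:
            print(f"iter {it:4d}  disc {disc:.3e}  step {gamma:.3g}")
        if disc < tol:
            break
        if disc > prev_disc * 1.05:
            gamma = max(gamma * 0.5, 1e-3)
        prev_disc = disc

        if update_rule == "log":
            dh = np.log(f_uni) - np.log(m_uni)
            dJ = np.log(f_bi) - np.log(m_bi)
        elif update_rule == "linear":
            dh = f_uni - m_uni
            dJ = f_bi - m_bi
        else:
            raise ValueError(f"unknown update_rule {update_rule!r}")
        h = model.h - gamma * dh
        J = model.J - gamma * dJ
        J = _apply_scad(J, scad_lambda, scad_a, gamma)
        model = PottsModel(h, J, alphabet)

    converged = best[0] < tol
    final = model if history and history[-1] == best[0] else PottsModel(
        best[1], best[2], alphabet
    )
    final.fit_report = FitReport(
        converged=converged,
        iterations=it,
        final_discrepancy=best[0],
        step_final=gamma,
        estimator=estimator,
        history=history,
    )
    return final


# ---------------------------------------------------------------------------
# triplet injection


def inject_triplet(
    model: PottsModel,
    positions: tuple[int, int, int],
    strength: float,
    pattern: np.ndarray | tuple[int, int, int] = None,
) -> tuple[PottsModel, TripletTerm]:
    """Augment a pairwise model with a single triplet interaction.

    ``pattern`` is either a full ``q x q x q`` mask or a single letter triple
    ``(a, b, c)`` marking one entry; the energy contribution of the term is
    ``strength * pattern``.  The pairwise model itself is returned unchanged;
    the (model, triplet) pair defines the augmented target distribution.
    """
    q = model.q
    if pattern is None:
        raise ValueError("pattern is required (mask or single letter triple)")
    K = np.zeros((q, q, q))
    pattern_arr = np.asarray(pattern)
    if pattern_arr.shape == (q, q, q):
        K = strength * pattern_arr.astype(float)
    elif pattern_arr.shape == (3,):
        a, b, c = (int(x) for x in pattern_arr)
        K[a, b, c] = strength
    else:
        raise ValueError("pattern must be q x q x q or a letter triple")
    return model, TripletTerm(tuple(int(p) for p in positions), K)
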