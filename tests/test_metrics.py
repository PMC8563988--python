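"""Capacity metrics: covariance correlation, r20 / cc-r20, connected
correlations, TVD, log-log rescaling, energy correlation, estimation bounds."""

import numpy as np
import pytest

from gpsmcap import (
    MSA,
    Alphabet,
    cc_r20,
    connected_correlation,
    covariance_correlation,
    energy_correlation,
    estimation_bound,
    loglog_rescale,
    r20,
    tvd,
)
from gpsmcap.alphabet import reduced_alphabet
from gpsmcap.bench import parity_target, random_potts
from gpsmcap.indep import IndepModel, sample_indep
from gpsmcap.metrics import _pearson
from gpsmcap.potts import enumerate_distribution


def random_msa(n, L, q, seed):
    rng = np.random.default_rng(seed)
    return MSA(rng.integers(0, q, (n, L), dtype=np.uint8), reduced_alphabet(q))


# ---------------------------------------------------------------------------
# Pearson / covariance correlation


def test_pearson_degenerate_input_flagged():
    r = _pearson(np.ones(5), np.arange(5.0))
    assert r.rho == 0.0 and r.degenerate


def test_covariance_correlation_identity_is_one(small_potts):
    _, dist = small_potts
    msa = dist.sample(5000, seed=1)
    r = covariance_correlation(msa, msa)
    assert r.rho == pytest.approx(1.0)


def test_covariance_correlation_scale_blind_but_slope_reports_shrinkage(small_potts):
    """An eval MSA whose covariances are target's scaled by ~0.5 keeps rho=1;
    the shrinkage shows up in the regression slope instead."""
    _, dist = small_potts
    target = dist.sample(4000, seed=2)
    r_same = covariance_correlation(target, target)
    assert r_same.slope == pytest.approx(1.0)
    # mixing the MSA with uniform noise halves covariances but not rho's sign
    # structure; check pure-scaling algebraically through the slope estimator
    x = np.arange(20.0) - 10
    scaled = _pearson(x, 0.5 * x)
    assert scaled.rho == pytest.approx(1.0)
    assert scaled.slope == pytest.approx(0.5)


def test_independent_eval_covariances_uncorrelated(small_potts):
    """Sequences from a site-independent model carry no covariance signal, so
    rho against a coupled target is ~0."""
    _, dist = small_potts
    target = dist.sample(20_000, seed=3)
    ind = IndepModel(dist.univariate(), reduced_alphabet(3))
    ev = sample_indep(ind, 20_000, seed=4)
    r = covariance_correlation(ev, target)
    assert abs(r.rho) < 0.1


# ---------------------------------------------------------------------------
# r20


def test_r20_identity_is_one(small_potts):
    _, dist = small_potts
    msa = dist.sample(3000, seed=5)
    res = r20(msa, msa, word_lengths=(2, 3, 4), n_sets=20, seed=1)
    assert res.mean_scores == pytest.approx([1.0, 1.0, 1.0])


def test_r20_scores_bounded_and_mean_consistent(small_potts):
    _, dist = small_potts
    a, b = dist.sample(2000, seed=6), dist.sample(2000, seed=7)
    res = r20(a, b, word_lengths=(2, 3), n_sets=10, seed=2)
    for n_scores, mean in zip(res.per_set_scores, res.mean_scores):
        assert all(-1.0 <= s <= 1.0 for s in n_scores)
        assert mean == pytest.approx(np.mean(n_scores))


def test_r20_degenerate_tied_target_frequencies_skipped():
    """Spec toy: all top target words equally frequent -> zero variance ->
    the position set is skipped and counted."""
    ab = Alphabet("AB")
    target = MSA.from_sequences(["AB", "BA"] * 10, ab)
    ev = MSA.from_sequences(["AB"] * 8 + ["BA"] * 8 + ["AA", "AA", "BB", "BB"], ab)
    res = r20(target, ev, word_lengths=(2,), n_sets=5, seed=0)
    assert res.n_skipped[0] == 1  # the single (0,1) set
    assert np.isnan(res.mean_scores[0])


def test_indep_r20_below_potts_ordering(small_potts):
    """Coupled-target comparison: an independent fit scores below the
    self-comparison at n >= 2 (word frequencies mis-predicted)."""
    _, dist = small_potts
    target = dist.sample(30_000, seed=8)
    ind = IndepModel(dist.univariate(), reduced_alphabet(3))
    ind_eval = sample_indep(ind, 30_000, seed=9)
    self_eval = dist.sample(30_000, seed=10)
    lengths = (2, 3, 4)
    res_ind = r20(target, ind_eval, lengths, n_sets=10, seed=3)
    res_self = r20(target, self_eval, lengths, n_sets=10, seed=3)
    for ind_s, self_s in zip(res_ind.mean_scores, res_self.mean_scores):
        assert ind_s < self_s


# ---------------------------------------------------------------------------
# connected correlations


def test_connected_correlation_order_two_reduces_to_covariance():
    msa = random_msa(300, 5, 3, 11)
    from gpsmcap.stats import covariances, pair_index

    C = covariances(msa)
    got = connected_correlation(msa, (1, 3), (2, 0))
    assert got == pytest.approx(C[pair_index(1, 3, 5), 2, 0], abs=1e-12)


def test_connected_correlation_zero_for_independent_distribution():
    """Any site-independent distribution has exactly zero connected
    correlations at every order >= 2."""
    rng = np.random.default_rng(1)
    f = rng.dirichlet(np.ones(3), size=4)
    dist = IndepModel(f, reduced_alphabet(3)).enumerate_distribution()
    worst = 0.0
    for positions, letters in [((0, 1), (2, 1)), ((0, 1, 2), (1, 0, 2)),
                               ((0, 1, 2, 3), (0, 0, 1, 2))]:
        worst = max(worst, abs(connected_correlation(dist, positions, letters)))
    assert worst < 1e-12


def test_parity_three_point_connected_correlation_hand_value():
    """XOR distribution (s3 = s1 ^ s2, uniform bits): the 3-point connected
    correlation at letters (1,1,0) is 0.25 - 3*(0.25*0.5) + 2*(0.5)^3."""
    dist = parity_target(2)
    got = connected_correlation(dist, (0, 1, 2), (1, 1, 0))
    assert got == pytest.approx(0.125, abs=1e-12)


def test_connected_correlation_argument_validation(small_potts):
    _, dist = small_potts
    with pytest.raises(ValueError):
        connected_correlation(dist, (0, 1), (1,))
    with pytest.raises(ValueError):
        connected_correlation(dist, (0,), (1,))


# ---------------------------------------------------------------------------
# cc-r20


def test_cc_r20_identity_is_one(small_potts):
    _, dist = small_potts
    msa = dist.sample(4000, seed=12)
    res = cc_r20(msa, msa, word_lengths=(2, 3), n_sets=8, seed=4)
    for m in res.mean_scores:
        assert m == pytest.approx(1.0)


def test_cc_r20_independent_eval_scores_near_zero(small_potts):
    """The eval connected correlations of an independent model are pure
    sampling noise around 0, so cc-r20 against a coupled target is ~0."""
    _, dist = small_potts
    target = dist.sample(50_000, seed=13)
    ind = IndepModel(dist.univariate(), reduced_alphabet(3))
    ev = sample_indep(ind, 50_000, seed=14)
    res = cc_r20(target, ev, word_lengths=(2, 3), n_sets=10, seed=5)
    assert abs(res.mean_scores[0]) < 0.25
    assert abs(res.mean_scores[1]) < 0.25


# ---------------------------------------------------------------------------
# TVD


def test_tvd_identical_and_disjoint():
    a = np.zeros(12)
    a[5] = 1.0
    b = np.zeros(12)
    b[10] = 1.0
    assert tvd(a, a) == 0.0
    assert tvd(a, b) == 1.0


def test_tvd_hand_value():
    assert tvd([0.5, 0.5, 0.0], [0.5, 0.0, 0.5]) == pytest.approx(0.5)


def test_tvd_rejects_unnormalized_or_mismatched():
    with pytest.raises(ValueError):
        tvd([0.5, 0.4], [0.5, 0.5])
    with pytest.raises(ValueError):
        tvd([1.0], [0.5, 0.5])


# ---------------------------------------------------------------------------
# log-log rescaling


def test_loglog_rescale_toy_histogram():
    t = loglog_rescale(np.array([0.1, 0.6, 0.3]), distances=np.array([1, 2, 3]))
    assert t.mode_distance == 2
    assert t.right[0].tolist() == [1.5]
    assert t.right[1][0] == pytest.approx(0.5)
    assert t.left[0].tolist() == [0.5]
    assert t.left[1][0] == pytest.approx(0.1 / 0.6)


def test_loglog_rescale_preserves_frequency_ordering():
    hist = np.array([0.0, 0.05, 0.2, 0.4, 0.25, 0.1])
    t = loglog_rescale(hist)
    assert (np.diff(t.left[1]) > 0).all()  # rising toward the mode
    assert (np.diff(t.right[1]) < 0).all()  # falling after the mode


# ---------------------------------------------------------------------------
# energy correlation


def test_energy_correlation_identity_and_shift_invariance():
    rng = np.random.default_rng(2)
    e = rng.normal(size=100)
    assert energy_correlation(e, e).rho == pytest.approx(1.0)
    assert energy_correlation(e + 11.0, e).rho == pytest.approx(1.0)


def test_energy_correlation_potts_beats_indep_on_coupled_target(small_potts):
    """Fig-5-style ordering on an enumerable target: a refit Potts model
    correlates better with the true energies than the independent model."""
    from gpsmcap.indep import fit_indep, indep_energy
    from gpsmcap.potts import fit_potts, potts_energy

    model, dist = small_potts
    train = dist.sample(30_000, seed=15)
    test = dist.sample(1000, seed=16)
    e_true = dist.neg_log_prob(test)
    potts_fit = fit_potts(train, max_iters=150)
    ind_fit = fit_indep(train)
    r_potts = energy_correlation(potts_energy(potts_fit, test), e_true).rho
    r_ind = energy_correlation(indep_energy(ind_fit, test), e_true).rho
    assert r_potts > r_ind
    assert r_potts > 0.95


# ---------------------------------------------------------------------------
# estimation bound


def test_estimation_bound_rejects_identical_seeds(small_potts):
    _, dist = small_potts
    with pytest.raises(ValueError):
        estimation_bound(dist.sample, 100, 100, covariance_correlation, 3, 3)


def test_estimation_bound_decreases_with_word_length(small_potts):
    """Rarer words at higher n mean more sampling noise, so the
    self-comparison ceiling at n=4 sits below the one at n=2
    (averaged over independent seed pairs)."""
    _, dist = small_potts
    lows, highs = [], []
    for s in range(5):
        res = estimation_bound(
            dist.sample, 1500, 1500,
            lambda a, b: r20(a, b, (2, 4), n_sets=10, seed=9),
            seed_a=100 + s, seed_b=200 + s,
        )
        highs.append(res.mean_scores[0])
        lows.append(res.mean_scores[1])
    assert np.mean(lows) < np.mean(highs)
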