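"""Potts model: energies, gauge, enumeration oracle, Gibbs sampling,
inverse-Ising inference and triplet injection."""

import numpy as np
import pytest

from gpsmcap import (
    MSA,
    Alphabet,
    McmcSettings,
    PottsModel,
    bivariate_marginals,
    enumerate_distribution,
    fit_potts,
    indep_param_count,
    inject_triplet,
    mcmc_sample,
    num_free_params,
    potts_energy,
    univariate_marginals,
)
from gpsmcap.alphabet import reduced_alphabet
from gpsmcap.bench import random_potts
from gpsmcap.errors import SizeError
from gpsmcap.metrics import connected_correlation
from gpsmcap.potts import fit_potts_to_marginals

AB = Alphabet("AB")


# ---------------------------------------------------------------------------
# energies


def test_zero_model_energy_is_zero():
    model = PottsModel.zeros(3, 2, AB)
    msa = MSA.from_sequences(["AAB", "BBB"], AB)
    assert np.allclose(potts_energy(model, msa), 0.0)


def test_single_coupling_hand_example():
    model = PottsModel.zeros(2, 2, AB)
    model.J[0, 0, 0] = -1.0
    msa = MSA.from_sequences(["AA", "AB", "BA", "BB"], AB)
    assert potts_energy(model, msa).tolist() == [-1.0, 0.0, 0.0, 0.0]


def test_triplet_energy_additivity():
    model = PottsModel.zeros(4, 2, AB)
    _, trip = inject_triplet(model, (0, 1, 3), strength=-2.0, pattern=(1, 1, 0))
    msa = MSA.from_sequences(["BBAA", "BBAB", "ABAA"], AB)
    base = potts_energy(model, msa)
    aug = potts_energy(model, msa, trip)
    assert (aug - base).tolist() == [-2.0, 0.0, 0.0]


def test_gauge_transformation_preserves_probability_ratios():
    """Shifting J^{01}_{a.} by c and h^0_a by -c leaves p(S)/p(S') unchanged
    (exhaustive check on L=3, q=2)."""
    model = random_potts(3, 2, 1.0, 0.7, 0.4, seed=5)
    shifted = PottsModel(model.h.copy(), model.J.copy(), model.alphabet)
    c = 0.9
    shifted.J[0, 0, :] += c  # pair (0,1), first letter A: all second letters
    shifted.h[0, 0] -= c
    p1 = enumerate_distribution(model).probs
    p2 = enumerate_distribution(shifted).probs
    assert np.allclose(p1, p2, atol=1e-12)


def test_zero_sum_gauge_preserves_distribution():
    model = random_potts(4, 3, 0.6, 0.8, 0.3, seed=2)
    gauged = model.to_zero_sum_gauge()
    p1 = enumerate_distribution(model).probs
    p2 = enumerate_distribution(gauged).probs
    assert np.allclose(p1, p2, atol=1e-10)
    for block in gauged.J:
        assert np.allclose(block.sum(axis=0), 0.0, atol=1e-9)
        assert np.allclose(block.sum(axis=1), 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# enumeration oracle


def test_zero_model_enumerates_to_uniform():
    dist = enumerate_distribution(PottsModel.zeros(3, 2, AB))
    assert np.allclose(dist.probs, 1 / 8)


def test_enumeration_normalization_and_marginal_consistency():
    model = random_potts(4, 3, 0.5, 0.6, 0.2, seed=8)
    dist = enumerate_distribution(model)
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
    # two-path: bivariate via bincount vs direct summation over the table
    bi = dist.bivariate()
    direct = np.zeros_like(bi[0])
    for k, s in enumerate(dist.seqs):
        direct[s[0], s[2]] += dist.probs[k]
    from gpsmcap.stats import pair_index

    assert np.allclose(bi[pair_index(0, 2, 4)], direct, atol=1e-12)


def test_enumeration_size_cap():
    with pytest.raises(SizeError):
        enumerate_distribution(PottsModel.zeros(30, 5))


# ---------------------------------------------------------------------------
# parameter counts


@pytest.mark.parametrize(
    "L,q,expected",
    [(2, 2, 3), (1, 4, 3), (232, 21, 10_723_040)],
)
def test_num_free_params(L, q, expected):
    assert num_free_params(L, q) == expected


def test_num_free_params_matches_joint_dof():
    """(L=2, q=2): a 2x2 joint distribution has 3 degrees of freedom."""
    # brute force: dimension of the space of 2x2 tables summing to 1
    assert num_free_params(2, 2) == 2 * 2 - 1


@pytest.mark.parametrize("L,q,expected", [(232, 21, 4640), (1, 2, 1), (5, 1, 0)])
def test_indep_param_count(L, q, expected):
    assert indep_param_count(L, q) == expected


# ---------------------------------------------------------------------------
# Gibbs sampling


def test_mcmc_deterministic_under_seed(small_potts):
    model, _ = small_potts
    settings = McmcSettings(n_chains=16, burn_in_sweeps=20, thin_sweeps=2, seed=4)
    a = mcmc_sample(model, 50, settings)
    b = mcmc_sample(model, 50, settings)
    assert np.array_equal(a.data, b.data)


def test_mcmc_zero_model_uniform_marginals():
    model = PottsModel.zeros(4, 3)
    settings = McmcSettings(n_chains=500, burn_in_sweeps=30, thin_sweeps=2, seed=1)
    msa = mcmc_sample(model, 20_000, settings)
    f = univariate_marginals(msa, 0.0).uni
    sigma = np.sqrt((1 / 3) * (2 / 3) / msa.N)
    assert np.abs(f - 1 / 3).max() < 4 * sigma


def test_mcmc_marginals_match_enumeration(small_potts):
    """1- and 2-point Gibbs marginals agree with the exact table (4 sigma)."""
    model, dist = small_potts
    settings = McmcSettings(n_chains=1000, burn_in_sweeps=100, thin_sweeps=5, seed=3)
    msa = mcmc_sample(model, 40_000, settings)
    f1, f2 = dist.univariate(), dist.bivariate()
    e1 = univariate_marginals(msa, 0.0).uni
    e2 = bivariate_marginals(msa, 0.0).bi
    s1 = np.sqrt(f1 * (1 - f1) / msa.N)
    s2 = np.sqrt(f2 * (1 - f2) / msa.N)
    assert (np.abs(e1 - f1) <= 4 * s1 + 1e-9).all()
    assert (np.abs(e2 - f2) <= 4.5 * s2 + 1e-9).all()


# ---------------------------------------------------------------------------
# inference


def test_fit_fixed_point_on_exact_marginals(small_potts):
    """Moment matching: fitting to the exact bivariate marginals of an
    enumerable target recovers those marginals."""
    model, dist = small_potts
    fit = fit_potts_to_marginals(
        dist.univariate(),
        dist.bivariate(),
        model.alphabet,
        scad_lambda=0.0,
        tol=1e-5,
        max_iters=400,
    )
    fdist = enumerate_distribution(fit)
    assert np.abs(fdist.bivariate() - dist.bivariate()).max() < 1e-4


def test_fit_reaches_reported_tolerance(small_potts):
    model, dist = small_potts
    train = dist.sample(20_000, seed=6)
    fit = fit_potts(train, max_iters=200)
    fr = fit.fit_report
    assert fr.converged
    assert fr.final_discrepancy < 1.0 / np.sqrt(train.N)


def test_scad_drives_couplings_to_zero_on_independent_data():
    """Data from an independent model: SCAD-penalized couplings end smaller
    than unpenalized ones."""
    rng = np.random.default_rng(9)
    from gpsmcap.indep import IndepModel, sample_indep

    f = rng.dirichlet(np.ones(3) * 3, size=4)
    train = sample_indep(IndepModel(f, reduced_alphabet(3)), 5_000, seed=3)
    free = fit_potts(train, scad_lambda=0.0, max_iters=100, tol=1e-6)
    pen = fit_potts(train, scad_lambda=0.1, max_iters=100, tol=1e-6)
    J_free = np.abs(free.to_zero_sum_gauge().J)
    J_pen = np.abs(pen.to_zero_sum_gauge().J)
    assert J_pen.max() < J_free.max()
    assert J_pen.mean() < 0.5 * J_free.mean()


def test_fit_nonconvergence_is_flagged(small_potts):
    model, dist = small_potts
    train = dist.sample(5_000, seed=8)
    fit = fit_potts(train, max_iters=2, tol=1e-9)
    assert fit.fit_report.converged is False
    assert fit.fit_report.iterations == 2


# ---------------------------------------------------------------------------
# triplet injection


def test_inject_triplet_zero_strength_is_identity(small_potts):
    model, dist = small_potts
    _, trip = inject_triplet(model, (0, 2, 4), strength=0.0, pattern=(1, 1, 0))
    aug = enumerate_distribution(model, trip)
    assert np.allclose(aug.probs, dist.probs, atol=1e-12)


def test_inject_triplet_creates_three_point_structure():
    """A single K entry at (0,1,2) on a fields-only (site-independent) base
    turns the 3-point connected correlation there from exactly 0 to the
    closed-form value computed from the eight triple-cell weights."""
    base = random_potts(5, 2, coupling_density=0.0, coupling_scale=0.0,
                        field_scale=0.1, seed=12)
    strength = -2.0
    _, trip = inject_triplet(base, (0, 1, 2), strength=strength, pattern=(1, 1, 1))
    d_base = enumerate_distribution(base)
    d_aug = enumerate_distribution(base, trip)
    assert connected_correlation(d_base, (0, 1, 2), (1, 1, 1)) == pytest.approx(
        0.0, abs=1e-12
    )
    # independent oracle: reweight the 2x2x2 cell table of the independent
    # triple by exp(-strength) on cell (1,1,1) and take the third cumulant
    f = np.exp(-base.h) / np.exp(-base.h).sum(axis=1, keepdims=True)
    cells = np.einsum("a,b,c->abc", f[0], f[1], f[2])
    cells[1, 1, 1] *= np.exp(-strength)
    cells /= cells.sum()
    f111 = cells[1, 1, 1]
    f12, f13, f23 = cells[1, 1, :].sum(), cells[1, :, 1].sum(), cells[:, 1, 1].sum()
    f1, f2, f3 = cells[1].sum(), cells[:, 1, :].sum(), cells[..., 1].sum()
    expected = f111 - f12 * f3 - f13 * f2 - f23 * f1 + 2 * f1 * f2 * f3
    got = connected_correlation(d_aug, (0, 1, 2), (1, 1, 1))
    assert got == pytest.approx(expected, abs=1e-10)
    assert abs(got) > 1e-3


def test_inject_triplet_duplicate_positions_rejected(small_potts):
    model, _ = small_potts
    with pytest.raises(ValueError):
        inject_triplet(model, (1, 1, 2), strength=1.0, pattern=(0, 0, 0))


# ---------------------------------------------------------------------------
# persistence


def test_save_load_roundtrip(tmp_path, small_potts):
    model, _ = small_potts
    p = tmp_path / "potts.npz"
    model.save(p)
    back = PottsModel.load(p)
    assert np.array_equal(back.h, model.h)
    assert np.array_equal(back.J, model.J)
    assert back.alphabet.symbols == model.alphabet.symbols
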