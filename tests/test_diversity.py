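"""Weir-Cockerham theta, per-site diversity and genic G-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radpopgen.diversity import (
    genic_test,
    pairwise_theta,
    site_diversity,
    theta_bootstrap_ci,
    wc_theta,
)
from radpopgen.genotypes import MISSING
from radpopgen.synthetic import generate_balding_nichols

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent WC84 oracle: direct loop transcription of the estimator
# ---------------------------------------------------------------------------

def wc84_oracle(pop_columns):
    """a, b, c for one locus from per-population genotype lists (may contain
    MISSING).  Straight transcription with scalar arithmetic."""
    ns, ps, hs = [], [], []
    for col in pop_columns:
        col = [g for g in col if g != MISSING]
        if not col:
            continue
        n = len(col)
        ns.append(n)
        ps.append(sum(col) / (2 * n))
        hs.append(sum(1 for g in col if g == 1) / n)
    r = len(ns)
    if r < 2:
        return 0.0, 0.0, 0.0
    nbar = sum(ns) / r
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    if pbar <= 0 or pbar >= 1:
        return 0.0, 0.0, 0.0
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc84_oracle_theta(geno, labels):
    groups = sorted(set(labels))
    A = B = C = 0.0
    for j in range(geno.shape[1]):
        cols = [geno[np.array(labels) == g, j].tolist() for g in groups]
        a, b, c = wc84_oracle(cols)
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


def test_wc_theta_matches_oracle_on_random_instances():
    rng = np.random.default_rng(77)
    for _ in range(200):
        n_pops = rng.integers(2, 5)
        sizes = rng.integers(3, 12, n_pops)
        L = int(rng.integers(2, 8))
        labels = np.repeat([f"p{k}" for k in range(n_pops)], sizes)
        geno = rng.integers(0, 3, size=(sizes.sum(), L)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.1] = MISSING
        G = make_matrix(geno, list(labels))
        try:
            impl = wc_theta(G, labels).theta
        except ValueError:
            continue  # no usable polymorphic locus; oracle agrees trivially
        oracle = wc84_oracle_theta(geno, labels)
        assert impl == pytest.approx(oracle, abs=1e-12)


def test_theta_fixed_difference_is_one():
    G = make_matrix([[0], [0], [0], [2], [2], [2]], ["P1"] * 3 + ["P2"] * 3)
    assert wc_theta(G).theta == pytest.approx(1.0)


def test_theta_identical_populations_near_zero():
    rng = np.random.default_rng(3)
    col = rng.binomial(2, 0.5, 30).astype(np.int8)
    geno = np.tile(col[:, None], (2, 5))  # two pops, identical columns
    G = make_matrix(geno, ["P1"] * 30 + ["P2"] * 30)
    th = wc_theta(G).theta
    assert th <= 0 or abs(th) < 0.01


def test_theta_toy_instance_equals_oracle(two_pop_toy):
    labels = list(two_pop_toy.site_codes)
    assert wc_theta(two_pop_toy).theta == pytest.approx(
        wc84_oracle_theta(two_pop_toy.genotypes, labels), abs=1e-12
    )


def test_theta_invariant_to_locus_and_individual_order(bn_small):
    G, _ = bn_small
    rng = np.random.default_rng(8)
    base = wc_theta(G).theta
    assert wc_theta(G.take_loci(rng.permutation(G.n_loci))).theta == pytest.approx(base)
    assert wc_theta(G.take_samples(rng.permutation(G.n_samples))).theta == pytest.approx(base)


def test_theta_monomorphic_only_errors():
    G = make_matrix([[0], [0], [0], [0]], ["P1"] * 2 + ["P2"] * 2)
    with pytest.raises(ValueError, match="monomorphic|polymorphic"):
        wc_theta(G)


def test_bn_recovery_bias_within_ten_percent():
    thetas = []
    for seed in range(5):
        G, _ = generate_balding_nichols(
            K_sites=2, n_per_site=40, L=2000, F_per_site=0.01, seed=seed
        )
        thetas.append(wc_theta(G).theta)
    assert abs(np.mean(thetas) - 0.01) < 0.1 * 0.01


def test_pairwise_theta_symmetric_and_permutation_invariant(bn_small):
    G, _ = bn_small
    pw = pairwise_theta(G)
    m = pw.theta
    assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
    rng = np.random.default_rng(4)
    pw2 = pairwise_theta(G.take_samples(rng.permutation(G.n_samples)))
    pd.testing.assert_frame_equal(
        m.sort_index().sort_index(axis=1),
        pw2.theta.sort_index().sort_index(axis=1),
    )


# ---------------------------------------------------------------------------
# Bootstrap CI
# ---------------------------------------------------------------------------

def test_bootstrap_ci_deterministic_and_degenerate(two_pop_toy):
    res = wc_theta(two_pop_toy)
    ci1 = theta_bootstrap_ci(res, n_boot=200, seed=5)
    ci2 = theta_bootstrap_ci(res, n_boot=200, seed=5)
    assert ci1 == ci2
    # identical components at every locus -> zero-width CI at theta
    res.a[:] = 0.01
    res.b[:] = 0.02
    res.c[:] = 0.03
    lo, hi = theta_bootstrap_ci(res, n_boot=100, seed=1)
    assert lo == pytest.approx(res.theta) and hi == pytest.approx(res.theta)


def test_bootstrap_ci_covers_generator_truth():
    hits = 0
    for seed in range(20):
        G, _ = generate_balding_nichols(
            K_sites=2, n_per_site=30, L=500, F_per_site=0.01, seed=100 + seed
        )
        res = wc_theta(G)
        lo, hi = theta_bootstrap_ci(res, n_boot=300, seed=seed)
        if lo <= 0.01 <= hi:
            hits += 1
    assert hits >= 18  # nominal 95%; allow Monte-Carlo slack


# ---------------------------------------------------------------------------
# Site diversity
# ---------------------------------------------------------------------------

def test_all_het_locus_negative_fis():
    G = make_matrix([[1], [1], [1], [1]], ["X"] * 4)
    div = site_diversity(G).table
    assert div.loc["X", "Ho"] == pytest.approx(1.0)
    assert div.loc["X", "Fis"] < 0


def test_monomorphic_locus_zero_heterozygosity():
    G = make_matrix([[0], [0], [0]], ["X"] * 3)
    div = site_diversity(G).table
    assert div.loc["X", "He"] == 0.0
    assert div.loc["X", "Ho"] == 0.0
    assert div.loc["X", "Sp"] == 0.0


def test_he_matches_unbiased_expectation(bn_small):
    G, manifest = bn_small
    div = site_diversity(G).table
    for site in div.index:
        p = np.array(manifest.site_freqs[site])
        n = (np.array(G.site_codes) == site).sum()
        expect = np.mean(2 * p * (1 - p)) * (2 * n / (2 * n - 1))
        # He averages over sampled frequencies; allow 3 SE of the locus mean
        se = np.std(2 * p * (1 - p)) / np.sqrt(len(p))
        assert abs(div.loc[site, "He"] - expect) < 3 * se + 0.01


# ---------------------------------------------------------------------------
# Genic G-tests
# ---------------------------------------------------------------------------

def test_genic_identical_counts_null():
    G = make_matrix([[1], [1], [1], [1]], ["P1"] * 2 + ["P2"] * 2)
    res = genic_test(G, ("P1", "P2"), n_perm=200, seed=0)
    assert res.per_locus["G"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert res.per_locus["p"].iloc[0] == 1.0


def test_genic_fixed_difference_hand_oracle():
    # pop1 alleles 30 alt / 0 ref, pop2 0 alt / 30 ref
    G = make_matrix(
        np.array([[2]] * 15 + [[0]] * 15, dtype=np.int8),
        ["P1"] * 15 + ["P2"] * 15,
    )
    res = genic_test(G, ("P1", "P2"), n_perm=999, seed=1)
    # hand-computed G = 2 * sum O ln(O/E); E = 15 in every cell
    g_hand = 2 * (30 * np.log(30 / 15.0) + 30 * np.log(30 / 15.0))
    assert res.per_locus["G"].iloc[0] == pytest.approx(g_hand, rel=1e-9)
    assert res.per_locus["p"].iloc[0] <= 2.0 / 1000.0


def test_genic_null_pvalues_roughly_uniform():
    # exchangeable data: per-locus p should be near-uniform
    rng = np.random.default_rng(50)
    pvals = []
    for seed in range(3):
        geno = rng.binomial(2, rng.uniform(0.2, 0.8, 150), size=(60, 150)).astype(np.int8)
        G = make_matrix(geno, ["P1"] * 30 + ["P2"] * 30)
        res = genic_test(G, ("P1", "P2"), n_perm=199, seed=seed)
        pvals.extend(res.per_locus["p"].tolist())
    pvals = np.array(pvals)
    # tie-inclusive permutation p-values are valid but conservative:
    # P(p <= alpha) <= alpha (approximately), and p is not degenerate
    assert np.mean(pvals <= 0.05) <= 0.08
    assert np.mean(pvals <= 0.10) <= 0.14
    assert 0.45 < pvals.mean() < 0.70
    assert np.mean(pvals >= 0.9) < 0.35


def test_genic_zero_call_group_excluded():
    geno = np.array([[1, MISSING], [1, MISSING], [1, 0], [1, 2]], dtype=np.int8)
    G = make_matrix(geno, ["P1"] * 2 + ["P2"] * 2)
    res = genic_test(G, ("P1", "P2"), n_perm=50, seed=0)
    assert res.n_excluded == 1
    assert len(res.per_locus) == 1


def test_fisher_combination_chi_square_null():
    # -2 sum(ln p) ~ chi2(2k) for uniform p
    rng = np.random.default_rng(9)
    k = 200
    sims = np.array([-2 * np.log(rng.random(k)).sum() for _ in range(500)])
    assert stats.kstest(sims, "chi2", args=(2 * k,)).pvalue > 0.01
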