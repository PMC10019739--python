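"""Filter cascade, HWE screening and replicate-based error estimation."""

import numpy as np
import pytest
from scipy import stats

from radpopgen.genotypes import MISSING
from radpopgen.qc import (
    FilterReport,
    filter_individuals,
    filter_snps,
    genotyping_error,
    hwe_exact_test,
    hwe_filter,
    select_snp_per_tag,
)
from radpopgen.synthetic import generate_balding_nichols, inject_artifacts

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Locus / individual filters
# ---------------------------------------------------------------------------

def _maf_column(maf, n=50):
    """Dosage column with exact minor allele count 2*n*maf (alt minor)."""
    alt = int(round(2 * n * maf))
    col = [0] * n
    for i in range(alt // 2):
        col[i] = 2
    if alt % 2:
        col[alt // 2] = 1
    return col


def test_maf_threshold_inclusive():
    n = 50
    rows = np.array([_maf_column(0.04, n), _maf_column(0.05, n)], dtype=np.int8).T
    G = make_matrix(rows, ["X"] * n)
    G2, rep = filter_snps(G)
    assert G2.locus_ids == ["L1"]  # 0.05 kept, 0.04 dropped
    assert rep.dropped_loci["L0"] == "min_maf"


def test_locus_missingness_strictly_greater():
    n = 100
    base = _maf_column(0.3, n)
    col_31 = list(base)
    col_30 = list(base)
    for i in range(31):
        col_31[-(i + 1)] = MISSING
    for i in range(30):
        col_30[-(i + 1)] = MISSING
    G = make_matrix(np.array([col_31, col_30], dtype=np.int8).T, ["X"] * n)
    G2, rep = filter_snps(G)
    assert rep.dropped_loci == {"L0": "max_locus_missing"}
    assert G2.locus_ids == ["L1"]


def test_individual_missingness_boundary():
    # 30.0% missing kept ("more than 30%" removed); 100% missing dropped
    L = 10
    rows = [[1] * L, [1] * 7 + [MISSING] * 3, [MISSING] * L]
    G = make_matrix(np.array(rows, dtype=np.int8), ["X"] * 3)
    G2, rep = filter_individuals(G)
    assert G2.sample_ids == ["ind0", "ind1"]
    assert rep.dropped_individuals == {"ind2": "max_ind_missing"}


def test_planted_violations_counted_exactly():
    G, _ = generate_balding_nichols(K_sites=2, n_per_site=30, L=200, seed=7)
    G, manifest = inject_artifacts(
        G, seed=8, missing_individuals=["S01_ind000", "S01_ind001"],
        individual_missing_rate=0.5,
    )
    G1, _ = filter_snps(G)
    G2, rep = filter_individuals(G1)
    assert set(rep.dropped_individuals) == set(manifest.planted["missing_individuals"])


def test_filter_cascade_idempotent():
    G, _ = generate_balding_nichols(K_sites=3, n_per_site=25, L=300, seed=9)
    G, _ = inject_artifacts(G, missing_rate=0.05, seed=10)
    G1, _ = filter_snps(G)
    G1, _ = filter_individuals(G1)
    G2, rep2 = filter_snps(G1)
    G2, rep2b = filter_individuals(G2)
    assert G2 == G1
    assert not rep2.dropped_loci and not rep2b.dropped_individuals


def test_select_snp_per_tag_matches_brute_force():
    rng = np.random.default_rng(12)
    n, L = 40, 60
    geno = rng.binomial(2, rng.uniform(0.05, 0.5, L), size=(n, L)).astype(np.int8)
    tags = [f"tag{j % 17}" for j in range(L)]
    G = make_matrix(geno, ["X"] * n, tags=tags, positions=list(rng.integers(1, 1000, L)))
    G2, _ = select_snp_per_tag(G)

    # naive per-tag scan
    p = geno.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    expected = {}
    for j, l in enumerate(G.loci):
        key = l.tag_id
        cand = (-maf[j], l.position, l.locus_id)
        if key not in expected or cand < expected[key][0]:
            expected[key] = (cand, l.locus_id)
    assert set(G2.locus_ids) == {v[1] for v in expected.values()}
    assert len(G2.locus_ids) == len({l.tag_id for l in G.loci})


def test_per_tag_tiebreak_smallest_position():
    rows = [[1, 1], [1, 1], [0, 0], [2, 2]]  # equal MAF at both loci
    G = make_matrix(
        np.array(rows, dtype=np.int8), ["X"] * 4,
        tags=["t", "t"], positions=[40, 12],
    )
    G2, _ = select_snp_per_tag(G)
    assert [l.position for l in G2.loci] == [12]


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact test: enumerate all genotype tables with the same
    allele counts and sum multinomial-style probabilities <= observed."""
    from math import comb

    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # alt alleles
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - het) // 2
        AA = n - het - aa
        if AA < 0:
            continue
        # P(het | allele counts) ∝ n! / (AA! het! aa!) * 2^het
        probs[het] = comb(n, het) * comb(n - het, aa) * 2 ** het
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (5, 0, 5), (3, 7, 2), (10, 2, 10), (1, 1, 1), (0, 5, 0), (12, 0, 1)],
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        _hwe_enumeration_oracle(*counts), abs=1e-9
    )


def test_hwe_modal_table_p_one():
    # (25, 50, 25) is the modal outcome; every table is included
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)


def test_hwe_monomorphic_convention():
    assert hwe_exact_test(17, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 9) == 1.0


def test_hwe_probabilities_sum_to_one():
    # internal null distribution is a proper distribution
    from math import comb

    for n_AA, n_Aa, n_aa in [(30, 40, 30), (7, 3, 1)]:
        n = n_AA + n_Aa + n_aa
        n_a = 2 * n_aa + n_Aa
        total = 0.0
        probs = {}
        for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
            aa = (n_a - het) // 2
            probs[het] = comb(n, het) * comb(n - het, aa) * 2 ** het
        z = sum(probs.values())
        assert sum(v / z for v in probs.values()) == pytest.approx(1.0, abs=1e-12)


def test_hwe_negative_counts_rejected():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# HWE screen
# ---------------------------------------------------------------------------

def _matrix_with_hwe_violator(seed):
    """2 sites in HWE everywhere except locus 0, which is all-het in both."""
    rng = np.random.default_rng(seed)
    n, L = 40, 30
    p = rng.uniform(0.2, 0.8, L)
    geno = rng.binomial(2, p, size=(2 * n, L)).astype(np.int8)
    geno[:, 0] = 1  # grossly out of HWE in both sites
    return make_matrix(geno, ["A"] * n + ["B"] * n)


def test_hwe_filter_drop_rule():
    G = _matrix_with_hwe_violator(21)
    G2, res = hwe_filter(G)
    assert res.n_sites_failing["L0"] >= 2
    assert "L0" not in G2.locus_ids
    # q-values are BH-adjusted: q >= p wherever both defined
    mask = res.p.notna() & res.q.notna()
    assert (res.q[mask] >= res.p[mask] - 1e-12).all().all()


def test_hwe_filter_single_site_failure_kept():
    rng = np.random.default_rng(22)
    n, L = 40, 30
    p = rng.uniform(0.2, 0.8, L)
    geno = rng.binomial(2, p, size=(2 * n, L)).astype(np.int8)
    geno[:n, 0] = 1       # all-het in site A only
    geno[n:, 0] = rng.binomial(2, 0.5, n)
    G = make_matrix(geno, ["A"] * n + ["B"] * n)
    G2, res = hwe_filter(G)
    assert res.n_sites_failing["L0"] <= 1
    assert "L0" in G2.locus_ids


def test_hwe_filter_null_drops_nothing():
    # data simulated under exact HWE: BH control -> 0 expected drops
    dropped = 0
    for seed in (31, 32):
        G, _ = generate_balding_nichols(
            K_sites=9, n_per_site=30, L=2000, F_per_site=0.005, seed=seed
        )
        _, res = hwe_filter(G)
        dropped += int((~res.keep).sum())
    assert dropped == 0


# ---------------------------------------------------------------------------
# Genotyping error
# ---------------------------------------------------------------------------

def test_error_identical_replicates_zero():
    G = make_matrix([[0, 1, 2], [0, 1, 2]], ["X", "X"])
    est = genotyping_error(G, [("ind0", "ind1")])
    assert est.rate == 0.0
    assert est.n_comparisons == 3


def test_error_rate_definition_and_symmetry():
    rng = np.random.default_rng(5)
    col = rng.binomial(2, 0.5, 100).astype(np.int8)
    col2 = col.copy()
    col2[[3, 50]] = (col2[[3, 50]] + 1) % 3  # 2 discordant of 100
    G = make_matrix(np.stack([col, col2]), ["X", "X"])
    est = genotyping_error(G, [("ind0", "ind1")])
    assert est.rate == pytest.approx(0.02)
    est_rev = genotyping_error(G, [("ind1", "ind0")])
    assert est_rev.rate == est.rate


def test_error_ignores_jointly_missing_cells():
    G = make_matrix([[0, MISSING, 2], [0, 1, MISSING]], ["X", "X"])
    est = genotyping_error(G, [("ind0", "ind1")])
    assert est.n_comparisons == 1  # only locus 0 called in both


def test_injected_error_recovered_within_binomial_band():
    from radpopgen.synthetic import expected_replicate_discordance

    e = 0.01
    G, _ = generate_balding_nichols(K_sites=1, n_per_site=20, L=2000,
                                    F_per_site=0.0, seed=41)
    G2, manifest = inject_artifacts(G, allele_error_rate=e,
                                    n_replicate_pairs=10, seed=42)
    est = genotyping_error(G2, manifest.replicate_pairs)
    # het-cell expectation brackets the genotype mix; allow 3 binomial SD
    # around the analytic heterozygote value plus the hom-cell lower bound
    p_het = expected_replicate_discordance(e)
    p_lo = 0.5 * p_het  # extreme all-homozygote limit is ~half the het value
    sd = np.sqrt(p_het * (1 - p_het) / est.n_comparisons)
    assert p_lo - 3 * sd < est.rate < p_het + 3 * sd
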