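"""Per-site diversity summaries, Weir-Cockerham theta, and genic
differentiation G-tests.

The multi-locus FST estimator is the Weir & Cockerham (1984) ratio of sums:
per-locus variance components a (among populations), b (among individuals
within populations) and c (within individuals) are summed over loci before
taking the ratio.  Negative estimates are reported as-is; loci monomorphic
across the compared groups contribute zeros to all three sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def _labels_for(G: GenotypeMatrix, groups) -> np.ndarray:
    if groups is None:
        return G.site_codes
    if isinstance(groups, Mapping):
        return np.array([groups[s.sample_id] for s in G.samples])
    labels = np.asarray(list(groups))
    if len(labels) != G.n_samples:
        raise ValueError("group labels length != number of samples")
    return labels


# ---------------------------------------------------------------------------
# Per-site diversity
# ---------------------------------------------------------------------------

@dataclass
class SiteDiversity:
    """Mean H_E, H_O, per-locus Weir-Cockerham f (F_IS) and proportion of
    polymorphic SNPs, per collection site."""

    table: pd.DataFrame  # index site; columns n, He, Ho, Fis, Sp

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep=".", float_format="%.6g")


def site_diversity(
    G: GenotypeMatrix, site_assignment=None
) -> SiteDiversity:
    """Per-site diversity summary.

    Per locus within a site: H_O is the heterozygote fraction among called
    individuals; H_E is the unbiased expected heterozygosity
    2p(1-p) * 2n/(2n-1); F_IS is the Weir-Cockerham within-population f
    from the single-population b and c components.  Site means average
    H_E/H_O over all loci with calls and F_IS over loci polymorphic within
    the site.  S_P is the fraction of loci with both alleles observed.
    """
    labels = _labels_for(G, site_assignment)
    sites = list(dict.fromkeys(labels))
    geno = G.genotypes
    rows = []
    for site in sites:
        sub = geno[labels == site]
        if sub.shape[0] == 0:
            raise ValueError(f"site {site} has no individuals")
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        has = n > 0
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(has, alt / (2.0 * n), np.nan)
            ho = np.where(has, (sub == 1).sum(axis=0) / n, np.nan)
            he = 2.0 * p * (1.0 - p) * np.where(n > 0.5, 2.0 * n / (2.0 * n - 1.0), np.nan)
        # Weir-Cockerham single-population components per locus
        with np.errstate(invalid="ignore", divide="ignore"):
            b = (n / (n - 1.0)) * (
                p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * ho
            )
            c = ho / 2.0
            fis = 1.0 - c / (b + c)
        poly = has & (alt > 0) & (alt < 2 * n)
        usable_fis = poly & np.isfinite(fis)
        rows.append(
            dict(
                site=site,
                n=int((labels == site).sum()),
                He=float(np.nanmean(he[has])),
                Ho=float(np.nanmean(ho[has])),
                Fis=float(np.mean(fis[usable_fis])) if usable_fis.any() else np.nan,
                Sp=float(poly.sum() / G.n_loci),
            )
        )
    return SiteDiversity(pd.DataFrame(rows).set_index("site"))


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Per-locus WC84 variance components and the ratio-of-sums estimate."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    locus_ids: list[str]
    scope: str = "global"
    ci: tuple[float, float] | None = None

    @property
    def theta(self) -> float:
        denom = float(self.a.sum() + self.b.sum() + self.c.sum())
        if denom == 0.0:
            raise ValueError("theta undefined: all loci monomorphic")
        return float(self.a.sum()) / denom

    @property
    def per_locus_theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def _wc_components(
    geno: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 a, b, c for biallelic dosage data with missingness.

    Populations with zero calls at a locus are excluded from that locus;
    loci with fewer than two populations or no variation contribute zeros.
    """
    groups = list(dict.fromkeys(labels))
    r_all = len(groups)
    L = geno.shape[1]
    n_i = np.zeros((r_all, L))
    p_i = np.zeros((r_all, L))
    h_i = np.zeros((r_all, L))
    for k, g in enumerate(groups):
        sub = geno[labels == g]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n), 0.0)
            h_i[k] = np.where(n > 0, (sub == 1).sum(axis=0) / n, 0.0)

    present = n_i > 0
    r = present.sum(axis=0).astype(float)               # populations usable per locus
    nbar = np.where(r > 0, n_i.sum(axis=0) / np.maximum(r, 1), 0.0)
    sum_n2 = (n_i ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = np.where(
            r > 1, (r * nbar - sum_n2 / np.maximum(r * nbar, 1e-300)) / (r - 1), 0.0
        )
        pbar = np.where(r * nbar > 0, (n_i * p_i).sum(axis=0) / (r * nbar), 0.0)
        s2 = np.where(
            (r > 1) & (nbar > 0),
            (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar),
            0.0,
        )
        hbar = np.where(r * nbar > 0, (n_i * h_i).sum(axis=0) / (r * nbar), 0.0)

        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2
            - (1.0 / np.maximum(nbar - 1.0, 1e-300))
            * (pbar * (1 - pbar) - (r - 1) / np.maximum(r, 1) * s2 - hbar / 4.0)
        )
        b = (nbar / np.maximum(nbar - 1.0, 1e-300)) * (
            pbar * (1 - pbar)
            - (r - 1) / np.maximum(r, 1) * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    # loci unusable (r < 2, nbar <= 1, or nc <= 0) or monomorphic: zero out
    mono = (pbar <= 0.0) | (pbar >= 1.0)
    bad = (r < 2) | (nbar <= 1.0) | (nc <= 0.0) | mono
    a = np.where(bad, 0.0, a)
    b = np.where(bad, 0.0, b)
    c = np.where(bad, 0.0, c)
    return a, b, c


def wc_theta(G: GenotypeMatrix, groups=None, scope: str = "global") -> FstResult:
    """Weir-Cockerham (1984) theta for >= 2 groups (ratio of sums over loci)."""
    labels = _labels_for(G, groups)
    if len(set(labels)) < 2:
        raise ValueError("wc_theta requires >= 2 groups")
    a, b, c = _wc_components(G.genotypes, labels)
    res = FstResult(a=a, b=b, c=c, locus_ids=G.locus_ids, scope=scope)
    if a.sum() + b.sum() + c.sum() == 0.0:
        raise ValueError("theta undefined: no polymorphic loci shared by groups")
    return res


@dataclass
class PairwiseFst:
    """Symmetric site x site matrix of pairwise theta (diagonal undefined)."""

    theta: pd.DataFrame
    results: dict[tuple[str, str], FstResult]

    def write(self, path) -> None:
        self.theta.to_csv(path, sep="\t", na_rep=".", float_format="%.6g")


def pairwise_theta(G: GenotypeMatrix, site_assignment=None) -> PairwiseFst:
    """wc_theta for every unordered pair of sites."""
    labels = _labels_for(G, site_assignment)
    sites = list(dict.fromkeys(labels))
    mat = pd.DataFrame(np.nan, index=sites, columns=sites)
    results: dict[tuple[str, str], FstResult] = {}
    for s1, s2 in combinations(sites, 2):
        sel = (labels == s1) | (labels == s2)
        sub = G.take_samples(np.flatnonzero(sel))
        try:
            res = wc_theta(sub, labels[sel], scope=f"{s1}|{s2}")
        except ValueError as e:
            logger.warning("pairwise theta undefined for (%s, %s): %s", s1, s2, e)
            continue
        results[(s1, s2)] = res
        mat.loc[s1, s2] = mat.loc[s2, s1] = res.theta
    return PairwiseFst(theta=mat, results=results)


def theta_bootstrap_ci(
    result: FstResult, n_boot: int = 1000, level: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap CI for theta, resampling loci with replacement."""
    L = len(result.locus_ids)
    if L < 2:
        raise ValueError("bootstrap requires >= 2 loci")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; CI will be noisy", n_boot)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    a = result.a[idx].sum(axis=1)
    tot = a + result.b[idx].sum(axis=1) + result.c[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        thetas = np.where(tot != 0, a / tot, np.nan)
    thetas = thetas[np.isfinite(thetas)]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(thetas, [alpha, 1.0 - alpha])
    result.ci = (float(lo), float(hi))
    return result.ci


# ---------------------------------------------------------------------------
# Genic differentiation G-tests
# ---------------------------------------------------------------------------

@dataclass
class GenicTestResult:
    """Per-locus allele-count G statistics with Monte-Carlo permutation
    p-values, combined across loci by Fisher's method."""

    per_locus: pd.DataFrame  # locus_id, G, p
    global_chi2: float
    global_df: int
    global_p: float
    n_excluded: int

    def write(self, path) -> None:
        self.per_locus.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _g_statistics(geno: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Vectorized per-locus G over the 2x2 allele-count table (0*log0 = 0)."""
    counts = []
    for m in (mask1, mask2):
        sub = geno[m]
        called = sub != MISSING
        n2 = 2.0 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0).astype(float)
        counts.append((alt, n2 - alt))
    obs = np.stack([counts[0][0], counts[0][1], counts[1][0], counts[1][1]])
    row1 = obs[0] + obs[1]
    row2 = obs[2] + obs[3]
    col_alt = obs[0] + obs[2]
    col_ref = obs[1] + obs[3]
    tot = row1 + row2
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.stack(
            [
                row1 * col_alt, row1 * col_ref, row2 * col_alt, row2 * col_ref,
            ]
        ) / np.maximum(tot, 1e-300)
        term = np.where(obs > 0, obs * np.log(obs / np.maximum(exp, 1e-300)), 0.0)
    g = 2.0 * term.sum(axis=0)
    g[~np.isfinite(g)] = 0.0
    return np.maximum(g, 0.0)


def genic_test(
    G: GenotypeMatrix,
    group_pair: tuple[str, str],
    groups=None,
    n_perm: int = 10000,
    seed: int | None = None,
    batch: int = 500,
) -> GenicTestResult:
    """Monte-Carlo G-test of genic differentiation between two groups.

    Per-locus p-values come from permuting individuals between the two
    groups ((count >= observed) + 1) / (n_perm + 1); the global p combines
    locus p-values by Fisher's method.  Loci where either group has zero
    calls are excluded and counted.
    """
    labels = _labels_for(G, groups)
    g1, g2 = group_pair
    m1, m2 = labels == g1, labels == g2
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError(f"empty group in pair {group_pair}")
    geno = G.genotypes[m1 | m2]
    is1 = (labels[m1 | m2] == g1)
    n1 = int(is1.sum())

    called = geno != MISSING
    ok = (called[is1].sum(axis=0) > 0) & (called[~is1].sum(axis=0) > 0)
    n_excluded = int((~ok).sum())
    geno_ok = geno[:, ok]

    g_obs = _g_statistics(geno_ok, is1, ~is1)
    rng = np.random.default_rng(seed)
    count_ge = np.zeros(geno_ok.shape[1], dtype=int)
    n_tot = geno.shape[0]
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        for _ in range(nb):
            perm = rng.permutation(n_tot)
            pm1 = np.zeros(n_tot, dtype=bool)
            pm1[perm[:n1]] = True
            g_perm = _g_statistics(geno_ok, pm1, ~pm1)
            count_ge += g_perm >= g_obs - 1e-12
        done += nb
    p = (count_ge + 1.0) / (n_perm + 1.0)

    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    global_p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    ids = np.array(G.locus_ids)[ok]
    return GenicTestResult(
        per_locus=pd.DataFrame({"locus_id": ids, "G": g_obs, "p": p}),
        global_chi2=chi2,
        global_df=df,
        global_p=global_p,
        n_excluded=n_excluded,
    )


def pairwise_genic_tests(
    G: GenotypeMatrix, site_assignment=None, n_perm: int = 10000, seed: int | None = None
) -> pd.DataFrame:
    """Global genic-differentiation p for every unordered site pair."""
    labels = _labels_for(G, site_assignment)
    sites = list(dict.fromkeys(labels))
    out = pd.DataFrame(np.nan, index=sites, columns=sites)
    ss = np.random.SeedSequence(seed)
    for (s1, s2), child in zip(
        combinations(sites, 2), ss.spawn(len(sites) * (len(sites) - 1) // 2)
    ):
        res = genic_test(
            G, (s1, s2), groups=labels, n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        out.loc[s1, s2] = out.loc[s2, s1] = res.global_p
    return out
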