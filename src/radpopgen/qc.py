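"""SNP and individual filtering cascade, HWE screening, and the
replicate-based genotyping-error estimate.

The cascade applies, in a fixed order: non-biallelic/indel removal, QUAL,
per-locus missingness, global minor allele frequency, then one SNP per RAD
tag, then per-individual missingness.  The MAF threshold is inclusive
(MAF >= 0.05 kept) while missingness thresholds remove strictly-greater
values ("more than 30%").  Hardy-Weinberg screening drops a locus only when
it fails (BH q < alpha) in at least ``min_failing_sites`` collection sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, GenotypeMatrix, allele_frequencies

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """All loci (or all individuals) were removed by a filter."""


@dataclass
class FilterReport:
    """Ordered per-filter counts plus a per-item drop reason.

    Each dropped locus/individual records the *first* filter that removed
    it; counts are monotonically non-increasing through the cascade.
    """

    steps: list[dict] = field(default_factory=list)
    dropped_loci: dict[str, str] = field(default_factory=dict)
    dropped_individuals: dict[str, str] = field(default_factory=dict)

    def add_step(
        self, name: str, n_loci_before: int, n_loci_after: int,
        n_ind_before: int, n_ind_after: int,
    ) -> None:
        if n_loci_after > n_loci_before or n_ind_after > n_ind_before:
            raise ValueError("filter cannot add loci or individuals")
        self.steps.append(
            dict(
                filter_name=name,
                n_loci_before=n_loci_before, n_loci_after=n_loci_after,
                n_individuals_before=n_ind_before, n_individuals_after=n_ind_after,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _global_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per locus over all called individuals pooled.

    Loci with zero calls report NaN.
    """
    geno = G.genotypes
    called = geno != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_snps(
    G: GenotypeMatrix,
    min_qual: float = 20.0,
    min_maf: float = 0.05,
    max_locus_missing: float = 0.30,
    biallelic_snps_only: bool = True,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Locus filter cascade: indel/multi-allelic -> QUAL -> missingness -> MAF."""
    rep = report if report is not None else FilterReport()
    n_ind = G.n_samples
    keep = np.ones(G.n_loci, dtype=bool)

    def apply(name: str, fail_mask: np.ndarray) -> None:
        before = int(keep.sum())
        newly = keep & fail_mask
        for i in np.flatnonzero(newly):
            rep.dropped_loci[G.loci[i].locus_id] = name
        keep[newly] = False
        rep.add_step(name, before, int(keep.sum()), n_ind, n_ind)

    if biallelic_snps_only:
        fail = np.array([not (l.is_snp and l.is_biallelic) for l in G.loci])
        apply("biallelic_snps_only", fail)

    qual = np.array([l.qual for l in G.loci])
    apply("min_qual", qual < min_qual)

    missing_frac = (G.genotypes == MISSING).mean(axis=0)
    apply("max_locus_missing", missing_frac > max_locus_missing)

    maf = _global_maf(G)
    apply("min_maf", ~(maf >= min_maf))  # NaN (no calls) also fails

    if not keep.any():
        raise EmptyResultError("all loci removed by filter_snps")
    return G.take_loci(np.flatnonzero(keep)), rep


def filter_individuals(
    G: GenotypeMatrix,
    max_ind_missing: float = 0.30,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove individuals with strictly more than ``max_ind_missing`` missing data."""
    rep = report if report is not None else FilterReport()
    missing_frac = (G.genotypes == MISSING).mean(axis=1)
    keep = missing_frac <= max_ind_missing
    for i in np.flatnonzero(~keep):
        rep.dropped_individuals[G.samples[i].sample_id] = "max_ind_missing"
    rep.add_step(
        "max_ind_missing", G.n_loci, G.n_loci, G.n_samples, int(keep.sum())
    )
    if not keep.any():
        raise EmptyResultError("all individuals removed by filter_individuals")
    G2 = G.take_samples(np.flatnonzero(keep))
    lost_sites = set(G.site_codes) - set(G2.site_codes)
    if lost_sites:
        logger.warning("sites lost all individuals: %s", sorted(lost_sites))
    return G2, rep


def select_snp_per_tag(
    G: GenotypeMatrix, report: FilterReport | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep, per RAD tag, the SNP with the highest minor allele frequency.

    Ties break to the smallest position, then lexicographic locus_id.
    """
    rep = report if report is not None else FilterReport()
    maf = _global_maf(G)
    best: dict[str, int] = {}
    for i, l in enumerate(G.loci):
        j = best.get(l.tag_id)
        if j is None:
            best[l.tag_id] = i
            continue
        lj = G.loci[j]
        cand = (-(maf[i] if np.isfinite(maf[i]) else -1.0), l.position, l.locus_id)
        incumbent = (-(maf[j] if np.isfinite(maf[j]) else -1.0), lj.position, lj.locus_id)
        if cand < incumbent:
            best[l.tag_id] = i
    keep_idx = sorted(best.values())
    kept = set(keep_idx)
    for i, l in enumerate(G.loci):
        if i not in kept:
            rep.dropped_loci[l.locus_id] = "one_snp_per_tag"
    rep.add_step("one_snp_per_tag", G.n_loci, len(keep_idx), G.n_samples, G.n_samples)
    return G.take_loci(keep_idx), rep


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (probability-ordering, biallelic)
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test for Hardy-Weinberg proportions at a biallelic locus.

    Conditions on the observed allele counts and enumerates all heterozygote
    counts of the same parity; the p-value sums the probabilities of all
    outcomes no more probable than the observed one (two-sided
    probability-ordering test).  A monomorphic sample returns p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic

    # P(n_het | n, n_rare) via the standard recurrence, normalized at the end.
    het_values = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    probs = {}
    # start from the smallest admissible het count with unnormalized mass 1
    h0 = het_values[0]
    probs[h0] = 1.0
    for h in het_values[:-1]:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # ratio P(h+2)/P(h)
        probs[h + 2] = probs[h] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    return min(1.0, sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12)))


@dataclass
class HweScreenResult:
    """Per-locus x per-site HWE screen with BH correction within each site."""

    p: pd.DataFrame             # sites x loci, NaN where untestable
    q: pd.DataFrame             # BH-adjusted within each site's tested loci
    n_sites_failing: pd.Series  # per locus, count of sites with q < alpha
    keep: pd.Series             # per locus, True if retained
    alpha: float
    min_failing_sites: int

    def write(self, path) -> None:
        out = pd.DataFrame(
            {
                "n_sites_failing": self.n_sites_failing,
                "keep": self.keep,
            }
        )
        out.to_csv(path, sep="\t", na_rep=".")


def hwe_filter(
    G: GenotypeMatrix,
    site_assignment: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    min_failing_sites: int = 2,
) -> tuple[GenotypeMatrix, HweScreenResult]:
    """Drop loci out of HWE (BH q < alpha) in >= ``min_failing_sites`` sites.

    The BH family is the set of testable loci within one site.  A site with
    zero called genotypes at a locus contributes no test there.
    """
    if site_assignment is None:
        labels = G.site_codes
    else:
        labels = np.array([site_assignment[s.sample_id] for s in G.samples])
    sites = list(dict.fromkeys(labels))
    if len(sites) < 2:
        raise ValueError("HWE screen requires >= 2 sites")

    ids = G.locus_ids
    geno = G.genotypes
    p = pd.DataFrame(np.nan, index=sites, columns=ids)
    q = pd.DataFrame(np.nan, index=sites, columns=ids)
    for site in sites:
        sub = geno[labels == site]
        n_AA = (sub == 0).sum(axis=0)
        n_Aa = (sub == 1).sum(axis=0)
        n_aa = (sub == 2).sum(axis=0)
        testable = (n_AA + n_Aa + n_aa) > 0
        pvals = np.array(
            [
                hwe_exact_test(int(a), int(h), int(b))
                for a, h, b in zip(n_AA[testable], n_Aa[testable], n_aa[testable])
            ]
        )
        p.loc[site, np.array(ids)[testable]] = pvals
        if pvals.size:
            q.loc[site, np.array(ids)[testable]] = multipletests(
                pvals, method="fdr_bh"
            )[1]

    n_failing = (q < alpha).sum(axis=0)
    keep = n_failing < min_failing_sites
    result = HweScreenResult(
        p=p, q=q, n_sites_failing=n_failing, keep=keep,
        alpha=alpha, min_failing_sites=min_failing_sites,
    )
    kept_idx = [i for i, lid in enumerate(ids) if keep[lid]]
    if not kept_idx:
        raise EmptyResultError("all loci removed by hwe_filter")
    return G.take_loci(kept_idx), result


# ---------------------------------------------------------------------------
# Replicate-based genotyping error
# ---------------------------------------------------------------------------

@dataclass
class ErrorEstimate:
    """Genotype-level discordance across replicate pairs.

    ``rate`` = total mismatching cells / cells called in both members;
    ``per_locus_mismatches`` histograms mismatches per locus across pairs.
    """

    rate: float
    per_locus_mismatches: pd.Series
    n_pairs: int
    n_comparisons: int

    def mismatch_histogram(self) -> pd.Series:
        """Count of loci with exactly k mismatches, for k >= 1."""
        nz = self.per_locus_mismatches[self.per_locus_mismatches > 0]
        return nz.value_counts().sort_index()


def replicate_pairs_from_metadata(G: GenotypeMatrix) -> list[tuple[str, str]]:
    """Pairs (original, replicate) declared via SampleInfo.is_replicate_of."""
    return [
        (s.is_replicate_of, s.sample_id)
        for s in G.samples
        if s.is_replicate_of is not None
    ]


def genotyping_error(
    G: GenotypeMatrix, replicate_pairs: Sequence[tuple[str, str]] | None = None
) -> ErrorEstimate:
    """Discordance rate between replicate genotypings of the same individuals."""
    if replicate_pairs is None:
        replicate_pairs = replicate_pairs_from_metadata(G)
    if not replicate_pairs:
        raise ValueError("no replicate pairs supplied or declared")
    mismatch = np.zeros(G.n_loci, dtype=int)
    n_comp = 0
    n_pairs = 0
    for a, b in replicate_pairs:
        ia, ib = G.sample_index(a), G.sample_index(b)
        ga, gb = G.genotypes[ia], G.genotypes[ib]
        both = (ga != MISSING) & (gb != MISSING)
        if not both.any():
            logger.warning("replicate pair (%s, %s) shares no called loci", a, b)
            continue
        n_pairs += 1
        n_comp += int(both.sum())
        mismatch += (both & (ga != gb)).astype(int)
    if n_comp == 0:
        raise ValueError("no jointly-called cells in any replicate pair")
    return ErrorEstimate(
        rate=float(mismatch.sum()) / n_comp,
        per_locus_mismatches=pd.Series(mismatch, index=G.locus_ids),
        n_pairs=n_pairs,
        n_comparisons=n_comp,
    )
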