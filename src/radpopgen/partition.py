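"""Partition SNPs into putatively adaptive and putatively neutral sets.

Evidence comes from external per-SNP tables: FST-outlier flags (two
independent outlier scans), per-predictor Bayes factors from a
gene-environment association scan, and ordination-axis loadings from a
redundancy analysis.  A SNP is putatively adaptive if *any* rule fires:

* flagged by either FST-outlier method,
* Bayes factor >= 10 ("strong" support) for at least one predictor,
* loading more than 3 SD from the mean on at least one retained axis.

The neutral set is the complement; the partition is exhaustive and
disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EvidenceTable:
    """Per-SNP evidence columns; any component may be absent (None).

    ``bayescan`` / ``outflank``: boolean outlier flags indexed by SNP id.
    ``bayes_factors``: SNPs x predictors, non-negative.
    ``rda_loadings``: SNPs x retained axes.
    """

    bayescan: pd.Series | None = None
    outflank: pd.Series | None = None
    bayes_factors: pd.DataFrame | None = None
    rda_loadings: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.bayes_factors is not None and (self.bayes_factors < 0).any().any():
            raise ValueError("Bayes factors must be non-negative")

    def snp_ids(self) -> set[str]:
        ids: set[str] = set()
        for s in (self.bayescan, self.outflank):
            if s is not None:
                ids |= set(s.index)
        for df in (self.bayes_factors, self.rda_loadings):
            if df is not None:
                ids |= set(df.index)
        return ids


def bayes_factor_rule(
    evidence: EvidenceTable | pd.DataFrame, bf_min: float = 10.0
) -> pd.Series:
    """Flag SNPs with Bayes factor >= ``bf_min`` for at least one predictor.

    Returns a boolean Series; its ``.attrs['n_predictors']`` Series counts
    how many predictors fired per SNP (mean over flagged SNPs mirrors the
    "average number of correlated predictors" summary).
    """
    bf = evidence.bayes_factors if isinstance(evidence, EvidenceTable) else evidence
    if bf is None:
        raise ValueError("no Bayes factor columns present")
    hits = bf >= bf_min  # inclusive threshold
    flags = hits.any(axis=1)
    flags.attrs["n_predictors"] = hits.sum(axis=1)
    return flags


def rda_loading_rule(loadings: pd.DataFrame, k_sd: float = 3.0) -> pd.Series:
    """Flag SNPs whose loading is > ``k_sd`` population SDs from the axis mean,
    on any retained axis."""
    if loadings is None or loadings.shape[1] == 0:
        raise ValueError("no loading columns present")
    flags = pd.Series(False, index=loadings.index)
    for axis in loadings.columns:
        col = loadings[axis].astype(float)
        sd = float(col.std(ddof=0))
        if sd == 0.0:
            logger.warning("axis %s has zero-variance loadings; no flags", axis)
            continue
        flags |= (col - col.mean()).abs() > k_sd * sd
    return flags


@dataclass
class Partition:
    """Disjoint, exhaustive split of SNP ids with per-SNP rule provenance."""

    adaptive: set[str]
    neutral: set[str]
    provenance: pd.DataFrame  # SNP x rule booleans
    method_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.adaptive & self.neutral:
            raise ValueError("adaptive and neutral sets overlap")

    def label_of(self, snp_id: str) -> str:
        return "adaptive" if snp_id in self.adaptive else "neutral"

    def write(self, path) -> None:
        rows = [(s, "adaptive") for s in sorted(self.adaptive)]
        rows += [(s, "neutral") for s in sorted(self.neutral)]
        pd.DataFrame(rows, columns=["snp_id", "set"]).to_csv(
            path, sep="\t", index=False
        )


def classify(
    evidence: EvidenceTable,
    all_snps: Sequence[str],
    bf_min: float = 10.0,
    k_sd: float = 3.0,
) -> Partition:
    """Union-of-rules classification into putatively adaptive vs neutral."""
    all_ids = list(all_snps)
    unknown = evidence.snp_ids() - set(all_ids)
    if unknown:
        raise ValueError(f"evidence names SNPs outside the dataset: {sorted(unknown)[:5]}")

    rules: dict[str, pd.Series] = {}
    if evidence.bayescan is not None:
        rules["bayescan"] = evidence.bayescan.astype(bool)
    if evidence.outflank is not None:
        rules["outflank"] = evidence.outflank.astype(bool)
    if evidence.bayes_factors is not None:
        rules["bayes_factor"] = bayes_factor_rule(evidence, bf_min=bf_min)
    if evidence.rda_loadings is not None:
        rules["rda_loading"] = rda_loading_rule(evidence.rda_loadings, k_sd=k_sd)
    if not rules:
        raise ValueError("at least one evidence column is required")

    prov = pd.DataFrame(False, index=pd.Index(all_ids, name="snp_id"), columns=list(rules))
    for name, flags in rules.items():
        fired = flags[flags].index
        prov.loc[prov.index.intersection(fired), name] = True

    adaptive = set(prov.index[prov.any(axis=1)])
    neutral = set(all_ids) - adaptive
    counts = {name: int(prov[name].sum()) for name in prov.columns}
    counts["adaptive_total"] = len(adaptive)
    for a in prov.columns:
        for b in prov.columns:
            if a < b:
                counts[f"{a}&{b}"] = int((prov[a] & prov[b]).sum())
    return Partition(
        adaptive=adaptive, neutral=neutral, provenance=prov, method_counts=counts
    )


def empirical_theta_outlier_flags(
    per_locus_theta: pd.Series, top_fraction: float = 0.05
) -> pd.Series:
    """Naive top-quantile per-locus theta scan.

    Test plumbing only: flags the highest-theta fraction of loci so the
    partition machinery can be exercised without external scans.  Not a
    publication-grade outlier method.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    cutoff = per_locus_theta.quantile(1.0 - top_fraction)
    return per_locus_theta > cutoff
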