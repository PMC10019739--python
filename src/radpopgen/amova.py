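"""Hierarchical analysis of molecular variance (AMOVA) with permutation tests.

Three levels: among groups of sites (sigma2_a, Phi_CT), among sites within
groups (sigma2_b, Phi_SC) and within sites (sigma2_c).  Distances are
squared Euclidean distances between individual dosage vectors, with
pairwise-complete handling of missing genotypes (the mean squared
difference over jointly-called loci, rescaled to the full locus count).
Variance components use the standard unbalanced-design coefficients and
are not truncated at zero.  Phi_CT significance permutes whole sites among
groups; Phi_SC significance permutes individuals among sites within groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SiteTable

logger = logging.getLogger(__name__)


@dataclass
class Hierarchy:
    """One named grouping: site code -> group label."""

    name: str
    site_to_group: dict[str, str]

    def __post_init__(self) -> None:
        groups = set(self.site_to_group.values())
        if len(groups) < 2:
            raise ValueError(f"grouping {self.name!r} needs >= 2 groups, got {groups}")


@dataclass
class AmovaResult:
    """Variance components, Phi-statistics and permutation p-values."""

    grouping: str
    sigma2_a: float
    sigma2_b: float
    sigma2_c: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float | None
    p_sc: float | None
    n_perm: int
    degenerate: bool = False

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_a + self.sigma2_b + self.sigma2_c

    @property
    def ratio_ct_sc(self) -> float:
        return self.phi_ct / self.phi_sc if self.phi_sc != 0 else math.nan


def _pairwise_sq_distances(geno: np.ndarray, n_loci: int) -> np.ndarray:
    """Squared Euclidean distances over dosage vectors, pairwise-complete.

    d2_ij = L * mean over jointly-called loci of (x_i - x_j)^2.
    Pairs with no jointly-called locus get distance 0 with a warning.
    """
    x = geno.astype(float)
    called = geno != MISSING
    x[~called] = 0.0
    c = called.astype(float)
    # sum over jointly-called loci of (xi - xj)^2, expanded:
    xi2 = (x ** 2) @ c.T          # sum_l xi^2 over loci called in both
    cross = x @ x.T
    ss = xi2 + xi2.T - 2.0 * cross
    n_joint = c @ c.T
    if (n_joint == 0).any():
        logger.warning("individual pairs with no jointly-called loci; distance 0 used")
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(n_joint > 0, ss / np.maximum(n_joint, 1) * n_loci, 0.0)
    np.fill_diagonal(d2, 0.0)
    return d2


def _components(
    d2: np.ndarray, site_labels: np.ndarray, group_of: Mapping[str, str]
) -> tuple[float, float, float, bool]:
    """Excoffier-style SS decomposition -> (sigma2_a, sigma2_b, sigma2_c, degenerate)."""
    N = len(site_labels)
    sites = list(dict.fromkeys(site_labels))
    groups = list(dict.fromkeys(group_of[s] for s in sites))
    S, Gn = len(sites), len(groups)

    def ss_within(mask: np.ndarray) -> float:
        n = int(mask.sum())
        if n < 2:
            return 0.0
        sub = d2[np.ix_(mask, mask)]
        return float(sub.sum() / 2.0 / n)

    all_mask = np.ones(N, dtype=bool)
    ss_total = ss_within(all_mask)
    site_masks = {s: site_labels == s for s in sites}
    ss_wp = sum(ss_within(site_masks[s]) for s in sites)
    group_masks = {}
    for g in groups:
        m = np.zeros(N, dtype=bool)
        for s in sites:
            if group_of[s] == g:
                m |= site_masks[s]
        group_masks[g] = m
    ss_wg = sum(ss_within(group_masks[g]) for g in groups)
    ss_ap = ss_wg - ss_wp        # among sites within groups
    ss_ag = ss_total - ss_wg     # among groups

    df_c = N - S
    df_b = S - Gn
    df_a = Gn - 1
    n_s = np.array([int(site_masks[s].sum()) for s in sites], dtype=float)
    N_g = {g: float(group_masks[g].sum()) for g in groups}
    sum_ns2_over_Ng = sum(
        sum(n_s[i] ** 2 for i, s in enumerate(sites) if group_of[s] == g) / N_g[g]
        for g in groups
    )
    sum_ns2_over_N = float((n_s ** 2).sum()) / N
    sum_Ng2_over_N = sum(N_g[g] ** 2 for g in groups) / N

    n_prime = (N - sum_ns2_over_Ng) / df_b if df_b > 0 else 0.0
    n_dprime = (sum_ns2_over_Ng - sum_ns2_over_N) / df_a if df_a > 0 else 0.0
    n_tprime = (N - sum_Ng2_over_N) / df_a if df_a > 0 else 0.0

    ms_c = ss_wp / df_c if df_c > 0 else 0.0
    ms_b = ss_ap / df_b if df_b > 0 else 0.0
    ms_a = ss_ag / df_a if df_a > 0 else 0.0

    sigma2_c = ms_c
    sigma2_b = (ms_b - sigma2_c) / n_prime if n_prime > 0 else 0.0
    sigma2_a = (
        (ms_a - sigma2_c - n_dprime * sigma2_b) / n_tprime if n_tprime > 0 else 0.0
    )
    degenerate = ss_total == 0.0
    return sigma2_a, sigma2_b, sigma2_c, degenerate


def _phis(s_a: float, s_b: float, s_c: float, degenerate: bool):
    tot = s_a + s_b + s_c
    if degenerate or tot == 0.0:
        return 0.0, 0.0, 0.0
    phi_ct = s_a / tot
    phi_sc = s_b / (s_b + s_c) if (s_b + s_c) != 0 else 0.0
    phi_st = (s_a + s_b) / tot
    return phi_ct, phi_sc, phi_st


def amova(
    G: GenotypeMatrix,
    hierarchy: Hierarchy,
    site_assignment=None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Three-level AMOVA over individual dosage distances with permutation tests."""
    if site_assignment is None:
        site_labels = G.site_codes
    else:
        site_labels = np.array([site_assignment[s.sample_id] for s in G.samples])
    sites = list(dict.fromkeys(site_labels))
    unlabeled = [s for s in sites if s not in hierarchy.site_to_group]
    if unlabeled:
        raise ValueError(f"grouping {hierarchy.name!r} misses sites {unlabeled}")
    group_of = {s: hierarchy.site_to_group[s] for s in sites}
    if len(set(group_of.values())) < 2:
        raise ValueError(f"grouping {hierarchy.name!r} has < 2 groups among these sites")

    d2 = _pairwise_sq_distances(G.genotypes, G.n_loci)
    s_a, s_b, s_c, degen = _components(d2, site_labels, group_of)
    phi_ct, phi_sc, phi_st = _phis(s_a, s_b, s_c, degen)
    if degen:
        logger.warning("all individuals identical; AMOVA components degenerate")

    rng = np.random.default_rng(seed)
    p_ct = p_sc = None
    if n_perm > 0 and not degen:
        # Phi_CT: permute whole sites among groups (site-level label shuffle)
        group_labels = [group_of[s] for s in sites]
        n_distinct = math.factorial(len(sites))
        if len(sites) <= 5:
            logger.warning(
                "Phi_CT permutation space is small (%d site orderings)", n_distinct
            )
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(sites))
            g_perm = {s: group_labels[perm[i]] for i, s in enumerate(sites)}
            if len(set(g_perm.values())) < 2:
                continue
            a_p, b_p, c_p, dg = _components(d2, site_labels, g_perm)
            ct_p, _, _ = _phis(a_p, b_p, c_p, dg)
            if ct_p >= phi_ct - 1e-12:
                count += 1
        p_ct = (count + 1.0) / (n_perm + 1.0)

        # Phi_SC: permute individuals among sites within each group
        count = 0
        idx_by_group = {
            g: np.flatnonzero(np.isin(site_labels, [s for s in sites if group_of[s] == g]))
            for g in set(group_of.values())
        }
        for _ in range(n_perm):
            labels_p = site_labels.copy()
            for g, idx in idx_by_group.items():
                labels_p[idx] = site_labels[idx][rng.permutation(len(idx))]
            a_p, b_p, c_p, dg = _components(d2, labels_p, group_of)
            _, sc_p, _ = _phis(a_p, b_p, c_p, dg)
            if sc_p >= phi_sc - 1e-12:
                count += 1
        p_sc = (count + 1.0) / (n_perm + 1.0)

    return AmovaResult(
        grouping=hierarchy.name,
        sigma2_a=s_a, sigma2_b=s_b, sigma2_c=s_c,
        phi_ct=phi_ct, phi_sc=phi_sc, phi_st=phi_st,
        p_ct=p_ct, p_sc=p_sc, n_perm=n_perm, degenerate=degen,
    )


# ---------------------------------------------------------------------------
# The study's five groupings, from SiteTable labels
# ---------------------------------------------------------------------------

def standard_groupings(site_table: SiteTable) -> list[Hierarchy]:
    """Build the five standard groupings from SiteTable label columns.

    NPC: north vs south of the North Pacific Current; Victoria Sill:
    inside vs outside the Salish Sea; Admiralty Inlet: inside vs outside
    Puget Sound proper (``ps`` column); All Barriers: the joint
    SS/PS/NPC label combination; State: state or province code.
    """
    npc = site_table.label("npc")
    ss = site_table.label("salish_sea")
    ps = site_table.label("ps")
    state = site_table.label("state")
    joint = {c: f"{ss[c]}{ps[c]}{npc[c]}" for c in site_table.codes}
    return [
        Hierarchy("NPC", npc),
        Hierarchy("VictoriaSill", ss),
        Hierarchy("AdmiraltyInlet", ps),
        Hierarchy("AllBarriers", joint),
        Hierarchy("State", state),
    ]


def run_standard_groupings(
    G: GenotypeMatrix,
    site_table: SiteTable,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict[str, AmovaResult]:
    """AMOVA for each of the five standard groupings."""
    out = {}
    ss = np.random.SeedSequence(seed)
    hiers = standard_groupings(site_table)
    for h, child in zip(hiers, ss.spawn(len(hiers))):
        out[h.name] = amova(
            G, h, n_perm=n_perm, seed=int(child.generate_state(1)[0] % (2**31))
        )
    return out


def results_table(results: Mapping[str, AmovaResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append(
            dict(
                grouping=name,
                phi_ct=r.phi_ct, p_ct=r.p_ct,
                phi_sc=r.phi_sc, p_sc=r.p_sc,
                ratio=r.ratio_ct_sc,
                sig_ct="*" if (r.p_ct is not None and r.p_ct < 0.05) else "",
                sig_sc="*" if (r.p_sc is not None and r.p_sc < 0.05) else "",
            )
        )
    return pd.DataFrame(rows)
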