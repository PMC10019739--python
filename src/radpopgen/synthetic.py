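"""Synthetic genotype generators with truth manifests.

Two generative models cover the statistical structure the analyses assume:

* Balding-Nichols: site allele frequencies are Beta-distributed around a
  shared ancestral frequency with differentiation parameter F, giving a
  closed-form link between F and expected Weir-Cockerham theta.
* Linear stepping-stone: K demes exchanging migrants with neighbours under
  Wright-Fisher drift, producing genuine isolation-by-distance for
  Mantel/IBD recovery tests (a parametric model cannot encode the distance
  decay of covariance).

``inject_artifacts`` adds missingness, per-allele genotyping error and
duplicated (replicate) individuals.  Every generator is deterministic
under a fixed seed and returns a manifest sufficient to recompute the
expectations used in tests.  Default shapes mirror a mid-sized RAD-seq
study: ~9 collection sites, 10-50 individuals each, ~2,075 SNPs with
MAF >= 0.05 and weak structure (pairwise FST in the 0.001-0.015 range).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    LocusInfo,
    SampleInfo,
    SiteTable,
    write_distance_matrix,
    write_sample_metadata,
    write_vcf,
)

_NUCS = ("A", "C", "G", "T")


@dataclass
class TruthManifest:
    """Everything needed to recompute the expectations a test asserts."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)
    site_freqs: dict | None = None       # site -> list of true frequencies
    missing_rate: float = 0.0
    allele_error_rate: float = 0.0
    replicate_pairs: list = field(default_factory=list)
    planted: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @classmethod
    def read(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _make_loci(L: int, rng: np.random.Generator, snps_per_tag: int = 1) -> list[LocusInfo]:
    loci = []
    for j in range(L):
        tag = f"tag{j // snps_per_tag:05d}"
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            LocusInfo(
                locus_id=f"snp{j:05d}",
                tag_id=tag,
                position=int(1 + (j % snps_per_tag) * 37 + rng.integers(0, 10)),
                ref_allele=_NUCS[ref],
                alt_allele=_NUCS[alt],
                qual=float(np.round(rng.uniform(30, 90), 1)),
            )
        )
    return loci


def generate_balding_nichols(
    K_sites: int = 9,
    n_per_site=None,
    L: int = 2075,
    F_per_site: float | list[float] = 0.01,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | None = None,
) -> tuple[GenotypeMatrix, TruthManifest]:
    """Balding-Nichols genotypes: Beta site frequencies, HWE within sites.

    ``n_per_site`` may be an int, a list, or None (drawn from 10..50 to
    mirror field sample sizes).  ``F_per_site`` scalar or per-site list;
    F = 0 copies the ancestral frequency exactly.
    """
    rng = np.random.default_rng(seed)
    if n_per_site is None:
        n_per_site = rng.integers(10, 51, size=K_sites).tolist()
    elif np.isscalar(n_per_site):
        n_per_site = [int(n_per_site)] * K_sites
    if np.isscalar(F_per_site):
        F_per_site = [float(F_per_site)] * K_sites
    if len(n_per_site) != K_sites or len(F_per_site) != K_sites:
        raise ValueError("per-site parameter lengths must equal K_sites")
    if any(not (0.0 <= F < 1.0) for F in F_per_site):
        raise ValueError("F must lie in [0, 1)")
    if any(n < 2 for n in n_per_site):
        raise ValueError("need >= 2 individuals per site")

    lo, hi = maf_range
    p_anc = rng.uniform(lo, hi, size=L)
    sites = [f"S{k+1:02d}" for k in range(K_sites)]
    site_freqs = {}
    blocks, samples = [], []
    for k, site in enumerate(sites):
        F = F_per_site[k]
        if F == 0.0:
            p_site = p_anc.copy()
        else:
            ratio = (1.0 - F) / F
            p_site = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
        site_freqs[site] = p_site.tolist()
        blocks.append(rng.binomial(2, p_site, size=(n_per_site[k], L)).astype(np.int8))
        samples.extend(
            SampleInfo(f"{site}_ind{i:03d}", site) for i in range(n_per_site[k])
        )
    G = GenotypeMatrix(np.concatenate(blocks), _make_loci(L, rng), samples)
    manifest = TruthManifest(
        generator="balding_nichols",
        seed=seed,
        params=dict(
            K_sites=K_sites, n_per_site=list(map(int, n_per_site)), L=L,
            F_per_site=F_per_site, maf_range=list(maf_range),
        ),
        site_freqs={"ancestral": p_anc.tolist(), **site_freqs},
    )
    return G, manifest


def generate_ibd_transect(
    K_sites: int = 9,
    spacing_km: float = 100.0,
    Ne: int = 1000,
    m_neighbor: float = 0.01,
    T: int = 500,
    L: int = 2000,
    n_per_site: int = 30,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthManifest]:
    """Linear stepping-stone transect with true isolation by distance.

    K demes on a line exchange a fraction ``m_neighbor`` of their gene pool
    with each neighbour per generation, drifting for T generations from a
    common ancestral pool; site i sits at position i * spacing_km.
    """
    if K_sites < 4:
        raise ValueError("transect needs >= 4 sites")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.1, 0.9, size=L)
    counts = rng.binomial(2 * Ne, p0, size=(K_sites, L))
    for _ in range(T):
        p = counts / (2.0 * Ne)
        p_mig = p.copy()
        for i in range(K_sites):
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < K_sites]
            m_tot = m_neighbor * len(neighbors)
            p_mig[i] = (1.0 - m_tot) * p[i] + m_neighbor * sum(p[j] for j in neighbors)
        counts = rng.binomial(2 * Ne, np.clip(p_mig, 0.0, 1.0))

    p_final = counts / (2.0 * Ne)
    sites = [f"T{k+1:02d}" for k in range(K_sites)]
    blocks = [
        rng.binomial(2, p_final[k], size=(n_per_site, L)).astype(np.int8)
        for k in range(K_sites)
    ]
    samples = [
        SampleInfo(f"{site}_ind{i:03d}", site)
        for site in sites
        for i in range(n_per_site)
    ]
    G = GenotypeMatrix(np.concatenate(blocks), _make_loci(L, rng), samples)

    pos = np.arange(K_sites) * spacing_km
    dist = pd.DataFrame(
        np.abs(pos[:, None] - pos[None, :]), index=sites, columns=sites, dtype=float
    )
    manifest = TruthManifest(
        generator="ibd_transect",
        seed=seed,
        params=dict(
            K_sites=K_sites, spacing_km=spacing_km, Ne=Ne,
            m_neighbor=m_neighbor, T=T, L=L, n_per_site=n_per_site,
        ),
        site_freqs={s: p_final[k].tolist() for k, s in enumerate(sites)},
    )
    return G, dist, manifest


def inject_artifacts(
    G: GenotypeMatrix,
    missing_rate: float = 0.0,
    allele_error_rate: float = 0.0,
    n_replicate_pairs: int = 0,
    seed: int | None = None,
    missing_individuals: list[str] | None = None,
    individual_missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, TruthManifest]:
    """Add genotyping error, missingness and replicate individuals.

    Each allele flips independently with ``allele_error_rate`` (dosage
    moves by +-1, capped to [0, 2]); each cell goes missing with
    ``missing_rate``.  Replicates duplicate the first ``n_replicate_pairs``
    individuals and apply errors independently to each copy.
    ``missing_individuals`` optionally plants extra missingness (at
    ``individual_missing_rate``) into named individuals, for testing the
    per-individual missingness filter.
    """
    if not (0.0 <= missing_rate < 1.0 and 0.0 <= allele_error_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    geno = G.genotypes.copy()
    samples = list(G.samples)

    if n_replicate_pairs > 0:
        if n_replicate_pairs > G.n_samples:
            raise ValueError("more replicate pairs than individuals")
        rep_rows = geno[:n_replicate_pairs].copy()
        geno = np.concatenate([geno, rep_rows])
        for i in range(n_replicate_pairs):
            orig = samples[i]
            samples.append(
                SampleInfo(f"{orig.sample_id}_rep", orig.site_code, orig.sample_id)
            )
    pairs = [
        (samples[i].sample_id, f"{samples[i].sample_id}_rep")
        for i in range(n_replicate_pairs)
    ]

    called = geno != MISSING
    if allele_error_rate > 0:
        flips = rng.binomial(2, allele_error_rate, size=geno.shape)
        signs = rng.choice((-1, 1), size=geno.shape)
        noisy = np.clip(geno + flips * signs, 0, 2).astype(np.int8)
        geno = np.where(called, noisy, geno)
    if missing_rate > 0:
        drop = rng.random(geno.shape) < missing_rate
        geno[drop & called] = MISSING
    if missing_individuals:
        idx = {s.sample_id: i for i, s in enumerate(samples)}
        for sid in missing_individuals:
            row = idx[sid]
            drop = rng.random(geno.shape[1]) < individual_missing_rate
            geno[row, drop] = MISSING

    manifest = TruthManifest(
        generator="inject_artifacts",
        seed=seed,
        params=dict(n_replicate_pairs=n_replicate_pairs),
        missing_rate=missing_rate,
        allele_error_rate=allele_error_rate,
        replicate_pairs=pairs,
        planted=dict(
            missing_individuals=list(missing_individuals or []),
            individual_missing_rate=individual_missing_rate,
        ),
    )
    return GenotypeMatrix(geno, list(G.loci), samples), manifest


def expected_replicate_discordance(e: float) -> float:
    """Closed-form genotype discordance between two error-injected copies.

    Each copy independently perturbs the genotype: with probability
    (1-e)^2 it is unchanged, with 2e(1-e) it moves +-1 (capped), with e^2
    it moves +-2 (capped).  The discordance probability marginalizes over
    both copies; caps make it genotype-dependent, so this returns the
    value for a heterozygous cell (the dominant case at intermediate MAF)
    bracketed by homozygous cells in tests.
    """
    # heterozygote (dosage 1): P(stay) = (1-e)^2; P(go to 0) = P(go to 2)
    # = (2e(1-e) + e^2)/2 because the move direction is a fair coin.
    p_move = (2 * e * (1 - e) + e ** 2) / 2.0
    p_same = (1 - e) ** 4 + 2.0 * p_move ** 2
    return 1.0 - p_same


def write_fixture_directory(
    path,
    K_sites: int = 9,
    L: int = 300,
    n_per_site: int = 20,
    F: float = 0.01,
    seed: int | None = 0,
) -> dict:
    """Produce a complete miniature study directory (VCF, metadata, sites,
    distances, manifest) accepted unmodified by the package readers."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    G, manifest = generate_balding_nichols(
        K_sites=K_sites, n_per_site=n_per_site, L=L, F_per_site=F, seed=seed
    )
    rng = np.random.default_rng(seed)
    sites = sorted(set(G.site_codes))
    K = len(sites)
    lat = 43.0 + np.arange(K) * 1.8
    lon = -152.0 + np.arange(K) * 3.4
    states = ["AK"] * 3 + ["BC"] * 1 + ["WA"] * 4 + ["OR"] * 1
    ss = ["O"] * 5 + ["I"] * 3 + ["O"] * 1
    ps = ["O"] * 6 + ["I"] * 2 + ["O"] * 1
    npc = ["N"] * 4 + ["S"] * 5
    site_table = SiteTable(
        pd.DataFrame(
            dict(
                code=sites,
                name=[f"Site {s}" for s in sites],
                lat=lat[:K], long=lon[:K],
                state=(states * ((K // 9) + 1))[:K],
                salish_sea=(ss * ((K // 9) + 1))[:K],
                ps=(ps * ((K // 9) + 1))[:K],
                npc=(npc * ((K // 9) + 1))[:K],
            )
        )
    )
    pos = np.cumsum(rng.uniform(80, 400, size=K)) - 80
    dist = pd.DataFrame(
        np.abs(pos[:, None] - pos[None, :]), index=sites, columns=sites
    )

    write_vcf(G, path / "genotypes.vcf")
    write_sample_metadata(G.samples, path / "samples.tsv")
    site_table.write(path / "sites.tsv")
    write_distance_matrix(dist, path / "distances.tsv")
    manifest.write(path / "truth.json")
    return dict(
        vcf=path / "genotypes.vcf",
        samples=path / "samples.tsv",
        sites=path / "sites.tsv",
        distances=path / "distances.tsv",
        manifest=path / "truth.json",
    )
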