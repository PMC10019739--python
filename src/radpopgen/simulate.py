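"""Two-deme forward-time Wright-Fisher drift-migration simulator.

Two populations of constant diploid size Ne split from an infinitely large
ancestral pool with known allele frequencies and exchange migrants at rate
m per generation.  Each generation applies migration (frequency mixing at
rate m) followed by binomial resampling of 2*Ne allele copies per locus —
the exact per-locus marginal of random mating with random biparental
choice with replacement, no selection and free recombination.  Pairwise
Weir-Cockerham theta between the two full demes, averaged over replicates,
maps each (Ne, m, T) grid cell to below / within / above an empirical FST
range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LocusInfo, SampleInfo

logger = logging.getLogger(__name__)

#: Study-shaped defaults for the simulation grid.
DEFAULT_NE = (500, 2500, 10000)
DEFAULT_M = (1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3)
DEFAULT_T = (10, 100, 1000)
DEFAULT_L = 1864  # neutral SNP count used to parameterize ancestral frequencies
DEFAULT_N_REPS = 5


@dataclass
class SimParams:
    """Parameters for one simulation cell."""

    Ne: int
    m: float
    T: int
    L: int = DEFAULT_L
    p0: np.ndarray | None = None
    n_reps: int = DEFAULT_N_REPS
    seed: int | None = None
    migration: str = "deterministic"  # or "stochastic" migrant counts

    def __post_init__(self) -> None:
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")
        if not 0.0 <= self.m <= 0.5:
            raise ValueError("m must lie in [0, 0.5]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.migration not in ("deterministic", "stochastic"):
            raise ValueError("migration must be 'deterministic' or 'stochastic'")
        if self.p0 is not None:
            self.p0 = np.asarray(self.p0, dtype=float)
            if np.any((self.p0 <= 0) | (self.p0 >= 1)):
                raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
            self.L = len(self.p0)


@dataclass
class SimState:
    """Per-deme per-locus alt-allele counts and the generation counter."""

    counts: np.ndarray  # shape (2, L), integer allele copies out of 2*Ne
    Ne: int
    generation: int = 0

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / (2.0 * self.Ne)


def default_p0(L: int = DEFAULT_L, rng: np.random.Generator | None = None) -> np.ndarray:
    """Ancestral frequencies drawn uniform on [0.05, 0.95] (MAF-filtered shape)."""
    rng = rng if rng is not None else np.random.default_rng()
    return rng.uniform(0.05, 0.95, size=L)


def init_populations(
    p0: np.ndarray, Ne: int, seed: int | np.random.Generator | None = None
) -> SimState:
    """Sample both demes from the ancestral pool: counts ~ Binomial(2*Ne, p0)."""
    p0 = np.asarray(p0, dtype=float)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.binomial(2 * Ne, p0, size=(2, len(p0)))
    return SimState(counts=counts, Ne=Ne)


def step(
    state: SimState,
    m: float,
    rng: np.random.Generator,
    migration: str = "deterministic",
) -> SimState:
    """One generation: migration then binomial reproduction.

    Deterministic migration mixes frequencies, p_i' = (1-m) p_i + m p_j,
    keeping replicate variance attributable to drift.  Stochastic mode
    instead draws a binomial number of migrant allele copies each way.
    """
    p = state.freqs
    if migration == "deterministic":
        p_mig = np.empty_like(p)
        p_mig[0] = (1.0 - m) * p[0] + m * p[1]
        p_mig[1] = (1.0 - m) * p[1] + m * p[0]
    else:
        n = 2 * state.Ne
        out0 = rng.binomial(n, m)   # allele copies emigrating each way
        out1 = rng.binomial(n, m)
        # hypergeometric draw of which copies leave, per locus
        leave0 = rng.hypergeometric(state.counts[0], n - state.counts[0], out0)
        leave1 = rng.hypergeometric(state.counts[1], n - state.counts[1], out1)
        c0 = state.counts[0] - leave0 + leave1
        c1 = state.counts[1] - leave1 + leave0
        tot0 = n - out0 + out1
        tot1 = n - out1 + out0
        p_mig = np.stack([c0 / np.maximum(tot0, 1), c1 / np.maximum(tot1, 1)])
    counts = rng.binomial(2 * state.Ne, np.clip(p_mig, 0.0, 1.0))
    return SimState(counts=counts, Ne=state.Ne, generation=state.generation + 1)


def _theta_from_counts(counts: np.ndarray, Ne: int) -> float:
    """Pairwise WC theta treating each full deme as a sampled population.

    Uses the allele-frequency route: per-deme genotype heterozygosity is
    taken at its Hardy-Weinberg value, consistent with random mating in
    the model.  Works directly from allele counts, avoiding construction
    of 2*Ne individuals.
    """
    r = 2
    n = float(Ne)
    p_i = counts / (2.0 * n)
    h_i = 2.0 * p_i * (1.0 - p_i)  # HWE within demes
    nbar = n
    nc = n  # equal sizes
    pbar = p_i.mean(axis=0)
    s2 = ((p_i - pbar) ** 2).sum(axis=0) / (r - 1) / nbar * n
    hbar = h_i.mean(axis=0)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    mono = (pbar <= 0.0) | (pbar >= 1.0)
    a[mono] = b[mono] = c[mono] = 0.0
    denom = a.sum() + b.sum() + c.sum()
    if denom == 0.0:
        raise ValueError("theta undefined: all loci fixed identically in both demes")
    return float(a.sum() / denom)


def run_cell(params: SimParams) -> list[float]:
    """Replicate thetas for one (Ne, m, T) cell; failed replicates are skipped."""
    ss = np.random.SeedSequence(params.seed)
    thetas = []
    p0 = params.p0
    for child in ss.spawn(params.n_reps):
        rng = np.random.default_rng(child)
        p = p0 if p0 is not None else default_p0(params.L, rng)
        state = init_populations(p, params.Ne, rng)
        for _ in range(params.T):
            state = step(state, params.m, rng, params.migration)
        try:
            thetas.append(_theta_from_counts(state.counts, params.Ne))
        except ValueError:
            logger.warning(
                "replicate with all loci identically fixed at Ne=%d m=%g T=%d",
                params.Ne, params.m, params.T,
            )
    return thetas


@dataclass
class SimResult:
    """Mean pairwise theta per grid cell with a below/within/above label."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: Ne, m, T, n_reps_ok, mean_theta, rep thetas as list column

    def classified(self) -> pd.DataFrame:
        return self.table

    def write(self, path) -> None:
        long = self.table.copy()
        long["thetas"] = long["thetas"].apply(
            lambda v: ",".join(f"{t:.6g}" for t in v)
        )
        long.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_grid(
    p0: np.ndarray | None = None,
    Ne_list=DEFAULT_NE,
    m_list=DEFAULT_M,
    T_list=DEFAULT_T,
    L: int = DEFAULT_L,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    migration: str = "deterministic",
) -> SimResult:
    """Run the full (Ne, m, T) grid, averaging theta over replicates."""
    ss = np.random.SeedSequence(seed)
    cells = [(Ne, m, T) for Ne in Ne_list for m in m_list for T in T_list]
    rows = []
    for (Ne, m, T), child in zip(cells, ss.spawn(len(cells))):
        params = SimParams(
            Ne=Ne, m=m, T=T, L=L, p0=p0, n_reps=n_reps,
            seed=int(child.generate_state(1)[0] % (2**31)), migration=migration,
        )
        thetas = run_cell(params)
        rows.append(
            dict(
                Ne=Ne, m=m, T=T,
                n_reps_ok=len(thetas),
                mean_theta=float(np.mean(thetas)) if thetas else np.nan,
                thetas=thetas,
            )
        )
    return SimResult(table=pd.DataFrame(rows))


def classify_cells(
    result: SimResult, theta_min: float, theta_max: float
) -> SimResult:
    """Label each cell below / within / above the empirical theta range.

    Bounds are inclusive: a mean exactly at either bound is "within".
    """
    if theta_min > theta_max:
        raise ValueError("theta_min must be <= theta_max")

    def label(mean):
        if np.isnan(mean):
            return "undefined"
        if mean < theta_min:
            return "below"
        if mean > theta_max:
            return "above"
        return "within"

    result.table["label"] = result.table["mean_theta"].map(label)
    return result


def sample_individuals(
    state: SimState, n_per_deme: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Draw HWE genotype samples from the final deme frequencies.

    Utility for tests and the stepping-stone generator; genotypes are
    binomial(2, p_deme) per individual per locus.
    """
    L = state.counts.shape[1]
    p = state.freqs
    geno = np.concatenate(
        [rng.binomial(2, p[d], size=(n_per_deme, L)) for d in range(p.shape[0])]
    ).astype(np.int8)
    samples = [
        SampleInfo(f"d{d}_i{i}", f"deme{d}")
        for d in range(p.shape[0])
        for i in range(n_per_deme)
    ]
    loci = [
        LocusInfo(f"sim_{j}", f"simtag_{j}", 1, "A", "C", 99.0) for j in range(L)
    ]
    return GenotypeMatrix(geno, loci, samples)
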