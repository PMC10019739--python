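"""Config-driven orchestration of the full analysis.

Stage order mirrors the analysis workflow: QC cascade -> diversity / FST /
genic tests -> AMOVA groupings -> adaptive/neutral partition (when evidence
tables are supplied) -> per-SNP-set FST / AMOVA / IBD / dispersal -> drift
simulator grid -> tile classification.  Every table carries a provenance
header (seed, thresholds); all randomness flows from the master seed
through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import amova as amova_mod
from . import diversity, ibd, qc, simulate
from .genotypes import (
    GenotypeMatrix,
    SiteTable,
    read_distance_matrix,
    read_sample_metadata,
    read_vcf,
)
from .partition import EvidenceTable, Partition, classify

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs, thresholds and grid definitions for one run."""

    vcf: str
    samples: str
    sites: str | None = None
    distances: str | None = None
    evidence: dict | None = None       # paths to evidence tables (optional)
    out_dir: str = "radpopgen_out"
    seed: int = 0
    # filters
    min_qual: float = 20.0
    min_maf: float = 0.05
    max_locus_missing: float = 0.30
    max_ind_missing: float = 0.30
    hwe_alpha: float = 0.05
    hwe_min_failing_sites: int = 2
    one_snp_per_tag: bool = True
    # inference
    n_perm_amova: int = 1000
    n_perm_mantel: int = 9999
    n_perm_genic: int = 1000
    n_boot: int = 1000
    densities: tuple = ibd.DEFAULT_DENSITIES
    # simulator
    sim_Ne: tuple = simulate.DEFAULT_NE
    sim_m: tuple = simulate.DEFAULT_M
    sim_T: tuple = simulate.DEFAULT_T
    sim_L: int = simulate.DEFAULT_L
    sim_reps: int = simulate.DEFAULT_N_REPS
    run_simulations: bool = True
    run_genic_tests: bool = False      # costly; off by default
    snp_sets: tuple = ("all",)         # extended to neutral/adaptive if evidence given

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for key in ("vcf", "samples"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {key} path does not exist: {p}")
        for key in ("sites", "distances"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {key} path does not exist: {p}")


def _provenance_header(cfg: RunConfig, stage: str, seed: int) -> str:
    digest = hashlib.sha256(
        f"{cfg.vcf}|{cfg.samples}|{cfg.min_maf}|{cfg.max_locus_missing}".encode()
    ).hexdigest()[:12]
    return (
        f"# stage={stage} seed={seed} inputs_hash={digest} "
        f"min_maf={cfg.min_maf} max_locus_missing={cfg.max_locus_missing}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str, seed: int,
                 index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg, stage, seed))
        df.to_csv(fh, sep="\t", na_rep=".", index=index, float_format="%.6g")


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_qc(cfg: RunConfig, G: GenotypeMatrix) -> tuple[GenotypeMatrix, qc.FilterReport]:
    report = qc.FilterReport()
    G1, _ = qc.filter_snps(
        G, min_qual=cfg.min_qual, min_maf=cfg.min_maf,
        max_locus_missing=cfg.max_locus_missing, report=report,
    )
    if cfg.one_snp_per_tag:
        G1, _ = qc.select_snp_per_tag(G1, report=report)
    G1, _ = qc.filter_individuals(G1, max_ind_missing=cfg.max_ind_missing, report=report)
    if len(set(G1.site_codes)) >= 2:
        G1, hwe_res = qc.hwe_filter(
            G1, alpha=cfg.hwe_alpha, min_failing_sites=cfg.hwe_min_failing_sites
        )
        n_dropped = int((~hwe_res.keep).sum())
        report.add_step(
            "hwe", G1.n_loci + n_dropped, G1.n_loci, G1.n_samples, G1.n_samples
        )
    for s in report.steps:
        logger.info(
            "filter %-22s loci %5d -> %5d  individuals %4d -> %4d",
            s["filter_name"], s["n_loci_before"], s["n_loci_after"],
            s["n_individuals_before"], s["n_individuals_after"],
        )
    return G1, report


def _load_evidence(paths: dict) -> EvidenceTable:
    def flag_series(p):
        s = pd.read_csv(p, sep="\t", index_col=0).iloc[:, 0]
        return s.astype(bool)

    return EvidenceTable(
        bayescan=flag_series(paths["bayescan"]) if "bayescan" in paths else None,
        outflank=flag_series(paths["outflank"]) if "outflank" in paths else None,
        bayes_factors=pd.read_csv(paths["bayes_factors"], sep="\t", index_col=0)
        if "bayes_factors" in paths else None,
        rda_loadings=pd.read_csv(paths["rda_loadings"], sep="\t", index_col=0)
        if "rda_loadings" in paths else None,
    )


def run_all(cfg: RunConfig) -> Path:
    """Execute every stage; returns the report directory.

    A stage failure raises :class:`StageError` naming the stage; tables
    written by earlier stages are retained.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, e) from e

    # --- load + QC ---------------------------------------------------------
    samples = read_sample_metadata(cfg.samples)
    G0 = run_stage("read_vcf", lambda: read_vcf(cfg.vcf, samples))
    G, report = run_stage("qc", lambda: run_qc(cfg, G0))
    _write_table(report.to_frame(), out / "filter_report.tsv", cfg, "qc",
                 _stage_seed(cfg.seed, "qc"), index=False)

    pairs = qc.replicate_pairs_from_metadata(G)
    if pairs:
        err = run_stage("genotyping_error", lambda: qc.genotyping_error(G, pairs))
        logger.info("replicate discordance rate %.4f over %d comparisons",
                    err.rate, err.n_comparisons)
        _write_table(
            pd.DataFrame([{"rate": err.rate, "n_pairs": err.n_pairs,
                           "n_comparisons": err.n_comparisons}]),
            out / "genotyping_error.tsv", cfg, "genotyping_error",
            _stage_seed(cfg.seed, "error"), index=False,
        )
        # analyses exclude replicate copies
        keep = [i for i, s in enumerate(G.samples) if s.is_replicate_of is None]
        G = G.take_samples(keep)

    site_table = SiteTable.read(cfg.sites) if cfg.sites else None
    dist = read_distance_matrix(cfg.distances) if cfg.distances else None

    # --- partition ----------------------------------------------------------
    snp_sets: dict[str, GenotypeMatrix] = {"all": G}
    partition: Partition | None = None
    if cfg.evidence:
        evidence = run_stage("evidence", lambda: _load_evidence(cfg.evidence))
        partition = run_stage(
            "classify", lambda: classify(evidence, G.locus_ids)
        )
        partition.write(out / "partition.tsv")
        if partition.neutral:
            snp_sets["neutral"] = G.select_loci(partition.neutral)
        if partition.adaptive:
            snp_sets["adaptive"] = G.select_loci(partition.adaptive)

    # --- per-SNP-set analyses ----------------------------------------------
    empirical_range = None
    for label, Gs in snp_sets.items():
        seed_div = _stage_seed(cfg.seed, f"diversity:{label}")
        div = run_stage("site_diversity", lambda Gs=Gs: diversity.site_diversity(Gs))
        _write_table(div.table, out / f"diversity_{label}.tsv", cfg,
                     f"diversity:{label}", seed_div)

        if len(set(Gs.site_codes)) >= 2:
            fst = run_stage("wc_theta", lambda Gs=Gs: diversity.wc_theta(Gs))
            ci = diversity.theta_bootstrap_ci(fst, n_boot=cfg.n_boot, seed=seed_div)
            pw = run_stage("pairwise_theta", lambda Gs=Gs: diversity.pairwise_theta(Gs))
            _write_table(pw.theta, out / f"pairwise_fst_{label}.tsv", cfg,
                         f"fst:{label}", seed_div)
            _write_table(
                pd.DataFrame([{"theta": fst.theta, "ci_low": ci[0], "ci_high": ci[1]}]),
                out / f"global_fst_{label}.tsv", cfg, f"fst:{label}", seed_div,
                index=False,
            )
            if label == "all":
                vals = pw.theta.to_numpy()
                finite = vals[np.isfinite(vals)]
                if finite.size:
                    empirical_range = (float(finite.min()), float(finite.max()))

            if cfg.run_genic_tests:
                gt = run_stage(
                    "genic_tests",
                    lambda Gs=Gs: diversity.pairwise_genic_tests(
                        Gs, n_perm=cfg.n_perm_genic,
                        seed=_stage_seed(cfg.seed, f"genic:{label}"),
                    ),
                )
                _write_table(gt, out / f"genic_p_{label}.tsv", cfg,
                             f"genic:{label}", seed_div)

            if site_table is not None:
                res = run_stage(
                    "amova",
                    lambda Gs=Gs: amova_mod.run_standard_groupings(
                        Gs, site_table, n_perm=cfg.n_perm_amova,
                        seed=_stage_seed(cfg.seed, f"amova:{label}"),
                    ),
                )
                _write_table(
                    amova_mod.results_table(res), out / f"amova_{label}.tsv",
                    cfg, f"amova:{label}", _stage_seed(cfg.seed, f"amova:{label}"),
                    index=False,
                )

            if dist is not None:
                reg = run_stage(
                    "ibd",
                    lambda Gs=Gs, label=label: diversity.pairwise_theta(Gs),
                )
                reg_res = run_stage(
                    "ibd",
                    lambda reg=reg, label=label: ibd.ibd_regression(
                        reg.theta, dist, snp_set=label,
                        n_perm=cfg.n_perm_mantel,
                        seed=_stage_seed(cfg.seed, f"ibd:{label}"),
                    ),
                )
                _write_table(
                    pd.DataFrame([reg_res.summary_row()]),
                    out / f"ibd_{label}.tsv", cfg, f"ibd:{label}",
                    _stage_seed(cfg.seed, f"ibd:{label}"), index=False,
                )
                if reg_res.slope > 0:
                    table = ibd.dispersal_distance(
                        {label: reg_res.slope}, densities=cfg.densities
                    )
                    _write_table(table.rounded, out / f"dispersal_{label}.tsv",
                                 cfg, f"dispersal:{label}",
                                 _stage_seed(cfg.seed, f"ibd:{label}"))
            elif dist is None:
                logger.info("no distance matrix supplied; IBD stage skipped")

    # --- simulator -----------------------------------------------------------
    if cfg.run_simulations:
        sim = run_stage(
            "simulate",
            lambda: simulate.run_grid(
                Ne_list=cfg.sim_Ne, m_list=cfg.sim_m, T_list=cfg.sim_T,
                L=cfg.sim_L, n_reps=cfg.sim_reps,
                seed=_stage_seed(cfg.seed, "simulate"),
            ),
        )
        if empirical_range is not None:
            simulate.classify_cells(sim, *empirical_range)
        sim.write(out / "simulation_grid.tsv")

    return out
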