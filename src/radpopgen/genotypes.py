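"""Canonical in-memory genotype container and readers/writers.

Genotypes are stored as diploid alt-allele dosages (0, 1, 2) with a single
missing marker (:data:`MISSING`).  Phase is discarded: no analysis in this
package uses it.  VCF positions are kept 1-based and internal locus order is
file order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-genotype marker in the dosage matrix.
MISSING: int = -1


class GenotypeIOError(ValueError):
    """Raised on malformed input files or metadata mismatches."""


@dataclass(frozen=True)
class LocusInfo:
    """One SNP (or flagged non-SNP record) and where it came from.

    ``tag_id`` is the RAD tag / contig of origin (VCF CHROM); ``position``
    is the 1-based coordinate on that tag.  Records that are not biallelic
    SNPs are retained with ``is_snp`` / ``is_biallelic`` flags so that the
    QC cascade can drop them with attribution.
    """

    locus_id: str
    tag_id: str
    position: int
    ref_allele: str
    alt_allele: str
    qual: float
    is_snp: bool = True
    is_biallelic: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.locus_id}")
        if self.qual < 0:
            raise ValueError(f"negative QUAL at {self.locus_id}")


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced individual: id, collection site, optional replicate link."""

    sample_id: str
    site_code: str
    is_replicate_of: str | None = None


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosage matrix with registries.

    Invariants checked at construction: shape matches the registries, all
    dosages are in {0, 1, 2, MISSING}, and ids are unique.
    """

    genotypes: np.ndarray
    loci: list[LocusInfo]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} != "
                f"({len(self.samples)} samples, {len(self.loci)} loci)"
            )
        ok = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.genotypes[~ok])
            raise ValueError(f"invalid dosage codes {bad.tolist()}")
        if len({l.locus_id for l in self.loci}) != len(self.loci):
            raise ValueError("duplicate locus ids")
        if len({s.sample_id for s in self.samples}) != len(self.samples):
            raise ValueError("duplicate sample ids")
        for s in self.samples:
            if s.is_replicate_of is not None:
                if s.is_replicate_of == s.sample_id:
                    raise ValueError(f"{s.sample_id} is a replicate of itself")
                if s.is_replicate_of not in {t.sample_id for t in self.samples}:
                    raise ValueError(
                        f"{s.sample_id} replicates unknown sample {s.is_replicate_of}"
                    )

    # -- registry accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def site_codes(self) -> np.ndarray:
        """Per-sample site code, in sample order."""
        return np.array([s.site_code for s in self.samples])

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id}") from None

    # -- subsetting ---------------------------------------------------------
    def take_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.genotypes[:, index],
            [self.loci[i] for i in index],
            list(self.samples),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        kept_ids = {self.samples[i].sample_id for i in index}
        samples = []
        for i in index:
            s = self.samples[i]
            if s.is_replicate_of is not None and s.is_replicate_of not in kept_ids:
                s = replace(s, is_replicate_of=None)
            samples.append(s)
        return GenotypeMatrix(self.genotypes[index, :], list(self.loci), samples)

    def select_loci(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(locus_ids)
        idx = [i for i, l in enumerate(self.loci) if l.locus_id in wanted]
        missing = wanted - {self.loci[i].locus_id for i in idx}
        if missing:
            raise KeyError(f"unknown loci: {sorted(missing)}")
        return self.take_loci(idx)

    # -- elementwise summaries ---------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.loci == other.loci
            and self.samples == other.samples
        )


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Per-group, per-locus alt-allele frequency and call counts.

    ``freq`` is NaN where a group has zero calls at a locus (undefined, not
    zero).  Frequencies are alt-allele counts over ``2 * n_called``.
    """

    freq: pd.DataFrame      # groups x loci
    n_called: pd.DataFrame  # groups x loci, individuals with a call


def allele_frequencies(
    G: GenotypeMatrix, grouping: Mapping[str, str] | Sequence[str] | None = None
) -> AlleleFrequencies:
    """Alt-allele frequency per group per locus.

    ``grouping`` maps every sample_id to a group label (or is a per-sample
    label sequence in sample order).  ``None`` groups samples by site code.
    """
    if grouping is None:
        labels = G.site_codes
    elif isinstance(grouping, Mapping):
        try:
            labels = np.array([grouping[s.sample_id] for s in G.samples])
        except KeyError as e:
            raise GenotypeIOError(f"sample missing from grouping: {e}") from None
    else:
        labels = np.asarray(list(grouping))
        if len(labels) != G.n_samples:
            raise GenotypeIOError("grouping length != number of samples")

    groups = list(dict.fromkeys(labels))  # first-appearance order
    geno = G.genotypes
    called = geno != MISSING
    freq_rows, n_rows = [], []
    for g in groups:
        sel = labels == g
        n = called[sel].sum(axis=0)
        alt = np.where(called[sel], geno[sel], 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, alt / (2.0 * n), np.nan)
        freq_rows.append(f)
        n_rows.append(n)
    ids = G.locus_ids
    return AlleleFrequencies(
        freq=pd.DataFrame(freq_rows, index=groups, columns=ids, dtype=float),
        n_called=pd.DataFrame(n_rows, index=groups, columns=ids, dtype=int),
    )


# ---------------------------------------------------------------------------
# Site metadata and distance matrices
# ---------------------------------------------------------------------------

class SiteTable:
    """Collection-site registry: coordinates plus grouping labels.

    Columns: ``code``, ``name``, ``lat``, ``long``, ``state``,
    ``salish_sea`` (I/O, inside or outside the Salish Sea), ``ps`` (I/O,
    inside or outside Puget Sound proper, i.e. south of Admiralty Inlet)
    and ``npc`` (N/S of the North Pacific Current bifurcation).
    """

    REQUIRED = ("code", "name", "lat", "long", "state", "salish_sea", "ps", "npc")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise GenotypeIOError(f"site table missing columns {missing}")
        if table["code"].duplicated().any():
            raise GenotypeIOError("duplicate site codes")
        if not table["lat"].between(-90, 90).all():
            raise GenotypeIOError("latitude outside [-90, 90]")
        if not table["long"].between(-180, 180).all():
            raise GenotypeIOError("longitude outside [-180, 180]")
        self.table = table.reset_index(drop=True)

    @property
    def codes(self) -> list[str]:
        return self.table["code"].tolist()

    def label(self, column: str) -> dict[str, str]:
        """Site code -> label for one grouping column."""
        if column not in self.table.columns:
            raise KeyError(f"no such site label column: {column}")
        return dict(zip(self.table["code"], self.table[column].astype(str)))

    @classmethod
    def read(cls, path) -> "SiteTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"code": str}))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep=".")


def read_sample_metadata(path) -> list[SampleInfo]:
    """Tab-separated sample table: sample_id, site_code, is_replicate_of ('.' = none)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "site_code"):
        if col not in df.columns:
            raise GenotypeIOError(f"sample metadata missing column {col}")
    out = []
    for _, row in df.iterrows():
        rep = row.get("is_replicate_of")
        if rep in (None, ".", "") or pd.isna(rep):
            rep = None
        out.append(SampleInfo(row["sample_id"], row["site_code"], rep))
    return out


def write_sample_metadata(samples: Sequence[SampleInfo], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "site_code": [s.site_code for s in samples],
            "is_replicate_of": [s.is_replicate_of or "." for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def validate_distance_matrix(dist: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    """Check a site x site in-water distance matrix (km): square, symmetric,
    zero diagonal, non-negative."""
    if list(dist.index) != list(dist.columns):
        raise GenotypeIOError("distance matrix index and columns differ")
    a = dist.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise GenotypeIOError("distance matrix not square")
    if not np.allclose(a, a.T, atol=atol):
        raise GenotypeIOError("distance matrix not symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=atol):
        raise GenotypeIOError("distance matrix diagonal not zero")
    if (a < -atol).any():
        raise GenotypeIOError("negative distances")
    return dist


def read_distance_matrix(path) -> pd.DataFrame:
    return validate_distance_matrix(pd.read_csv(path, sep="\t", index_col=0))


def write_distance_matrix(dist: pd.DataFrame, path) -> None:
    validate_distance_matrix(dist).to_csv(path, sep="\t", na_rep=".")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_metadata: Sequence[SampleInfo]) -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    One column per record, in file order.  ``./.`` maps to MISSING; phased
    and unphased genotypes are treated identically.  Indels and
    multi-allelic records are retained but flagged (``is_snp`` /
    ``is_biallelic``) so that QC can drop them; a genotype carrying an
    allele index above 1 is stored as MISSING at that cell.

    Every VCF sample must appear in ``sample_metadata``.
    """
    from cyvcf2 import VCF

    meta = {s.sample_id: s for s in sample_metadata}
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as e:  # htslib raises bare exceptions on bad files
        raise GenotypeIOError(f"cannot parse VCF {path}: {e}") from e

    unknown = [s for s in vcf.samples if s not in meta]
    if unknown:
        raise GenotypeIOError(
            f"VCF samples absent from metadata: {unknown}"
        )
    samples = [meta[s] for s in vcf.samples]

    loci: list[LocusInfo] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for i, v in enumerate(vcf):
        alts = v.ALT or ["."]
        is_biallelic = len(alts) == 1
        alt0 = alts[0]
        is_snp = len(v.REF) == 1 and all(len(a) == 1 for a in alts) and alt0 != "."
        locus_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if locus_id in seen:
            locus_id = f"{locus_id}#{i}"
        seen.add(locus_id)
        loci.append(
            LocusInfo(
                locus_id=locus_id,
                tag_id=v.CHROM,
                position=v.POS,
                ref_allele=v.REF,
                alt_allele=alt0,
                # htslib stores QUAL as float32; round away the excess digits
                qual=round(float(v.QUAL), 3) if v.QUAL is not None else 0.0,
                is_snp=is_snp,
                is_biallelic=is_biallelic,
            )
        )
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        col = np.asarray(v.gt_types, dtype=np.int8)
        col[col == 3] = MISSING
        if not is_biallelic:
            # any call touching allele index >= 2 is unusable as a dosage
            gt = np.asarray(v.genotypes, dtype=object)
            for j, g in enumerate(gt):
                if any(isinstance(a, int) and a >= 2 for a in g[:-1]):
                    col[j] = MISSING
        columns.append(col)

    if not columns:
        raise GenotypeIOError(f"VCF {path} contains no records")
    return GenotypeMatrix(np.stack(columns, axis=1), loci, samples)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields from the dosage matrix."""
    tags = list(dict.fromkeys(l.tag_id for l in G.loci))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for t in tags:
            fh.write(f"##contig=<ID={t}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, l in enumerate(G.loci):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in G.genotypes[:, j])
            fh.write(
                f"{l.tag_id}\t{l.position}\t{l.locus_id}\t{l.ref_allele}\t"
                f"{l.alt_allele}\t{l.qual:g}\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# genepop dialect
# ---------------------------------------------------------------------------
# Two-digit allele codes: ref = 01, alt = 02, missing = 0000.  One POP block
# per site, in site first-appearance order.  Sample labels are written as
# "site:sample_id" so site assignment survives the round trip.

_DOSAGE_TO_GENEPOP = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
_GENEPOP_TO_DOSAGE = {v: k for k, v in _DOSAGE_TO_GENEPOP.items()}
_GENEPOP_TO_DOSAGE["0201"] = 1  # allele order is unordered


def write_genepop(G: GenotypeMatrix, path, title: str = "radpopgen export") -> None:
    """Write a genepop file (2-digit allele coding, one POP block per site)."""
    bad = [l.locus_id for l in G.loci if not (l.is_snp and l.is_biallelic)]
    if bad:
        raise GenotypeIOError(
            f"genepop export supports biallelic SNPs only; offending loci: {bad[:5]}"
        )
    sites = list(dict.fromkeys(s.site_code for s in G.samples))
    site_arr = G.site_codes
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for l in G.loci:
            fh.write(l.locus_id + "\n")
        for site in sites:
            fh.write("POP\n")
            idx = np.flatnonzero(site_arr == site)
            if idx.size == 0:
                logger.warning("site %s has no individuals; empty POP block", site)
            for i in idx:
                row = " ".join(
                    _DOSAGE_TO_GENEPOP[int(d)] for d in G.genotypes[i, :]
                )
                fh.write(f"{site}:{G.samples[i].sample_id} ,  {row}\n")


def read_genepop(path) -> GenotypeMatrix:
    """Read a genepop file written in the 2-digit dialect of :func:`write_genepop`.

    Sample labels of the form ``site:sample_id`` restore site codes exactly;
    otherwise POP blocks are labelled POP1, POP2, ...
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GenotypeIOError(f"empty genepop file {path}")
    lines = lines[1:]  # title
    locus_names: list[str] = []
    i = 0
    while i < len(lines) and lines[i].strip().upper() != "POP":
        name = lines[i].strip()
        if name:
            # loci may also be comma-separated on one line
            locus_names.extend(x.strip() for x in name.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenotypeIOError("no POP line found")

    samples: list[SampleInfo] = []
    rows: list[list[int]] = []
    pop_no = 0
    for ln in lines[i:]:
        if ln.strip().upper() == "POP":
            pop_no += 1
            continue
        if not ln.strip():
            continue
        if "," not in ln:
            raise GenotypeIOError(f"malformed genepop row (no comma): {ln!r}")
        label, geno = ln.split(",", 1)
        label = label.strip()
        if ":" in label:
            site, sample_id = label.split(":", 1)
        else:
            site, sample_id = f"POP{pop_no}", label
        codes = geno.split()
        if len(codes) != len(locus_names):
            raise GenotypeIOError(
                f"row {sample_id!r} has {len(codes)} genotypes, "
                f"expected {len(locus_names)}"
            )
        try:
            rows.append([_GENEPOP_TO_DOSAGE[c] for c in codes])
        except KeyError as e:
            raise GenotypeIOError(f"bad genepop code {e} in row {sample_id!r}") from None
        samples.append(SampleInfo(sample_id, site))

    loci = [
        LocusInfo(
            locus_id=name, tag_id=name, position=1, ref_allele="A",
            alt_allele="C", qual=0.0,
        )
        for name in locus_names
    ]
    return GenotypeMatrix(np.array(rows, dtype=np.int8), loci, samples)
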