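"""Genotype input/output and cohort-level QC.

Parses a multi-sample VCF into a dense alt-allele dosage matrix, applies
GATK-style per-site hard filters and cohort-level frequency/missingness
filters, and computes per-population alternate-allele frequencies — the
substrate for every downstream selection statistic.

Coordinates are VCF 1-based throughout; conversion to 0-based half-open
happens only at BED export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscan")

#: sentinel for an uncalled genotype in the dosage matrix
MISSING = -1

#: INFO metrics the hard filter inspects, with (bound, direction).
#: direction "gt" keeps sites with value > bound, "lt" keeps value < bound.
HARD_FILTER_BOUNDS: dict[str, tuple[float, str]] = {
    "QUAL": (30.0, "gt"),
    "QD": (5.0, "gt"),
    "FS": (60.0, "lt"),
    "MQ": (40.0, "gt"),
    "MQRankSum": (-12.5, "gt"),
    "ReadPosRankSum": (-8.0, "gt"),
}

INFO_METRIC_NAMES = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_BASES = frozenset("ACGT")


@dataclass
class VariantSite:
    """A biallelic SNP site with optional quality annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    info_metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only biallelic SNPs allowed, got {self.ref}>{self.alt} "
                f"at {self.chrom}:{self.pos}"
            )


class GenotypeMatrix:
    """Sites x samples alt-allele dosage matrix (0/1/2, MISSING = -1).

    Sites are stored column-wise as parallel numpy arrays (chrom, pos, ref,
    alt, qual) plus an optional ``info`` DataFrame holding the hard-filter
    metrics. Rows are sorted by (chrom, pos) with no duplicate coordinates.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        samples: Sequence[str],
        dosage: np.ndarray,
        qual: np.ndarray | None = None,
        info: pd.DataFrame | None = None,
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.samples = list(samples)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        self.qual = (
            np.full(len(self.pos), np.nan) if qual is None else np.asarray(qual, float)
        )
        self.info = info
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        self._check_sorted()

    def _check_sorted(self) -> None:
        key = list(zip(self.chrom, self.pos))
        if any(key[i] >= key[i + 1] for i in range(len(key) - 1)):
            raise ValueError("sites must be sorted by (chrom, pos) with no duplicates")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sites(self) -> list[VariantSite]:
        """Materialize per-site records (convenience view; O(n_sites))."""
        out = []
        has_info = self.info is not None
        for i in range(self.n_sites):
            metrics = {}
            if has_info:
                row = self.info.iloc[i]
                metrics = {k: float(row[k]) for k in self.info.columns if pd.notna(row[k])}
            q = None if np.isnan(self.qual[i]) else float(self.qual[i])
            out.append(
                VariantSite(self.chrom[i], int(self.pos[i]), self.ref[i], self.alt[i], q, metrics)
            )
        return out

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row-subset preserving order."""
        return GenotypeMatrix(
            self.chrom[idx],
            self.pos[idx],
            self.ref[idx],
            self.alt[idx],
            self.samples,
            self.dosage[idx],
            self.qual[idx],
            None if self.info is None else self.info.iloc[np.asarray(idx)].reset_index(drop=True),
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        missing = [s for s in names if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            self.chrom, self.pos, self.ref, self.alt, list(names),
            self.dosage[:, cols], self.qual, self.info,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.dosage, other.dosage)
        )


class PopulationMap:
    """sample -> population label mapping defining the comparison pairs."""

    def __init__(self, assignment: Mapping[str, str]):
        self.assignment = dict(assignment)

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        """Read a two-column `sample<TAB>population` TSV (no header)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str)
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate samples in population map: {dups}")
        return cls(dict(zip(df["sample"], df["population"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignment.items():
                fh.write(f"{s}\t{p}\n")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == population]

    def indices(self, population: str, samples: Sequence[str]) -> np.ndarray:
        """Column indices of a population's samples within ``samples``."""
        members = set(self.samples_of(population))
        idx = np.array([i for i, s in enumerate(samples) if s in members], dtype=int)
        if idx.size == 0:
            raise KeyError(f"population {population!r} has no samples in the matrix")
        return idx

    def validate(self, samples: Iterable[str]) -> None:
        unlabeled = [s for s in samples if s not in self.assignment]
        if unlabeled:
            raise ValueError(f"samples without population label: {unlabeled}")


# ---------------------------------------------------------------------------
# VCF parsing / writing
# ---------------------------------------------------------------------------

def parse_vcf(path, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Parse a VCF into a GenotypeMatrix of biallelic SNPs.

    Multiallelic records and non-SNP records (indels, symbolic alleles) are
    excluded with a logged count. Missing genotypes (./.) become MISSING.

    Parameters
    ----------
    path
        VCF file, plain or bgzipped.
    sample_subset
        Restrict to these samples (order preserved as given).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in header_samples]
        if absent:
            raise KeyError(f"samples not in VCF header: {absent}")
        vcf.close()
        vcf = VCF(str(path), gts012=True, samples=list(sample_subset))
    samples = list(vcf.samples)

    chroms, poss, refs, alts, quals = [], [], [], [], []
    dosages = []
    info_rows = []
    n_excluded = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_excluded += 1
            continue
        # gts012: 0=hom-ref 1=het 2=hom-alt 3=unknown
        gt = v.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        dosages.append(gt)
        info_rows.append([v.INFO.get(k) for k in INFO_METRIC_NAMES])
    vcf.close()
    if n_excluded:
        logger.info("parse_vcf: excluded %d multiallelic/non-SNP records", n_excluded)

    if not poss:
        dosage = np.empty((0, len(samples)), dtype=np.int8)
        info = pd.DataFrame(columns=list(INFO_METRIC_NAMES), dtype=float)
        return GenotypeMatrix(
            np.array([], dtype=object), np.array([], dtype=np.int64),
            np.array([], dtype=object), np.array([], dtype=object),
            samples, dosage, np.array([], dtype=float), info)

    info = pd.DataFrame(info_rows, columns=list(INFO_METRIC_NAMES), dtype=float)
    order = np.lexsort((np.asarray(poss), np.asarray(chroms, dtype=object)))
    mat = GenotypeMatrix(
        np.asarray(chroms, dtype=object)[order],
        np.asarray(poss, dtype=np.int64)[order],
        np.asarray(refs, dtype=object)[order],
        np.asarray(alts, dtype=object)[order],
        samples,
        np.vstack(dosages)[order],
        np.asarray(quals, float)[order],
        info.iloc[order].reset_index(drop=True),
    )
    mat.n_excluded_records = n_excluded  # type: ignore[attr-defined]
    return mat


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 text file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(matrix.chrom):
                fh.write(f"##contig=<ID={c}>\n")
        for k in INFO_METRIC_NAMES:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        has_info = matrix.info is not None
        for i in range(matrix.n_sites):
            qual = "." if np.isnan(matrix.qual[i]) else f"{matrix.qual[i]:g}"
            info_str = "."
            if has_info:
                row = matrix.info.iloc[i]
                parts = [f"{k}={row[k]:g}" for k in matrix.info.columns if pd.notna(row[k])]
                info_str = ";".join(parts) if parts else "."
            gts = "\t".join(_GT_STR[int(d)] for d in matrix.dosage[i])
            fh.write(f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                     f"{matrix.alt[i]}\t{qual}\t.\t{info_str}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def hard_filter_mask(matrix: GenotypeMatrix) -> tuple[np.ndarray, dict[str, int]]:
    """Vectorized hard-filter evaluation on a matrix.

    Returns (keep mask, removal counts per criterion). A site is kept iff
    every *available* metric satisfies its bound; missing metrics pass
    (GATK convention: un-annotated sites are not failed). A site failing
    several criteria is counted under each.
    """
    n = matrix.n_sites
    keep = np.ones(n, dtype=bool)
    report: dict[str, int] = {}
    for name, (bound, direction) in HARD_FILTER_BOUNDS.items():
        if name == "QUAL":
            vals = matrix.qual
        elif matrix.info is not None and name in matrix.info.columns:
            vals = matrix.info[name].to_numpy(float)
        else:
            vals = np.full(n, np.nan)
        with np.errstate(invalid="ignore"):
            fails = (vals <= bound) if direction == "gt" else (vals >= bound)
        fails &= ~np.isnan(vals)
        report[name] = int(fails.sum())
        keep &= ~fails
    return keep, report


def apply_hard_filters(sites: Sequence[VariantSite]) -> tuple[list[VariantSite], dict[str, int]]:
    """Filter per-site records by the GATK-style SNP criteria.

    Keeps a site iff QUAL > 30, QD > 5.0, FS < 60.0, MQ > 40.0,
    MQRankSum > -12.5 and ReadPosRankSum > -8.0, skipping any metric the
    site does not carry. Returns (kept sites, removals per criterion).
    """
    kept: list[VariantSite] = []
    report = {name: 0 for name in HARD_FILTER_BOUNDS}
    for s in sites:
        ok = True
        for name, (bound, direction) in HARD_FILTER_BOUNDS.items():
            val = s.qual if name == "QUAL" else s.info_metrics.get(name)
            if val is None:
                continue
            fails = (val <= bound) if direction == "gt" else (val >= bound)
            if fails:
                report[name] += 1
                ok = False
        if ok:
            kept.append(s)
    return kept, report


def hard_filter_matrix(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, dict[str, int]]:
    keep, report = hard_filter_mask(matrix)
    return matrix.take_sites(np.flatnonzero(keep)), report


def qc_filter(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    max_missing: float = 0.20,
) -> GenotypeMatrix:
    """Cohort-level site QC: MAF, call rate and missingness.

    Removes sites with pooled MAF strictly below ``maf_min`` (PLINK `--maf`
    convention: MAF exactly at the threshold is kept), call rate strictly
    below ``call_rate_min``, or missing fraction strictly above
    ``max_missing``. MAF pools all samples. Order is preserved; the filter
    is idempotent.
    """
    if matrix.n_sites == 0:
        raise ValueError("qc_filter: empty matrix")
    called = matrix.dosage != MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / matrix.n_samples
    alt_counts = np.where(called, matrix.dosage, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_called > 0, alt_counts / (2.0 * n_called), np.nan)
    maf = np.minimum(af, 1.0 - af)
    keep = (
        ~np.isnan(maf)
        & (maf >= maf_min)
        & (call_rate >= call_rate_min)
        & ((1.0 - call_rate) <= max_missing)
    )
    if not keep.any():
        logger.warning("qc_filter removed every site")
    return matrix.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(matrix: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-SNP per-population alternate-allele frequencies.

    AltAF_pop = (sum of dosages over called samples in pop) / (2 x called
    samples in pop); missing genotypes are excluded from numerator and
    denominator. A population with zero called samples at a site gets NaN
    (undefined) there.

    Returns a DataFrame with columns chrom, pos and, per population,
    ``af_<pop>`` and ``n_called_<pop>`` (called *alleles*, i.e. 2 x called
    individuals).
    """
    popmap.validate(matrix.samples)
    out = {"chrom": matrix.chrom, "pos": matrix.pos}
    called = matrix.dosage != MISSING
    for pop in popmap.populations:
        idx = popmap.indices(pop, matrix.samples)
        sub_called = called[:, idx]
        n_ind = sub_called.sum(axis=1)
        alt = np.where(sub_called, matrix.dosage[:, idx], 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            af = np.where(n_ind > 0, alt / (2.0 * n_ind), np.nan)
        out[f"af_{pop}"] = af
        out[f"n_called_{pop}"] = 2 * n_ind
    return pd.DataFrame(out)


def summarize_annotation_counts(category_counts: Mapping[str, float]) -> pd.DataFrame:
    """Tabulate category counts with percent-of-total (2 decimals).

    Accepts any non-negative counts (integers, or e.g. gigabases).
    """
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(category_counts.values())
    if total == 0:
        raise ValueError("total count is zero")
    rows = [
        (cat, count, round(100.0 * count / total, 2))
        for cat, count in category_counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
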