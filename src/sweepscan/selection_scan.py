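"""Sliding-window selective-sweep scan: Weir-Cockerham Fst and the
nucleotide-diversity (theta-pi) ratio.

The scan contrasts a target population against a control in overlapping
windows (default 100 kb, 10-kb step). Per window it reports the "weighted"
two-population Weir & Cockerham (1984) Fst, Sum(a)/Sum(a+b+c) over
polymorphic sites, and per-population windowed diversity pi (sum of per-site
heterozygosity over window length). Windows ranking in the top quantile of
both Fst and the ratio pi_control/pi_target are candidate sweeps; ratios
above 1 mean the target has lost diversity relative to the control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger("sweepscan")


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    snp_count: int = 0

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad window [{self.start}, {self.end}]")


@dataclass(frozen=True)
class FstComponents:
    """WC84 variance components at one site: among-population (a),
    among-individual-within-population (b), within-individual (c)."""

    a: float
    b: float
    c: float


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    max_fst: float
    max_theta_pi_ratio: float


def is_autosome(chrom: str) -> bool:
    """Numeric chromosome names (optionally 'chr'-prefixed) count as autosomes."""
    name = chrom.lower().removeprefix("chr")
    return name.isdigit()


def make_windows(
    chrom_lengths: Mapping[str, int], size: int = 100_000, step: int = 10_000
) -> list[Window]:
    """Sliding windows per chromosome: starts 1, 1+step, ... while start <=
    length; end = min(start+size-1, length). Trailing windows truncate."""
    if not (size >= step >= 1):
        raise ValueError(f"need size >= step >= 1, got size={size} step={step}")
    windows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}: {length}")
        start = 1
        while start <= length:
            windows.append(Window(chrom, start, min(start + size - 1, length)))
            start += step
    return windows


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------

def site_fst_components(
    n1: float, p1: float, h1: float, n2: float, p2: float, h2: float
) -> FstComponents:
    """Two-population Weir & Cockerham (1984) variance components at a site.

    Parameters are per population: n_i called individuals, p_i alt-allele
    frequency, h_i observed heterozygote fraction. Uses r=2,
    nbar=(n1+n2)/2, nc=(r*nbar - (n1^2+n2^2)/(r*nbar))/(r-1), frequency and
    heterozygosity means weighted by n_i, and
    s2 = sum n_i (p_i - pbar)^2 / ((r-1) nbar).

    Sites where both populations are monomorphic for the same allele yield
    a = b = c = 0 and contribute nothing to window sums.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one called individual per population")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    r = 2.0
    nbar = (n1 + n2) / r
    if nbar <= 1:
        # single individual per population: b undefined
        return FstComponents(0.0, 0.0, 0.0)
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    if pbar in (0.0, 1.0):
        return FstComponents(0.0, 0.0, 0.0)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return FstComponents(a, b, c)


def site_pi(alt_count: int, n_alleles: int) -> float:
    """Per-site nucleotide diversity: expected pairwise difference among the
    sampled alleles, 2*j*(n-j)/(n*(n-1)) for j alt alleles of n."""
    if n_alleles < 2:
        raise ValueError("need at least two called alleles")
    if not (0 <= alt_count <= n_alleles):
        raise ValueError("alt_count out of range")
    return 2.0 * alt_count * (n_alleles - alt_count) / (n_alleles * (n_alleles - 1.0))


def _per_site_arrays(matrix: GenotypeMatrix, idx: np.ndarray):
    """Called counts, alt counts, het counts for one population's columns."""
    sub = matrix.dosage[:, idx]
    called = sub != MISSING
    n_ind = called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    het = (sub == 1).sum(axis=1)
    return n_ind, alt, het


def _wc_components_vec(n1, p1, h1, n2, p2, h2):
    """Vectorized WC84 two-population components; returns (a, abc)."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2.0
    mono = (pbar <= 0.0) | (pbar >= 1.0) | (nbar <= 1)
    a = np.where(mono, 0.0, a)
    b = np.where(mono, 0.0, b)
    c = np.where(mono, 0.0, c)
    return a, a + b + c


def windowed_stats(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    target: str,
    control: str,
    windows: Sequence[Window],
    min_snps: int = 10,
) -> pd.DataFrame:
    """Per-window Fst, per-population pi and the theta-pi ratio.

    Window Fst = Sum(a)/Sum(a+b+c) over polymorphic sites; windowed pi =
    (sum of per-site pi)/(window length in bp); theta_pi_ratio =
    pi_control/pi_target. Windows with fewer than ``min_snps`` usable SNPs
    are dropped. Per-site sample sizes are the called individuals at that
    site; sites where either population has no called individual are
    skipped. A window with pi_target = 0 gets an infinite ratio (retained;
    the quantile step excludes it).

    Returns a DataFrame: chrom, start, end, n_snps, fst, pi_target,
    pi_control, theta_pi_ratio.
    """
    if target == control:
        raise ValueError("target and control must differ")
    ti = popmap.indices(target, matrix.samples)
    ci = popmap.indices(control, matrix.samples)

    n1, alt1, het1 = _per_site_arrays(matrix, ti)
    n2, alt2, het2 = _per_site_arrays(matrix, ci)
    usable = (n1 > 0) & (n2 > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, alt1 / (2.0 * n1), 0.0)
        p2 = np.where(n2 > 0, alt2 / (2.0 * n2), 0.0)
        h1 = np.where(n1 > 0, het1 / np.maximum(n1, 1), 0.0)
        h2 = np.where(n2 > 0, het2 / np.maximum(n2, 1), 0.0)
    a_site, abc_site = _wc_components_vec(
        n1.astype(float), p1, h1, n2.astype(float), p2, h2
    )
    # per-site pi for each population (0 when < 2 called alleles)
    def _pi_vec(alt, n_ind):
        n_al = 2 * n_ind
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = 2.0 * alt * (n_al - alt) / (n_al * (n_al - 1.0))
        return np.where(n_al >= 2, pi, 0.0)

    pi_t_site = _pi_vec(alt1.astype(float), n1)
    pi_c_site = _pi_vec(alt2.astype(float), n2)

    a_site = np.where(usable, a_site, 0.0)
    abc_site = np.where(usable, abc_site, 0.0)
    pi_t_site = np.where(usable, pi_t_site, 0.0)
    pi_c_site = np.where(usable, pi_c_site, 0.0)
    # a site counts toward snp_count if called in both populations; sites
    # monomorphic across the pair still contribute 0 to every sum
    counts_site = usable

    # prefix sums per chromosome over position-sorted sites
    rows = []
    chrom_order = list(dict.fromkeys(matrix.chrom))
    by_chrom = {c: np.flatnonzero(matrix.chrom == c) for c in chrom_order}
    prefix = {}
    for c, idx in by_chrom.items():
        pos = matrix.pos[idx]
        prefix[c] = (
            pos,
            np.concatenate([[0.0], np.cumsum(a_site[idx])]),
            np.concatenate([[0.0], np.cumsum(abc_site[idx])]),
            np.concatenate([[0.0], np.cumsum(pi_t_site[idx])]),
            np.concatenate([[0.0], np.cumsum(pi_c_site[idx])]),
            np.concatenate([[0], np.cumsum(counts_site[idx])]),
        )

    n_inf = 0
    for w in windows:
        if w.chrom not in prefix:
            continue
        pos, ca, cabc, cpt, cpc, cn = prefix[w.chrom]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        n_snps = int(cn[hi] - cn[lo])
        if n_snps < min_snps:
            continue
        sum_a = ca[hi] - ca[lo]
        sum_abc = cabc[hi] - cabc[lo]
        fst = sum_a / sum_abc if sum_abc != 0 else math.nan
        length = w.end - w.start + 1
        pi_t = (cpt[hi] - cpt[lo]) / length
        pi_c = (cpc[hi] - cpc[lo]) / length
        if pi_t > 0:
            ratio = pi_c / pi_t
        else:
            ratio = math.inf
            n_inf += 1
        rows.append((w.chrom, w.start, w.end, n_snps, fst, pi_t, pi_c, ratio))
    if n_inf:
        logger.info("windowed_stats: %d windows with pi_target = 0 (infinite ratio)", n_inf)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "fst", "pi_target",
                 "pi_control", "theta_pi_ratio"],
    )


# ---------------------------------------------------------------------------
# Outlier selection and region merging
# ---------------------------------------------------------------------------

def select_outliers(
    stats: pd.DataFrame, q: float = 0.95
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Joint top-quantile outliers of Fst and the theta-pi ratio.

    For each statistic the outlier set is the ceil((1-q)*N) highest-valued
    windows among the N windows finite in *both* statistics, with boundary
    ties all included; the returned set is the intersection. The realized
    thresholds (minimum value inside each outlier set) are reported.
    """
    finite = stats[np.isfinite(stats["fst"]) & np.isfinite(stats["theta_pi_ratio"])]
    n_usable = len(finite)
    if n_usable < 20:
        raise ValueError(f"only {n_usable} windows with finite statistics (< 20): "
                         "quantile unstable")
    if len(finite) < len(stats):
        logger.info("select_outliers: %d windows with non-finite statistics excluded",
                    len(stats) - n_usable)
    # tiny epsilon so e.g. (1-0.95)*20 == 1.0000000000000009 still gives k=1
    k = math.ceil((1.0 - q) * n_usable - 1e-9)
    if k == 0:
        return finite.iloc[0:0], {"fst": math.inf, "theta_pi_ratio": math.inf}
    thresholds = {}
    masks = []
    for col in ("fst", "theta_pi_ratio"):
        vals = finite[col].to_numpy()
        thr = np.sort(vals)[::-1][k - 1]  # k-th largest; ties at thr included
        thresholds[col] = float(thr)
        masks.append(vals >= thr)
    out = finite[masks[0] & masks[1]]
    return out, thresholds


def merge_regions(outliers: pd.DataFrame) -> list[CandidateRegion]:
    """bedtools-merge style: overlapping or book-ended (end+1 == next start)
    windows on one chromosome collapse into a region, carrying the window
    count and the max Fst / max ratio seen."""
    if outliers.empty:
        return []
    df = outliers.sort_values(["chrom", "start"]).reset_index(drop=True)
    regions: list[CandidateRegion] = []
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start <= cur["end"] + 1:
            cur["end"] = max(cur["end"], row.end)
            cur["n"] += 1
            cur["fst"] = max(cur["fst"], row.fst)
            cur["ratio"] = max(cur["ratio"], row.theta_pi_ratio)
        else:
            if cur is not None:
                regions.append(CandidateRegion(
                    cur["chrom"], cur["start"], cur["end"], cur["n"], cur["fst"], cur["ratio"]))
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "n": 1, "fst": row.fst, "ratio": row.theta_pi_ratio}
    regions.append(CandidateRegion(
        cur["chrom"], cur["start"], cur["end"], cur["n"], cur["fst"], cur["ratio"]))
    return regions


def regions_to_bed(regions: Sequence[CandidateRegion], path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    target: str,
    control: str,
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
    step: int = 10_000,
    min_snps: int = 10,
    q: float = 0.95,
    autosomes_only: bool = True,
) -> dict:
    """Full scan for one target/control pair: windows -> per-window stats ->
    joint outliers -> merged candidate regions."""
    lengths = {
        c: ln for c, ln in chrom_lengths.items()
        if (not autosomes_only) or is_autosome(c)
    }
    windows = make_windows(lengths, window, step)
    stats = windowed_stats(matrix, popmap, target, control, windows, min_snps)
    outliers, thresholds = select_outliers(stats, q)
    regions = merge_regions(outliers)
    return {
        "windows": stats,
        "outliers": outliers,
        "thresholds": thresholds,
        "regions": regions,
    }
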