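"""Population structure and linkage-disequilibrium summaries.

Genotype PCA (Patterson-scaled), allele-sharing (IBS) distances with a
neighbor-joining tree, and an LD-decay curve of genotype (composite) r^2 —
the structure checks that accompany a sweep scan: the scan's target/control
contrast is only meaningful if the labelled populations are in fact
genetically distinct clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger("sweepscan")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(matrix: GenotypeMatrix, k: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed per site; monomorphic sites dropped;
    each site is centered by 2*p and scaled by sqrt(2*p*(1-p)) (Patterson
    scaling). Coordinates are the top-k eigenvectors of the sample
    covariance scaled by sqrt(eigenvalue); eigenvalues are non-increasing.

    Returns (coordinates DataFrame: sample, PC1..PCk; explained-variance
    fractions).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    d = matrix.dosage.astype(float)
    miss = matrix.dosage == MISSING
    d[miss] = np.nan
    site_mean = np.nanmean(d, axis=1)
    rows = np.where(miss)[0]
    d[miss] = site_mean[rows]
    p = site_mean / 2.0
    poly = (p > 0) & (p < 1)
    d, p = d[poly], p[poly]
    z = (d - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    # samples x samples covariance, averaged over sites
    cov = z.T @ z / z.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(k, matrix.n_samples)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    explained = np.maximum(evals, 0.0)
    explained = explained / explained.sum()
    df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(k)])
    df.insert(0, "sample", matrix.samples)
    return df, explained[:k]


# ---------------------------------------------------------------------------
# IBS distance + neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def to_phylip(self, path) -> None:
        """PHYLIP square format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{name} {row}\n")


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance: mean over co-called sites of |d_i - d_j|/2."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = matrix.dosage.astype(float)
    called = matrix.dosage != MISSING
    n = matrix.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {matrix.samples[i]} and {matrix.samples[j]} share "
                    "no called sites")
            out[i, j] = out[j, i] = np.abs(d[both, i] - d[both, j]).sum() / (2.0 * m)
    return DistanceMatrix(list(matrix.samples), out)


class _Node:
    __slots__ = ("label", "children")  # children: list of (child, branch_length)

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.12g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dist: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in Newick.

    On an additive matrix the output tree's path distances reproduce the
    input exactly. Negative branch lengths are clamped to 0 with the excess
    transferred to the sister branch (their sum is preserved).
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dist.values.astype(float).copy()
    nodes = [_Node(label=name) for name in dist.ids]
    active = list(range(n))
    # grow D in place by appending rows for internal nodes
    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best, bi, bj = None, None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-15:
                    best, bi, bj = q, i, j
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = D[bi, bj] - li
        if li < 0:
            lj, li = D[bi, bj], 0.0
        elif lj < 0:
            li, lj = D[bi, bj], 0.0
        parent = _Node(children=[(nodes[bi], li), (nodes[bj], lj)])
        new = len(nodes)
        nodes.append(parent)
        Dn = np.zeros((new + 1, new + 1))
        Dn[:new, :new] = D
        for x in active:
            if x in (bi, bj):
                continue
            dxu = 0.5 * (D[bi, x] + D[bj, x] - D[bi, bj])
            Dn[new, x] = Dn[x, new] = dxu
        D = Dn
        active = [x for x in active if x not in (bi, bj)] + [new]
    i, j = active
    # join the last two nodes with the remaining distance on one edge,
    # split evenly for display (path length i--j stays D[i, j])
    root = _Node(children=[(nodes[i], D[i, j] / 2.0), (nodes[j], D[i, j] / 2.0)])
    return root.newick() + ";"


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDCurve:
    midpoints: np.ndarray  # bp
    mean_r2: np.ndarray
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dist_bp": self.midpoints.astype(int),
            "mean_r2": self.mean_r2,
            "n_pairs": self.pair_counts.astype(int),
        })


def ld_decay(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    max_dist: int = 300_000,
    bin_bp: int = 1000,
) -> LDCurve:
    """Genotype (composite) LD decay within one population.

    r^2 is the squared Pearson correlation of unphased dosage vectors, over
    all intra-chromosomal site pairs separated by at most ``max_dist``;
    pairs where either site is monomorphic within the population (among
    co-called samples) are skipped. Mean r^2 is reported per distance bin.
    """
    idx = popmap.indices(population, matrix.samples)
    if idx.size < 5:
        raise ValueError(f"population {population!r} has fewer than 5 samples")
    d = matrix.dosage[:, idx].astype(float)
    d[matrix.dosage[:, idx] == MISSING] = np.nan

    n_bins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for chrom in dict.fromkeys(matrix.chrom):
        rows = np.flatnonzero(matrix.chrom == chrom)
        pos = matrix.pos[rows]
        sub = d[rows]
        for a in range(len(rows)):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            for b in range(a + 1, hi):
                sep = int(pos[b] - pos[a])
                if sep == 0:
                    continue
                x, y = sub[a], sub[b]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                rho = np.corrcoef(xs, ys)[0, 1]
                bin_i = min((sep - 1) // bin_bp, n_bins - 1)
                sums[bin_i] += rho * rho
                counts[bin_i] += 1
    if counts.sum() == 0:
        logger.warning("ld_decay: no eligible site pairs")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (np.arange(n_bins) + 0.5) * bin_bp
    keep = counts > 0
    return LDCurve(mids[keep], mean_r2[keep], counts[keep])
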