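"""Per-SNP allele-frequency differentiation (delta-AF) and the
population-specific near-fixation screen.

delta-AF = |AltAF_target - AltAF_control| at each SNP; values near 1 mark
(nearly) fixed differences. The screen keeps SNPs with AltAF_target > hi
and AltAF_control < lo (default 0.80 / 0.20, strict), so any passing SNP
has delta-AF strictly above hi - lo = 0.6.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscan")


def compute_delta_af(af_table: pd.DataFrame, target: str, control: str) -> pd.DataFrame:
    """delta-AF per SNP between two populations of an allele-frequency table.

    ``af_table`` is the output of :func:`sweepscan.genotype_io.allele_frequencies`
    (columns chrom, pos, af_<pop>, ...). SNPs with an undefined frequency in
    either population are skipped with a logged count.

    Returns columns chrom, pos, af_target, af_control, delta_af.
    """
    for pop in (target, control):
        if f"af_{pop}" not in af_table.columns:
            raise KeyError(f"population {pop!r} not in allele-frequency table")
    af_t = af_table[f"af_{target}"].to_numpy(float)
    af_c = af_table[f"af_{control}"].to_numpy(float)
    defined = ~np.isnan(af_t) & ~np.isnan(af_c)
    n_skipped = int((~defined).sum())
    if n_skipped:
        logger.info("compute_delta_af: skipped %d SNPs with undefined AF", n_skipped)
    out = pd.DataFrame({
        "chrom": af_table["chrom"].to_numpy()[defined],
        "pos": af_table["pos"].to_numpy()[defined],
        "af_target": af_t[defined],
        "af_control": af_c[defined],
    })
    out["delta_af"] = np.abs(out["af_target"] - out["af_control"])
    return out


def population_specific_screen(
    records: pd.DataFrame, hi: float = 0.80, lo: float = 0.20
) -> pd.DataFrame:
    """Flag SNPs nearly fixed in the target but rare in the control.

    A record passes iff af_target > hi and af_control < lo, both strict.
    Returns the table with a boolean ``passes`` column added.
    """
    out = records.copy()
    out["passes"] = (out["af_target"] > hi) & (out["af_control"] < lo)
    return out


def snps_to_genes(
    passing: pd.DataFrame, genes: Sequence, updown_bp: int = 1000
) -> dict[str, pd.DataFrame]:
    """Assign screened SNPs to genes whose flanked span contains them.

    A SNP is assigned to *every* gene whose span (transcript-union start -
    updown_bp to end + updown_bp, floored at 1) contains its position;
    overlapping genes each receive the SNP.

    Parameters
    ----------
    passing
        DataFrame with chrom, pos (typically screen-passing SNPs).
    genes
        Sequence of :class:`sweepscan.annotation.GeneModel`.

    Returns
    -------
    dict mapping gene_id -> the sub-table of assigned SNPs (non-empty only).
    """
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, pd.DataFrame] = {}
    for chrom, chrom_genes in by_chrom.items():
        sub = passing[passing["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy(np.int64)
        for g in chrom_genes:
            lo_b = max(1, g.start - updown_bp)
            hi_b = g.end + updown_bp
            hit = (pos >= lo_b) & (pos <= hi_b)
            if hit.any():
                out[g.gene_id] = sub[hit]
    return out


def gene_summary(assignments: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene count of assigned screen SNPs."""
    rows = [(gid, len(df)) for gid, df in sorted(assignments.items())]
    return pd.DataFrame(rows, columns=["gene_id", "n_snps"])
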