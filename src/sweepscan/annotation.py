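"""Functional annotation of SNPs against gene models.

Classifies each SNP into one primary category — exonic > splicing >
UTR5/UTR3 > intronic > upstream/downstream > intergenic (precedence-based,
the convention of gene-centric annotators) — with exonic sub-effects
(synonymous / nonsynonymous / stopgain / stoploss / unknown) called from
spliced CDS sequences, and maps candidate regions to overlapping genes.

All genomic intervals are 1-based inclusive. Defaults: 1-kb
upstream/downstream flank, 2-bp splice window, standard nuclear code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genotype_io import VariantSite
from .selection_scan import CandidateRegion

PRECEDENCE = [
    "exonic", "splicing", "UTR5", "UTR3", "UTR5;UTR3",
    "intronic", "upstream", "downstream", "upstream/downstream", "intergenic",
]
_RANK = {
    "exonic": 0, "splicing": 1,
    "UTR5": 2, "UTR3": 2, "UTR5;UTR3": 2,
    "intronic": 3,
    "upstream": 4, "downstream": 4, "upstream/downstream": 4,
    "intergenic": 5,
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]  # sorted genomic, 1-based inclusive
    cds: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str | None = None  # spliced CDS, coding orientation

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(
                    f"CDS [{cs},{ce}] outside exons in {self.transcript_id}")
        if self.cds_seq is not None:
            if len(self.cds_seq) != self.cds_length:
                raise ValueError(
                    f"CDS sequence length {len(self.cds_seq)} != intervals "
                    f"{self.cds_length} in {self.transcript_id}")
            if self.cds_length % 3 != 0:
                raise ValueError(f"CDS length not divisible by 3 in {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return self.cds[0][0], self.cds[-1][1]

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS,
        in coding orientation; None if outside the CDS."""
        if not any(s <= pos <= e for s, e in self.cds):
            return None
        if self.strand == "+":
            off = 0
            for s, e in self.cds:
                if pos > e:
                    off += e - s + 1
                else:
                    return off + (pos - s)
        else:
            off = 0
            for s, e in reversed(self.cds):
                if pos < s:
                    off += e - s + 1
                else:
                    return off + (e - pos)
        return None  # pragma: no cover


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


def load_gff(path, fasta: Mapping[str, str] | None = None) -> list[GeneModel]:
    """Build gene models from a GFF3 file.

    Expects gene / mRNA (or transcript) / exon / CDS features linked by
    ID/Parent. If ``fasta`` maps transcript (or gene) ids to spliced CDS
    sequences, they are attached for coding-effect calls. Genes are
    returned sorted by (chrom, start).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), level=1):
            exons = [(f.start, f.end) for f in db.children(t, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(t, featuretype="CDS")]
            if not exons:
                exons = sorted(cds)
            seq = None
            if fasta is not None:
                seq = fasta.get(t.id) or fasta.get(g.id)
            transcripts.append(Transcript(t.id, t.strand, exons, cds, seq))
        if transcripts:
            genes.append(GeneModel(g.id, g.seqid, g.strand, transcripts))
    # orphan Parent check: any mRNA/exon/CDS whose Parent is not in the db
    ids = {f.id for f in db.all_features()}
    for f in db.all_features():
        for parent in f.attributes.get("Parent", []):
            if parent not in ids:
                raise ValueError(f"orphan Parent {parent!r} referenced by {f.id}")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def _classify_against_transcript(
    pos: int, t: Transcript, updown_bp: int, splice_bp: int
) -> str | None:
    """Category of a position w.r.t. one transcript, or None if unrelated."""
    if t.start <= pos <= t.end:
        in_exon = any(s <= pos <= e for s, e in t.exons)
        if in_exon:
            span = t.cds_span
            if span is None:
                return "exonic"  # non-coding transcript exon
            cs, ce = span
            if cs <= pos <= ce:
                # inside the CDS span and in an exon => coding (UTR cannot
                # occur between the CDS endpoints on the spliced transcript)
                return "exonic"
            # untranslated exon portion: 5' or 3' by strand
            before_cds = pos < cs
            if t.strand == "+":
                return "UTR5" if before_cds else "UTR3"
            return "UTR3" if before_cds else "UTR5"
        # intronic; splicing if within splice_bp of an exon boundary
        for s, e in t.exons:
            if 0 < s - pos <= splice_bp or 0 < pos - e <= splice_bp:
                return "splicing"
        return "intronic"
    # flanks, measured from transcript ends on the coding strand
    if t.start - updown_bp <= pos < t.start:
        return "upstream" if t.strand == "+" else "downstream"
    if t.end < pos <= t.end + updown_bp:
        return "downstream" if t.strand == "+" else "upstream"
    return None


def classify_site(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    updown_bp: int = 1000,
    splice_bp: int = 2,
) -> str:
    """Primary functional category of a SNP.

    A SNP hitting multiple transcripts takes the highest-precedence category
    across them. Within the UTR tier, a SNP that is UTR5 of one transcript
    and UTR3 of another gets the combined "UTR5;UTR3" label; likewise
    upstream of one gene and downstream of another gives
    "upstream/downstream".
    """
    hits: list[str] = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if not (g.start - updown_bp <= pos <= g.end + updown_bp):
            continue
        for t in g.transcripts:
            cat = _classify_against_transcript(pos, t, updown_bp, splice_bp)
            if cat is not None:
                hits.append(cat)
    if not hits:
        return "intergenic"
    best = min(_RANK[c] for c in hits)
    tier = {c for c in hits if _RANK[c] == best}
    if tier == {"UTR5", "UTR3"}:
        return "UTR5;UTR3"
    if tier == {"upstream", "downstream"}:
        return "upstream/downstream"
    # deterministic single label within a tier
    return min(tier, key=PRECEDENCE.index)


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------

def coding_effect(site: VariantSite, transcript: Transcript) -> str:
    """Exonic sub-effect of a SNP inside a transcript's CDS.

    Substitutes the alternate base into the affected codon (bases
    reverse-complemented on the minus strand), translates with the standard
    nuclear code, and classifies: synonymous, nonsynonymous, stopgain,
    stoploss, or unknown (incomplete codon / reference mismatch).
    """
    off = transcript.cds_offset(site.pos)
    if off is None:
        raise ValueError(f"{site.chrom}:{site.pos} is not in the CDS of "
                         f"{transcript.transcript_id}")
    if transcript.cds_seq is None:
        raise ValueError(f"no CDS sequence attached to {transcript.transcript_id}")
    seq = transcript.cds_seq.upper()
    codon_i, within = divmod(off, 3)
    codon = seq[3 * codon_i: 3 * codon_i + 3]
    if len(codon) < 3:
        return "unknown"
    ref, alt = site.ref.upper(), site.alt.upper()
    if transcript.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    if codon[within] != ref:
        return "unknown"
    alt_codon = codon[:within] + alt + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


# ---------------------------------------------------------------------------
# Region-to-gene mapping and summaries
# ---------------------------------------------------------------------------

def genes_in_regions(
    regions: Sequence[CandidateRegion], genes: Sequence[GeneModel]
) -> tuple[list[list[str]], list[str]]:
    """Genes overlapping each candidate region (1-based inclusive intersect).

    Returns (per-region gene-id lists, de-duplicated union preserving first
    appearance).
    """
    per_region: list[list[str]] = []
    union: dict[str, None] = {}
    for r in regions:
        hits = [
            g.gene_id for g in genes
            if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start
        ]
        per_region.append(hits)
        for gid in hits:
            union.setdefault(gid)
    return per_region, list(union)


def intersect_gene_lists(lists: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Venn-style membership table for named gene lists.

    Returns one row per gene in the union with a boolean column per list
    plus a ``cell`` column naming the exclusive intersection cell
    ("A&B", "A", ...). Use :func:`venn_counts` for per-cell totals.
    """
    named = {k: set(v) for k, v in lists.items()}
    if len(named) < 2:
        raise ValueError("need at least two gene lists")
    all_genes = sorted(set().union(*named.values()))
    rows = []
    for g in all_genes:
        member = {k: g in s for k, s in named.items()}
        cell = "&".join(k for k in named if member[k])
        rows.append({"gene_id": g, **member, "cell": cell})
    return pd.DataFrame(rows)


def venn_counts(lists: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Counts for all 2^k - 1 exclusive intersection cells (0 included)."""
    named = {k: set(v) for k, v in lists.items()}
    names = list(named)
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named[k] for k in combo))
            outside = set().union(*(named[k] for k in names if k not in combo), set())
            counts["&".join(combo)] = len(inside - outside)
    return counts


def categorize_sites(
    sites: Iterable[tuple[str, int]],
    genes: Sequence[GeneModel],
    updown_bp: int = 1000,
    splice_bp: int = 2,
) -> Counter:
    """Category counts over (chrom, pos) sites — a Table-1-style summary."""
    counts: Counter = Counter()
    for chrom, pos in sites:
        counts[classify_site(chrom, pos, genes, updown_bp, splice_bp)] += 1
    return counts
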