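"""Synthetic multi-population cohorts with known sweep locations.

The generator draws, per neutral SNP, an ancestral frequency
p ~ Uniform(0.05, 0.95) and per-population frequencies from the
Balding-Nichols model, Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected
pairwise Fst is approximately F. Genotypes are Binomial(2, p_pop) per
diploid sample. Inside designated sweep intervals the target population's
frequency is pushed toward fixation, p <- (1-s)p + s*round(p), so strength
s near 1 yields near-fixed alleles: reduced target diversity, elevated Fst
and delta-AF — exactly the signal the scan is built to detect. Sites are
independent by default; an optional block mode re-uses population
frequencies within blocks of adjacent sites so LD decays with distance.

It also emits gene models (multi-exon, frame-consistent CDS) and GMT gene
sets including a positive-control set enriched for genes inside sweep
intervals. Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enrichment import GeneSetCollection
from .genotype_io import GenotypeMatrix, MISSING, PopulationMap, write_vcf

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [c for c in _CODONS if c not in _STOPS and c != "ATG"]


@dataclass(frozen=True)
class SweepInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    population: str  # target of the sweep
    s: float = 0.95  # sweep strength in [0, 1]


@dataclass
class SweepSimConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the cohort structure the scan targets: 25 diploids per
    population, background divergence F = 0.05, one SNP per 2 kb.
    """

    populations: dict[str, int] = field(
        default_factory=lambda: {"XP": 25, "TT": 25})
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000})
    snp_density: float = 1.0 / 2000.0
    F: float = 0.05
    sweep_intervals: list[SweepInterval] = field(default_factory=list)
    fixed_diff_sites: list[tuple[str, int, str]] = field(default_factory=list)
    """Planted positive controls: (chrom, pos, target population) sites fixed
    alt in the target and fixed ref everywhere else."""
    missing_rate: float = 0.0
    ld_block_snps: int = 1  # > 1 shares population frequencies within blocks
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.F < 1):
            raise ValueError("F must be in (0, 1)")
        for iv in self.sweep_intervals:
            if iv.population not in self.populations:
                raise ValueError(f"sweep interval targets unknown population "
                                 f"{iv.population!r}")
            if not (1 <= iv.start <= iv.end <= self.chrom_lengths[iv.chrom]):
                raise ValueError(f"sweep interval {iv} outside chromosome bounds")
            if not (0 <= iv.s <= 1):
                raise ValueError("sweep strength s must be in [0, 1]")


@dataclass
class SweepTruth:
    """Ground truth: realized sweep intervals and the simulated SNPs inside
    them, plus per-SNP realized population frequencies."""

    intervals: list[SweepInterval]
    snp_positions: dict[int, list[tuple[str, int]]]  # interval index -> (chrom, pos)
    pop_freqs: dict[str, np.ndarray]  # population -> per-SNP frequency
    chrom: np.ndarray = None
    pos: np.ndarray = None

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.population}\t"
                         f"{iv.s:g}\n")


def simulate_genotypes(
    config: SweepSimConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SweepTruth]:
    """Draw a cohort in memory (see module docstring for the model)."""
    rng = np.random.default_rng(config.seed)
    pops = list(config.populations)

    chroms, positions = [], []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_snps = int(round(length * config.snp_density))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_snps, replace=False))
        chroms.append(np.full(n_snps, chrom, dtype=object))
        positions.append(pos)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions).astype(np.int64)
    n_sites = len(pos_arr)

    # planted fixed-difference sites replace the nearest simulated site
    planted = {}
    for pchrom, ppos, ptarget in config.fixed_diff_sites:
        on_chrom = np.flatnonzero(chrom_arr == pchrom)
        if on_chrom.size == 0:
            raise ValueError(f"no sites on chromosome {pchrom}")
        i = on_chrom[np.argmin(np.abs(pos_arr[on_chrom] - ppos))]
        pos_arr[i] = ppos
        planted[int(i)] = ptarget
    order = np.lexsort((pos_arr, chrom_arr))
    chrom_arr, pos_arr = chrom_arr[order], pos_arr[order]
    planted = {int(np.flatnonzero(order == i)[0]): t for i, t in planted.items()}

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    a = config.F
    conc = (1.0 - a) / a
    block = max(1, int(config.ld_block_snps))
    pop_freqs: dict[str, np.ndarray] = {}
    for pop in pops:
        if block == 1:
            q = rng.beta(p_anc * conc, (1.0 - p_anc) * conc)
        else:
            # one Beta draw per block of adjacent sites -> local LD
            n_blocks = int(np.ceil(n_sites / block))
            reps = np.repeat(np.arange(n_blocks), block)[:n_sites]
            p_block = p_anc[::block]
            q_block = rng.beta(p_block * conc, (1.0 - p_block) * conc)
            q = q_block[reps]
        pop_freqs[pop] = q

    # apply sweeps: push the target population's frequency toward fixation
    truth_snps: dict[int, list[tuple[str, int]]] = {}
    for k, iv in enumerate(config.sweep_intervals):
        in_iv = (chrom_arr == iv.chrom) & (pos_arr >= iv.start) & (pos_arr <= iv.end)
        q = pop_freqs[iv.population]
        q[in_iv] = (1.0 - iv.s) * q[in_iv] + iv.s * np.rint(q[in_iv])
        truth_snps[k] = [(c, int(p)) for c, p in
                         zip(chrom_arr[in_iv], pos_arr[in_iv])]
    for i, ptarget in planted.items():
        for pop in pops:
            pop_freqs[pop][i] = 1.0 if pop == ptarget else 0.0

    samples, columns = [], []
    assignment = {}
    for pop in pops:
        n = config.populations[pop]
        q = pop_freqs[pop]
        geno = rng.binomial(2, q[:, None], size=(n_sites, n)).astype(np.int8)
        for j in range(n):
            name = f"{pop}_{j:02d}"
            samples.append(name)
            assignment[name] = pop
        columns.append(geno)
    dosage = np.hstack(columns)
    if config.missing_rate > 0:
        drop = rng.random(dosage.shape) < config.missing_rate
        dosage[drop] = MISSING

    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "G", dtype=object)
    matrix = GenotypeMatrix(chrom_arr, pos_arr, ref, alt, samples, dosage,
                            qual=np.full(n_sites, 100.0))
    truth = SweepTruth(list(config.sweep_intervals), truth_snps, pop_freqs,
                       chrom=chrom_arr, pos=pos_arr)
    return matrix, PopulationMap(assignment), truth


def simulate_cohort(
    config: SweepSimConfig, out_dir
) -> tuple[Path, Path, SweepTruth]:
    """Simulate and write cohort files: VCF, popmap TSV and truth BED.

    Returns (vcf path, popmap path, truth). Byte-identical given the same
    config (including seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, popmap, truth = simulate_genotypes(config)
    vcf_path = out_dir / "cohort.vcf"
    popmap_path = out_dir / "popmap.tsv"
    write_vcf(matrix, vcf_path, contig_lengths=config.chrom_lengths)
    popmap.to_tsv(popmap_path)
    truth.to_bed(out_dir / "sweep_truth.bed")
    return vcf_path, popmap_path, truth


# ---------------------------------------------------------------------------
# Gene models + gene sets
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + sense codons + stop; no internal stops by construction."""
    body = "".join(rng.choice(_SENSE) for _ in range(n_codons - 2))
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + body + stop


def simulate_gene_models(
    chrom_lengths: dict[str, int],
    n_genes: int,
    seed: int = 0,
    sweep_intervals: list[SweepInterval] | None = None,
    n_sets: int = 10,
    genes_per_set: int = 8,
) -> tuple[str, dict[str, str], GeneSetCollection]:
    """Generate non-overlapping multi-exon gene models and gene sets.

    Returns (GFF3 text, transcript-id -> spliced CDS FASTA dict, GMT
    collection). Each gene has 2-4 exons with UTR flanks and a
    frame-consistent CDS (starts ATG, ends with a stop, length divisible by
    3). The collection holds ``n_sets`` random sets plus a "sweep_set"
    enriched for genes overlapping ``sweep_intervals`` — a positive control
    for the enrichment stage.
    """
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    slot = 12_000  # gene footprint + spacer
    if n_genes * slot > total:
        raise ValueError(f"cannot pack {n_genes} genes into {total} bp")

    # spread genes uniformly over chromosomes, proportionally to length
    per_chrom: dict[str, int] = {}
    remaining = n_genes
    chrom_list = sorted(chrom_lengths)
    for i, chrom in enumerate(chrom_list):
        if i == len(chrom_list) - 1:
            per_chrom[chrom] = remaining
        else:
            k = int(round(n_genes * chrom_lengths[chrom] / total))
            k = min(k, remaining)
            per_chrom[chrom] = k
            remaining -= k

    gff_lines = ["##gff-version 3"]
    fasta: dict[str, str] = {}
    gene_ids: list[str] = []
    gene_spans: dict[str, tuple[str, int, int]] = {}
    gid = 0
    for chrom in chrom_list:
        k = per_chrom[chrom]
        if k == 0:
            continue
        length = chrom_lengths[chrom]
        stride = length // k
        if stride < slot:
            raise ValueError(f"cannot pack {k} genes into {chrom} ({length} bp)")
        for g in range(k):
            gid += 1
            gene_id = f"gene{gid:04d}"
            tx_id = f"tx{gid:04d}"
            base = g * stride + int(rng.integers(500, max(501, stride - slot)))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            n_codons = int(rng.integers(40, 120))
            cds_len = 3 * n_codons
            utr5_len = int(rng.integers(50, 200))
            utr3_len = int(rng.integers(50, 200))
            tx_len = utr5_len + cds_len + utr3_len
            # split the transcript into exons with introns between
            cuts = np.sort(rng.choice(np.arange(1, tx_len), size=n_exons - 1,
                                      replace=False))
            pieces = np.diff(np.concatenate([[0], cuts, [tx_len]]))
            exons, cur = [], base
            for piece in pieces:
                exons.append((cur, cur + int(piece) - 1))
                cur += int(piece) + int(rng.integers(80, 500))  # intron
            start, end = exons[0][0], exons[-1][1]
            # CDS occupies transcript coords [utr5_len, utr5_len + cds_len)
            # (5'->3'); map to genomic intervals
            if strand == "+":
                lo_t, hi_t = utr5_len, utr5_len + cds_len - 1
            else:
                lo_t, hi_t = utr3_len, utr3_len + cds_len - 1  # genomic left = 3' end
            cds = []
            off = 0
            for (es, ee) in exons:
                ex_len = ee - es + 1
                a, b = off, off + ex_len - 1
                s = max(a, lo_t)
                e = min(b, hi_t)
                if s <= e:
                    cds.append((es + (s - a), es + (e - a)))
                off += ex_len
            seq = _random_cds(rng, n_codons)
            fasta[tx_id] = seq
            gene_ids.append(gene_id)
            gene_spans[gene_id] = (chrom, start, end)
            gff_lines.append(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}")
            gff_lines.append(
                f"{chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={tx_id};Parent={gene_id}")
            for es, ee in exons:
                gff_lines.append(
                    f"{chrom}\tsim\texon\t{es}\t{ee}\t.\t{strand}\t.\tParent={tx_id}")
            for cs, ce in cds:
                gff_lines.append(
                    f"{chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\tParent={tx_id}")

    # gene sets: random background sets + a sweep-enriched positive control
    sets: dict[str, set] = {}
    for i in range(n_sets):
        members = rng.choice(gene_ids, size=min(genes_per_set, len(gene_ids)),
                             replace=False)
        sets[f"set{i:02d}"] = set(members.tolist())
    if sweep_intervals:
        in_sweep = [
            g for g in gene_ids
            if any(iv.chrom == gene_spans[g][0]
                   and gene_spans[g][1] <= iv.end and gene_spans[g][2] >= iv.start
                   for iv in sweep_intervals)
        ]
        outside = [g for g in gene_ids if g not in in_sweep]
        n_pad = max(0, genes_per_set - len(in_sweep))
        pad = rng.choice(outside, size=min(n_pad, len(outside)), replace=False)
        sets["sweep_set"] = set(in_sweep) | set(pad.tolist())
    collection = GeneSetCollection(sets, {k: "simulated" for k in sets})
    return "\n".join(gff_lines) + "\n", fasta, collection


def write_gene_fixture(
    out_dir,
    chrom_lengths: dict[str, int],
    n_genes: int,
    seed: int = 0,
    sweep_intervals: list[SweepInterval] | None = None,
) -> tuple[Path, Path, Path]:
    """Write GFF3 + CDS FASTA + GMT files; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff, fasta, gmt = simulate_gene_models(
        chrom_lengths, n_genes, seed, sweep_intervals)
    gff_path = out_dir / "genes.gff3"
    fa_path = out_dir / "cds.fa"
    gmt_path = out_dir / "genesets.gmt"
    gff_path.write_text(gff)
    with open(fa_path, "w") as fh:
        for name, seq in fasta.items():
            fh.write(f">{name}\n{seq}\n")
    gmt.to_gmt(gmt_path)
    return gff_path, fa_path, gmt_path
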