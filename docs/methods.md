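# Methods

## The scan

`sweepscan` detects candidate selective sweeps in a target population by
contrasting it with a control population along the genome. The premise is
standard: positive selection drives an allele toward fixation, which locally
(i) raises allele-frequency differentiation between the selected population
and its relatives and (ii) erodes nucleotide diversity in the selected
population. The scan therefore combines two window statistics and one
per-SNP statistic.

**Weir–Cockerham F<sub>ST</sub>.** At each biallelic site, the
two-population Weir & Cockerham (1984) variance components are computed
from per-population called sample sizes n₁, n₂, alternate-allele
frequencies p₁, p₂ and observed heterozygote fractions h₁, h₂, with r = 2,
n̄ = (n₁+n₂)/2, n_c = (r·n̄ − (n₁²+n₂²)/(r·n̄))/(r−1), n-weighted means p̄
and h̄, and s² = Σᵢ nᵢ(pᵢ−p̄)²/((r−1)n̄):

- a — among-population component,
- b — among-individual-within-population component,
- c = h̄/2 — within-individual component.

The window estimate is the "weighted" ratio Σa/Σ(a+b+c) over sites, the
same combination VCFtools' windowed Fst uses. Sites monomorphic across the
pair (p̄ ∈ {0,1}) contribute zero to all three sums; sites where either
population has no called individual, or n̄ ≤ 1, are skipped. Negative
window values (the estimator's behavior when differentiation is at or below
its sampling noise) are reported as-is, not clamped — ranking, the only use
the scan makes of the values, is unaffected.

**Nucleotide diversity and the θπ ratio.** Per-site π is the expected
pairwise difference among the 2n called alleles, 2j(2n−j)/(2n(2n−1)) for j
alternate alleles. Windowed π sums the per-site values and divides by the
full window length in bp (monomorphic and uncalled positions count as
invariant). The ratio is oriented π_control/π_target, so values above 1
mean the target has lost diversity — the expected direction under
domestication/selection in the target. The orientation is a parameter of
the reporting, not of the mathematics: swapping target and control maps
every finite ratio to its reciprocal (asserted as a property test). Because
both populations share each window, the denominator convention cancels from
the ratio.

**Windows.** Sliding windows of 100 kb with a 10-kb step, starting at 1,
1+step, … for every start ≤ chromosome length (trailing windows truncate at
the chromosome end). Windows with fewer than 10 SNPs called in both
populations are discarded as unstable. Only autosomes (numeric chromosome
names) are scanned by default; a flag admits all sequences. Windows whose
target π is exactly 0 get an infinite ratio; they are retained in the
per-window table but excluded from quantile computation (logged), since a
rank among infinities is undefined.

**Joint outliers.** For the N windows finite in both statistics, each
statistic's outlier set is the k = ⌈(1−q)·N⌉ highest values (q = 0.95 by
default), with all boundary ties included; the candidate set is the
intersection. Top-k with tie inclusion was chosen over interpolated
percentiles for exact reproducibility; the realized thresholds (minimum
value inside each outlier set) are always reported so a run documents its
own cutoffs. At least 20 usable windows are required — below that a 5%
quantile is dominated by single windows. Outlier windows that overlap or
are book-ended (end+1 = next start) merge into candidate regions, carrying
the window count and the maximum of each statistic.

**ΔAF screen.** Per SNP, per population, AltAF is the dosage sum over
called samples divided by 2× the called count (missing genotypes leave both
numerator and denominator). ΔAF = |AltAF_target − AltAF_control|; the
population-specific screen keeps SNPs with AltAF_target > 0.8 and
AltAF_control < 0.2, both strict, so every passing SNP has ΔAF > 0.6. The
screened allele is the VCF alternate allele; no outgroup polarization is
attempted. The screen is pairwise (one control at a time); intersecting the
per-control passing sets approximates a multi-control consensus.

## Filters

Variant-level hard filters follow the GATK SNP convention: QUAL > 30,
QD > 5.0, FS < 60.0, MQ > 40.0, MQRankSum > −12.5, ReadPosRankSum > −8.0,
all strict as stated. A site missing a metric is not failed on it
(un-annotated sites pass, the GATK convention). Cohort QC removes sites
with pooled MAF < 0.05 (strictly below — MAF exactly 0.05 is kept, matching
PLINK `--maf`), call rate < 0.90, or missing fraction > 0.20. Call rate and
missing rate are complements, and both thresholds are applied independently
as configured even though one implies the other at the defaults. MAF is
pooled across all samples because filtering is applied to the merged cohort
before any per-pair scan. The QC filter is idempotent.

## Annotation

Gene models come from GFF3 (gene/mRNA/exon/CDS with ID/Parent links);
UTRs are derived as the exonic residue outside the CDS span, 5′ vs 3′ by
strand. Classification is precedence-based: exonic > splicing >
UTR5/UTR3 > intronic > upstream/downstream > intergenic, with a 2-bp
splicing window into introns and 1-kb flanks measured from transcript ends
on the coding strand — the defaults of gene-centric annotators. A SNP
hitting several transcripts takes the highest-precedence category; a SNP
that is UTR5 of one transcript and UTR3 of another (or upstream of one gene
and downstream of another) receives the combined label. Coding effects
substitute the alternate base into the affected codon of the spliced CDS
(reverse-complemented on minus-strand transcripts) and translate with the
standard nuclear code; a reference-base mismatch or incomplete codon yields
"unknown" rather than a guess.

## Population structure and LD

PCA mean-imputes missing dosages per site (imputation is used nowhere
else — every other statistic is complete-case per site), drops monomorphic
sites, and standardizes by 2p̂ and √(2p̂(1−p̂)) before an exact
eigendecomposition of the sample covariance; coordinates are eigenvectors
scaled by √eigenvalue. The IBS (allele-sharing) distance is the mean over
co-called sites of |dosage difference|/2, a metric on complete data.
Neighbor joining is the Saitou–Nei algorithm; on additive matrices it
reproduces the input path distances exactly (tested to 1e−9 on random
additive trees), and a negative branch length is clamped to 0 with the
excess moved to its sister so the pair's total is preserved. LD decay uses
genotype (composite) r² — squared Pearson correlation of unphased dosage
vectors — for all intra-chromosomal pairs within 300 kb by default, binned
by separation; pairs with a within-population monomorphic member are
skipped. Genotype r² was chosen because the inputs are unphased.

## Enrichment

Candidate gene lists are tested against user-supplied GMT gene sets with
the upper-tail hypergeometric probability P(X ≥ k) for overlap k, set size
K, selection size n, universe N; sets are intersected with the universe
first. The default significance flag is raw p < 0.05;
Benjamini–Hochberg q-values are computed and reported alongside but do not
gate the flag, since over-representation screens of this kind are
conventionally read on raw p. The default universe is the gene models'
gene set, not the GMT union.

## The simulator

The synthetic cohort generator exists so every stage can be validated
against known truth. Per neutral SNP an ancestral frequency is drawn
p ~ Uniform(0.05, 0.95) (the bounds keep small cohorts from being swamped
by monomorphic draws), and each population's frequency from the
Balding–Nichols distribution Beta(p(1−F)/F, (1−p)(1−F)/F), whose expected
pairwise Fst is ≈ F. Genotypes are Binomial(2, p_pop) per diploid.
Defaults are the study conditions the scan assumes: two populations of 25
diploids, F = 0.05, one SNP per 2 kb, no missingness.

Sweeps act on frequencies, not haplotypes: within a sweep interval the
target population's frequency becomes (1−s)·p + s·round(p), so s → 1
pushes alleles to near-fixation, jointly producing reduced target π,
elevated Fst and elevated ΔAF. This is adequate here because every in-scope
statistic is frequency- or dosage-based. Optional planted fixed-difference
sites (target frequency 1, all controls 0) give the ΔAF screen a
deterministic positive control. Sites are independent by default — LD-decay
curves on such cohorts are flat by construction — and an optional block
mode shares population frequencies within blocks of adjacent SNPs, giving
r² that decays with distance. What the simulator does **not** emulate:
recombination-explicit haplotype structure, demographic history, mutation-
rate heterogeneity, genotyping error that correlates with depth, and linked
background selection. Tests passing on these cohorts therefore validate the
statistics and their wiring, not the field behavior of the thresholds on
real genomes.

The gene-model generator packs non-overlapping multi-exon genes (2–4
exons, UTR flanks, CDS starting ATG, ending with a stop, length divisible
by 3, no internal stops) and emits GMT sets including one positive-control
set enriched ≥2× for genes inside sweep intervals.

## Validation problem sizes

The test suite runs at desk scale, chosen to make the checks sharp while
staying fast: estimator-oracle comparisons use 1,000 random sites /
transcripts; Fst calibration uses 25+25 diploids and 50,000 SNPs per F ∈
{0.05, 0.15, 0.3} (observed agreement within ±0.003, asserted at ±0.02);
sweep recovery uses two 10-Mb chromosomes (~10,000 SNPs, ~2,000 windows)
with two 500-kb sweeps at s = 0.95 — about 4% of windows, inside the 5%
quantile budget — over five seeds (observed recovery 100%, contamination
0%, asserted ≥80% / ≤1%); NJ exactness uses 100 random additive trees of
4–12 taxa at 1e−9.

## Known limitations

- Two-population Fst only; the multi-population generalization is out of
  scope (the published workflow is strictly pairwise).
- Windows with zero target diversity are excluded from ratio quantiles, so
  a complete, perfectly hard sweep can paradoxically drop out of the ratio
  ranking; it is still flagged through Fst and ΔAF.
- Gene assignment uses the transcript-union span plus 1-kb flanks; distal
  regulatory variation is invisible to it.
- The hypergeometric test treats genes as exchangeable; no correction for
  gene length or SNP density is applied.
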