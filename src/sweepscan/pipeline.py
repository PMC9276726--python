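"""Pipeline orchestration: run every stage in dependency order and write a
consolidated run report.

Stages: load/filter genotypes -> windowed Fst + theta-pi scan -> joint
outliers -> merged regions -> delta-AF screen -> gene annotation ->
population structure -> enrichment. Outputs are plain TSV/BED with a YAML
manifest (parameters, input checksums, per-stage counts) so a run can be
audited and reproduced.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import delta_af as daf
from . import enrichment as enr
from . import genotype_io as gio
from . import pop_structure as pst
from . import selection_scan as scan

logger = logging.getLogger("sweepscan")


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters.

    Defaults are the scan's standard operating point: 100-kb windows with
    10-kb step, at least 10 SNPs per window, joint top-5% outliers, MAF
    0.05 / 20% missingness QC, 0.80/0.20 near-fixation screen, 1-kb gene
    flanks.
    """

    vcf: str = ""
    popmap: str = ""
    target: str = "XP"
    control: str = "TT"
    gff: str | None = None
    gmt: str | None = None
    out_dir: str = "sweepscan_run"
    window: int = 100_000
    step: int = 10_000
    min_snps: int = 10
    quantile: float = 0.95
    maf: float = 0.05
    call_rate: float = 0.90
    max_missing: float = 0.20
    hi: float = 0.80
    lo: float = 0.20
    updown_bp: int = 1000
    apply_hard_filters: bool = True
    autosomes_only: bool = True
    run_structure: bool = True
    chrom_lengths: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 < self.quantile <= 1):
            raise ValueError("quantile must be in (0, 1]")
        if self.window < self.step or self.step < 1:
            raise ValueError("need window >= step >= 1")
        if self.target == self.control:
            raise ValueError("target and control must differ")
        for name in ("maf", "max_missing", "hi", "lo", "call_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_scan_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to
    ``out_dir`` along with every stage output and the manifest)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"stages": {}, "parameters": asdict(config)}
    manifest: dict = {"parameters": asdict(config), "inputs": {}}
    for key in ("vcf", "popmap", "gff", "gmt"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    def stage(name):
        logger.info("stage %-12s +%.1fs", name, time.time() - t0)

    try:
        stage("load")
        matrix = gio.parse_vcf(config.vcf)
        popmap = gio.PopulationMap.from_tsv(config.popmap)
        popmap.validate(matrix.samples)
        report["stages"]["sites_in"] = matrix.n_sites

        stage("filter")
        if config.apply_hard_filters:
            matrix, hf_report = gio.hard_filter_matrix(matrix)
            report["stages"]["hard_filter_removals"] = hf_report
        matrix = gio.qc_filter(matrix, config.maf, config.call_rate, config.max_missing)
        report["stages"]["sites_filtered"] = matrix.n_sites
        if matrix.n_sites == 0:
            raise RuntimeError("no sites left after filtering")

        chrom_lengths = config.chrom_lengths or {
            c: int(matrix.pos[matrix.chrom == c].max())
            for c in dict.fromkeys(matrix.chrom)
        }

        stage("scan")
        result = scan.scan(
            matrix, popmap, config.target, config.control, chrom_lengths,
            config.window, config.step, config.min_snps, config.quantile,
            config.autosomes_only,
        )
        stats, outliers = result["windows"], result["outliers"]
        regions = result["regions"]
        stats.to_csv(out / "window_stats.tsv", sep="\t", index=False)
        outliers.to_csv(out / "outlier_windows.tsv", sep="\t", index=False)
        scan.regions_to_bed(regions, out / "candidate_regions.bed")
        pd.DataFrame([vars(r) for r in regions]).to_csv(
            out / "candidate_regions.tsv", sep="\t", index=False)
        report["stages"]["windows"] = len(stats)
        report["stages"]["outlier_windows"] = len(outliers)
        report["stages"]["regions"] = len(regions)
        report["thresholds"] = result["thresholds"]

        stage("deltaaf")
        af = gio.allele_frequencies(matrix, popmap)
        af.to_csv(out / "allele_frequencies.tsv", sep="\t", index=False)
        records = daf.compute_delta_af(af, config.target, config.control)
        screened = daf.population_specific_screen(records, config.hi, config.lo)
        screened.to_csv(out / "delta_af.tsv", sep="\t", index=False)
        report["stages"]["screen_snps"] = int(screened["passes"].sum())

        genes = None
        if config.gff:
            stage("annotate")
            genes = ann.load_gff(config.gff)
            per_region, union = ann.genes_in_regions(regions, genes)
            pd.DataFrame({
                "chrom": [r.chrom for r in regions],
                "start": [r.start for r in regions],
                "end": [r.end for r in regions],
                "genes": [",".join(g) for g in per_region],
            }).to_csv(out / "region_genes.tsv", sep="\t", index=False)
            report["stages"]["region_genes"] = len(union)
            report["stages"]["total_genes"] = len(genes)
            passing = screened[screened["passes"]]
            assignments = daf.snps_to_genes(passing, genes, config.updown_bp)
            daf.gene_summary(assignments).to_csv(
                out / "screen_gene_summary.tsv", sep="\t", index=False)
            cats = ann.categorize_sites(
                zip(matrix.chrom, matrix.pos), genes, config.updown_bp)
            gio.summarize_annotation_counts(dict(cats)).to_csv(
                out / "annotation_summary.tsv", sep="\t", index=False)

            if config.gmt:
                stage("enrich")
                collection = enr.GeneSetCollection.from_gmt(config.gmt)
                universe = [g.gene_id for g in genes]
                selected = [g for g in union if g in set(universe)]
                if selected:
                    res = enr.hypergeom_enrich(selected, collection, universe)
                    res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                    report["stages"]["significant_sets"] = int(res["significant"].sum())
                else:
                    report["stages"]["significant_sets"] = 0

        if config.run_structure:
            stage("structure")
            coords, explained = pst.genotype_pca(matrix, k=min(10, matrix.n_samples))
            coords.to_csv(out / "pca_coords.tsv", sep="\t", index=False)
            pd.DataFrame({"component": range(1, len(explained) + 1),
                          "explained": explained}).to_csv(
                out / "pca_eigenvalues.tsv", sep="\t", index=False)
            dist = pst.ibs_distance(matrix)
            dist.to_phylip(out / "ibs_distance.phylip")
            (out / "nj_tree.nwk").write_text(pst.nj_tree(dist) + "\n")
    except Exception as exc:
        report["failed_stage"] = str(exc)
        (out / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
        raise

    manifest["report"] = report["stages"]
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return report
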