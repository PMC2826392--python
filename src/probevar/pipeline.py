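"""End-to-end orchestration of the SNP-in-probe survey.

Stages run in a fixed order — variant intake, known/novel annotation,
functional annotation, probe mapping, probeset/cluster/chromosome
cataloguing, prior-catalogue comparison, and the splicing-impact audit —
with per-stage counts appended to a plain-text run log so the flow is
auditable.  All outputs use stable (chrom, pos, probeset_id) ordering,
making re-runs byte-identical for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import array_model, catalogue, func_annot, probe_map, splicing_impact, variant_panel
from .array_model import ArrayAnnotation
from .catalogue import ChromosomeDistribution, ClusterSummary, ProbesetSummary
from .probe_map import BinDistribution, ProbeHit
from .splicing_impact import AuditResult, ExpressionMatrix, ReassessResult


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for one survey run."""

    probe_path: str
    probeset_path: str
    gene_path: str
    vcf_paths: Dict[str, str]            # population -> VCF
    known_path: str
    prior_path: Optional[str] = None
    expression_path: Optional[str] = None
    population_map_path: Optional[str] = None
    targets_path: Optional[str] = None
    out_dir: str = "survey_out"
    maf_threshold: float = 0.05
    near_gene_window: int = 2000
    probe_length: int = 25
    filter_mode: str = "common"          # 'common' or 'all'
    ttest_flavor: str = "pooled"
    offset_mode: str = "strand-aware"    # or 'genomic'
    summarizer: str = "mean"
    pass_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if self.filter_mode not in ("common", "all"):
            raise ValueError("filter_mode must be 'common' or 'all'")
        if self.offset_mode not in ("strand-aware", "genomic"):
            raise ValueError("offset_mode must be 'strand-aware' or 'genomic'")

    @classmethod
    def from_bundle(cls, bundle_dir, out_dir=None, populations=("CEU", "YRI"), **overrides):
        """Point every input at the standard file names of a fixture bundle."""
        b = Path(bundle_dir)
        return cls(
            probe_path=str(b / "probes.tsv"),
            probeset_path=str(b / "probesets.tsv"),
            gene_path=str(b / "genes.tsv"),
            vcf_paths={p: str(b / f"{p}.vcf") for p in populations},
            known_path=str(b / "known_snps.tsv"),
            prior_path=str(b / "prior_catalogue.tsv"),
            expression_path=str(b / "expression.tsv"),
            population_map_path=str(b / "sample_populations.tsv"),
            targets_path=str(b / "targets.tsv"),
            out_dir=str(out_dir if out_dir is not None else b / "survey_out"),
            **overrides,
        )


@dataclass
class SurveyResult:
    """Everything the survey computed, stage by stage."""

    annotation: ArrayAnnotation = None
    panels: Dict[str, variant_panel.PopulationPanel] = field(default_factory=dict)
    hits: Dict[str, List[ProbeHit]] = field(default_factory=dict)           # all frequencies
    summaries: Dict[str, Dict[str, List[ProbesetSummary]]] = field(default_factory=dict)
    cluster_summaries: Dict[str, List[ClusterSummary]] = field(default_factory=dict)
    reliability: Dict[str, Dict[str, int]] = field(default_factory=dict)
    chromosomes: Dict[str, ChromosomeDistribution] = field(default_factory=dict)
    bin_distribution: Dict[str, BinDistribution] = field(default_factory=dict)
    function_tables: Dict[str, Dict[str, int]] = field(default_factory=dict)
    prior_comparison: Dict[str, pd.DataFrame] = field(default_factory=dict)
    union_affected: Optional[int] = None
    audit: Optional[AuditResult] = None
    retests: List[ReassessResult] = field(default_factory=list)
    log: List[str] = field(default_factory=list)


def _check_inputs(config: PipelineConfig) -> None:
    required = [config.probe_path, config.probeset_path, config.gene_path,
                config.known_path, *config.vcf_paths.values()]
    for p in required:
        if not Path(p).exists():
            raise PipelineError("inputs", f"missing input file: {p}")


def run_survey(config: PipelineConfig) -> SurveyResult:
    """Execute the full survey; write TSV outputs and a run log."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = SurveyResult()
    log = result.log

    # annotation
    ann = array_model.read_array_annotation(
        config.probe_path, config.probeset_path, probe_length=config.probe_length
    )
    report = array_model.validate_annotation(ann)
    if not report.ok:
        raise PipelineError("annotation", f"{len(report.violations)} violations, "
                            f"first: {report.violations[0]}")
    result.annotation = ann
    log.append(f"annotation: {report.n_probes} probes, {report.n_probesets} probesets, "
               f"{report.n_clusters} clusters, {ann.n_skipped_probes} skipped")

    genes = func_annot.read_gene_models(config.gene_path)
    gene_index = func_annot.GeneIndex(genes)
    records = variant_panel.read_known_snp_table(config.known_path)
    cat_index = variant_panel.catalogue_by_position(records)
    neighbors = func_annot.build_neighbor_index(records)
    log.append(f"catalogue: {len(records)} known SNP records, {len(genes)} gene models")

    prior = catalogue.read_prior_catalogue(config.prior_path) if config.prior_path and Path(config.prior_path).exists() else None

    index = probe_map.build_probe_index(ann)
    thr = config.maf_threshold
    for pop, vcf_path in sorted(config.vcf_paths.items()):
        panel = variant_panel.read_population_vcf(vcf_path, pop, pass_only=config.pass_only)
        variant_panel.annotate_known_status(panel, cat_index)
        func_annot.annotate_panel_functions(
            panel, cat_index, gene_index, neighbors, config.near_gene_window
        )
        result.panels[pop] = panel
        n_known = sum(v.known for v in panel.variants)
        n_common = sum(v.freq_class(thr) == "common" for v in panel.variants)
        log.append(f"{pop}: {len(panel.variants)} variants read "
                   f"({panel.n_skipped_records} records skipped), "
                   f"{n_known} known / {len(panel.variants) - n_known} novel, "
                   f"{n_common} common at MAF>{thr}")

        hits = probe_map.map_variants_to_probes(
            panel, index, maf_filter=None, threshold=thr,
            genomic_offset=(config.offset_mode == "genomic"),
        )
        result.hits[pop] = hits
        result.bin_distribution[pop] = probe_map.position_distribution(hits)
        in_probe_keys = {(h.chrom, h.pos) for h in hits}
        lookup = panel.by_position()
        result.function_tables[pop] = func_annot.tabulate_function_classes(
            (lookup[k] for k in sorted(in_probe_keys)), maf_filter="common", threshold=thr
        )
        log.append(f"{pop}: {len(hits)} probe hits over {len(in_probe_keys)} distinct in-probe SNPs")

        result.summaries[pop] = {}
        for mode in ("common", "all"):
            result.summaries[pop][mode] = catalogue.summarize_probesets(
                hits, panel, ann, maf_filter=mode, threshold=thr
            )
        active = result.summaries[pop][config.filter_mode]
        n_affected = sum(s.affected for s in active)
        log.append(f"{pop}: {n_affected} affected probesets under filter={config.filter_mode}")
        result.cluster_summaries[pop] = catalogue.summarize_clusters(active, ann)
        result.reliability[pop] = catalogue.breakdown_by_reliability(active, ann)
        result.chromosomes[pop] = catalogue.chromosome_enrichment_test(active, ann)
        if prior is not None:
            result.prior_comparison[pop] = catalogue.compare_with_prior(
                result.summaries[pop]["all"], prior
            )

        # stage outputs
        probe_map.write_probe_hits(hits, ann, out / f"probe_hits_{pop}.tsv",
                                   f"population={pop} filter=all offset={config.offset_mode}")
        variant_panel.write_variant_table(panel, out / f"variants_{pop}.tsv", thr)
        catalogue.write_probeset_summaries(
            [s for s in active if s.affected], out / f"affected_probesets_{pop}.tsv",
            f"population={pop} filter={config.filter_mode} maf_threshold={thr}")
        catalogue.write_cluster_summaries(result.cluster_summaries[pop],
                                          out / f"cluster_summary_{pop}.tsv",
                                          f"population={pop} filter={config.filter_mode}")
        catalogue.write_chromosome_distribution(result.chromosomes[pop],
                                                out / f"chromosome_distribution_{pop}.tsv",
                                                f"population={pop} filter={config.filter_mode}")
        with open(out / f"function_classes_{pop}.tsv", "w") as fh:
            fh.write(f"# population={pop} in-probe common SNPs, maf_threshold={thr}\n")
            fh.write("function_class\tcount\n")
            for cls, n in result.function_tables[pop].items():
                fh.write(f"{cls}\t{n}\n")
        if prior is not None:
            result.prior_comparison[pop].to_csv(out / f"prior_comparison_{pop}.tsv", sep="\t")

    result.union_affected = catalogue.union_across_populations(
        {p: result.summaries[p][config.filter_mode] for p in result.summaries}
    )
    log.append(f"union: {result.union_affected} probesets affected in >=1 population")

    # splicing-impact audit + re-test
    if config.targets_path and Path(config.targets_path).exists():
        targets = [
            str(t) for t in pd.read_csv(config.targets_path, sep="\t", dtype=str).probeset_id
        ]
        all_summaries = {p: result.summaries[p]["all"] for p in result.summaries}
        result.audit = splicing_impact.audit_probesets(targets, all_summaries, ann)
        splicing_impact.write_audit(result.audit, out / "splicing_audit.tsv",
                                    "worst case: novel SNPs at all frequencies")
        log.append(f"audit: {result.audit.n_affected_targets}/{result.audit.n_targets} "
                   f"targets affected by novel SNPs "
                   f"({len(result.audit.unknown_ids)} unknown ids)")

        if config.expression_path and Path(config.expression_path).exists():
            expr = ExpressionMatrix.from_tsv(config.expression_path, config.population_map_path)
            novel_hit_keys = {
                p: {k for s in all_summaries[p] for k in s.novel_snp_keys}
                for p in all_summaries
            }
            hits_novel = [
                h for p in result.hits for h in result.hits[p]
                if (h.chrom, h.pos) in novel_hit_keys[p]
            ]
            for rec in result.audit.records:
                ps = ann.probesets[rec.probeset_id]
                result.retests.append(
                    splicing_impact.reassess_with_without(
                        expr, ps, hits_novel,
                        flavor=config.ttest_flavor, summarizer=config.summarizer,
                    )
                )
            with open(out / "retest.tsv", "w") as fh:
                fh.write(f"# t-test={config.ttest_flavor} summarizer={config.summarizer}\n")
                fh.write("probeset_id\tp_with\tp_without\tn_probes_excluded\tmeasurable_without\n")
                for r in result.retests:
                    pw = f"{r.p_with:.6g}"
                    po = "" if r.p_without is None else f"{r.p_without:.6g}"
                    fh.write(f"{r.probeset_id}\t{pw}\t{po}\t{r.n_probes_excluded}\t"
                             f"{int(r.measurable_without)}\n")
            log.append(f"retest: {len(result.retests)} probesets re-assessed with/without "
                       "SNP-containing probes")

    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return result
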