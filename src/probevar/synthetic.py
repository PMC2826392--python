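"""Self-contained synthetic fixtures for the SNP-in-probe survey.

The generator emulates the structures the survey consumes: a gene model
(UTR exons, coding exons, introns, 2-kb flanks) tiled by 25-mer probes
grouped four-per-probeset into probesets and gene-level clusters; two
population panels (57 + 56 samples by default) with genotypes drawn in
Hardy-Weinberg proportions from population-specific allele frequencies
(Balding-Nichols divergence around a shared ancestral frequency); a
known/novel split of variants into a dbSNP-style catalogue; and
probe-level log2 intensities with a dose-linear hybridization-artifact
effect on probes overlapping a variant.  Everything is recorded in a
machine-readable truth table so each pipeline stage can be validated
against planted ground truth.

Variants are unlinked (no LD) — linkage is irrelevant to interval
mapping — and genotype calls are error-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .array_model import (
    ArrayAnnotation,
    GenomicInterval,
    Probe,
    Probeset,
    RELIABILITY_CLASSES,
    TranscriptCluster,
    write_array_annotation,
)
from .catalogue import PriorCatalogue, count_class_of, write_prior_catalogue
from .func_annot import GeneModel, write_gene_models
from .probe_map import ProbeHit, is_middle, offset_bin
from .splicing_impact import ExpressionMatrix
from .variant_panel import (
    DEFAULT_MAF_THRESHOLD,
    KnownSnpRecord,
    PopulationPanel,
    Variant,
    classify_frequency,
    compute_maf,
)

NUCS = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions being emulated.

    Panel sizes default to 57 and 56 samples, probesets to four 25-mer
    probes, near-gene flanks to 2000 bases.  ``variant_density`` (per kb)
    is set so the default geometry carries on the order of 5,000 variants;
    ``fraction_known`` plants a 70/30 known/novel split.  The artifact is
    a per-alt-allele drop of ``artifact_delta`` log2 units against probe
    noise of ``noise_sd``; ``population_freq_divergence`` is the
    Balding-Nichols F between the two panels.
    """

    seed: int = 0
    n_chromosomes: int = 4
    n_genes: int = 200
    probesets_per_gene: int = 4
    probes_per_probeset: int = 4
    probe_length: int = 25
    n_samples: Dict[str, int] = field(default_factory=lambda: {"CEU": 57, "YRI": 56})
    variant_density: float = 4.0          # per kb
    maf_low: float = 0.01
    maf_high: float = 0.5
    fraction_known: float = 0.7
    near_gene_flank: int = 2000
    intron_length: int = 300
    intergenic_gap: int = 2000
    artifact_delta: float = 0.6           # log2 drop per alt allele
    noise_sd: float = 0.3                 # log2 units
    population_freq_divergence: float = 0.15
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    reliability_weights: Tuple[float, float, float] = (0.6, 0.25, 0.15)
    baseline_range: Tuple[float, float] = (5.0, 9.0)

    def validate(self) -> None:
        if min(self.n_chromosomes, self.n_genes, self.probesets_per_gene,
               self.probes_per_probeset) < 1:
            raise ValueError("all counts must be >= 1")
        if self.probe_length < 5:
            raise ValueError("probe_length must be >= 5")
        for frac in (self.fraction_known, self.population_freq_divergence):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("maf spectrum must satisfy 0 <= low <= high <= 0.5")
        if min(self.n_samples.values()) < 1:
            raise ValueError("each population needs at least one sample")


@dataclass
class VariantTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    known: bool
    rsid: Optional[str]
    true_class: str
    expected_class: str          # class the annotation stage should assign
    host_gene: Optional[str]     # intragenic host, if any
    assoc_gene: Optional[str]    # gene backing the function class (incl. flanks)
    pop: Dict[str, dict] = field(default_factory=dict)
    genotypes: Dict[str, np.ndarray] = field(default_factory=dict)  # not serialized

    def present(self, population: str) -> bool:
        return self.pop[population]["alt_count"] > 0


@dataclass
class SyntheticTruth:
    """Planted ground truth for every pipeline stage."""

    variants: List[VariantTruth] = field(default_factory=list)
    #: probe id -> list of (chrom, pos, strand-aware offset)
    probe_hits: Dict[str, List[Tuple[str, int, int]]] = field(default_factory=dict)
    #: population -> filter ('common'|'all') -> summary tables
    tables: Dict[str, Dict[str, dict]] = field(default_factory=dict)
    #: population -> function-class histogram of in-probe common variants
    function_histogram: Dict[str, Dict[str, int]] = field(default_factory=dict)
    prior: PriorCatalogue = field(default_factory=dict)
    targets: List[str] = field(default_factory=list)

    def by_position(self) -> Dict[Tuple[str, int], VariantTruth]:
        return {(v.chrom, v.pos): v for v in self.variants}

    def to_json(self, path) -> None:
        payload = {
            "variants": [
                {k: v for k, v in dataclasses.asdict(vt).items() if k != "genotypes"}
                for vt in self.variants
            ],
            "probe_hits": {k: [list(t) for t in v] for k, v in self.probe_hits.items()},
            "tables": self.tables,
            "function_histogram": self.function_histogram,
            "prior": {pid: sorted(map(list, keys)) for pid, keys in self.prior.items()},
            "targets": self.targets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        truth = cls()
        for d in payload["variants"]:
            truth.variants.append(VariantTruth(**d))
        truth.probe_hits = {
            k: [tuple(t) for t in v] for k, v in payload["probe_hits"].items()
        }
        truth.tables = payload["tables"]
        truth.function_histogram = payload["function_histogram"]
        truth.prior = {
            pid: frozenset((c, int(p)) for c, p in keys)
            for pid, keys in payload["prior"].items()
        }
        truth.targets = payload["targets"]
        return truth


# ---------------------------------------------------------------------------
# array geometry
# ---------------------------------------------------------------------------

@dataclass
class ArrayLayout:
    annotation: ArrayAnnotation
    genes: List[GeneModel]
    chrom_lengths: Dict[str, int]


def simulate_array(config: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> ArrayLayout:
    """Lay genes with UTR/coding exons and introns along chromosomes and
    tile every exon with one probeset of contiguous probes."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    exon_len = config.probes_per_probeset * config.probe_length
    probes: dict = {}
    probesets: dict = {}
    clusters: dict = {}
    genes: List[GeneModel] = []
    chrom_lengths: Dict[str, int] = {}
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil

    for gi in range(config.n_genes):
        chrom = f"chr{gi // per_chrom + 1}"
        cursor = chrom_lengths.get(chrom, config.intergenic_gap)
        gene_start = cursor + config.near_gene_flank + 1  # 1-based
        strand = "+" if rng.random() < 0.5 else "-"
        exon_ivs = []
        pos = gene_start
        for _ in range(config.probesets_per_gene):
            exon_ivs.append(GenomicInterval.from_1based(chrom, pos, pos + exon_len - 1, strand))
            pos += exon_len + config.intron_length
        gene_end = exon_ivs[-1].end1
        gene_iv = GenomicInterval.from_1based(chrom, gene_start, gene_end, strand)
        # 5'/3' UTR exons follow the strand; exons are listed left to right
        if config.probesets_per_gene >= 2:
            utr_left, utr_right = exon_ivs[0], exon_ivs[-1]
            utr5, utr3 = (utr_left, utr_right) if strand == "+" else (utr_right, utr_left)
        else:
            utr5 = utr3 = None
        gene_id = f"G{gi:04d}"
        cluster_id = f"TC{gi:04d}"
        genes.append(GeneModel(gene_id, gene_iv, tuple(exon_ivs), utr5, utr3))

        member_ids = []
        for j, exon in enumerate(exon_ivs):
            ps_id = f"PS{gi:04d}.{j}"
            member_ids.append(ps_id)
            reliability = rng.choice(RELIABILITY_CLASSES, p=config.reliability_weights)
            probe_ids = []
            for k in range(config.probes_per_probeset):
                p_start = exon.start1 + k * config.probe_length
                pr_id = f"PR{gi:04d}.{j}.{k}"
                probe_ids.append(pr_id)
                probes[pr_id] = Probe(
                    pr_id,
                    GenomicInterval.from_1based(chrom, p_start, p_start + config.probe_length - 1, strand),
                    ps_id,
                )
            probesets[ps_id] = Probeset(ps_id, exon, cluster_id, str(reliability), tuple(probe_ids))
        clusters[cluster_id] = TranscriptCluster(cluster_id, gene_iv, gene_id, tuple(member_ids))
        chrom_lengths[chrom] = gene_end + config.near_gene_flank + config.intergenic_gap

    ann = ArrayAnnotation(probes, probesets, clusters, genome_build="synthetic-v1")
    return ArrayLayout(ann, genes, chrom_lengths)


# ---------------------------------------------------------------------------
# variants, genotypes, truth
# ---------------------------------------------------------------------------

def _true_function_class(
    pos: int, chrom: str, genes: List[GeneModel], flank: int, rng: np.random.Generator
) -> Tuple[str, Optional[str], Optional[str]]:
    """(class, intragenic host gene, gene backing the class)."""
    best = None  # (distance, gene)
    for g in genes:
        iv = g.interval
        if iv.chrom != chrom:
            continue
        if iv.contains_pos(pos):
            for exon in g.exons:
                if exon.contains_pos(pos):
                    if g.utr5 is not None and exon == g.utr5:
                        return "utr-5", g.gene_id, g.gene_id
                    if g.utr3 is not None and exon == g.utr3:
                        return "utr-3", g.gene_id, g.gene_id
                    coding = rng.choice(
                        ["coding-synonymous", "missense", "nonsense"], p=[0.5, 0.45, 0.05]
                    )
                    return str(coding), g.gene_id, g.gene_id
            return "intron", g.gene_id, g.gene_id
        dist = iv.start1 - pos if pos < iv.start1 else pos - iv.end1
        if 0 < dist <= flank and (best is None or dist < best[0]):
            best = (dist, g)
    if best is not None:
        g = best[1]
        upstream = pos < g.interval.start1
        if g.strand == "+":
            cls = "near-gene-5" if upstream else "near-gene-3"
        else:
            cls = "near-gene-3" if upstream else "near-gene-5"
        return cls, None, g.gene_id
    return "NA", None, None


def _expected_novel_class(
    pos: int,
    known_sorted: List[Tuple[int, Optional[str], str]],
    window: int,
) -> str:
    """Bookkeeping twin of the two-sided neighbor rule, via plain scans."""
    left = right = None
    for p, gene, cls in known_sorted:
        if p < pos:
            left = (p, gene, cls)
        elif p > pos:
            right = (p, gene, cls)
            break
    if left is None or right is None:
        return "NA"
    if left[2] != right[2] or left[1] != right[1] or left[1] is None:
        return "NA"
    cls = left[2]
    if cls in ("utr-5", "utr-3"):
        return cls
    if cls in ("near-gene-5", "near-gene-3"):
        if pos - left[0] <= window and right[0] - pos <= window:
            return cls
    return "NA"


def simulate_variants(
    config: SyntheticConfig,
    layout: ArrayLayout,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, PopulationPanel], List[KnownSnpRecord], SyntheticTruth]:
    """Poisson-place variants, draw per-population frequencies and HWE
    genotypes, split known/novel, and record the full truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    pops = list(config.n_samples)
    sample_ids = {p: [f"{p}{i:03d}" for i in range(config.n_samples[p])] for p in pops}
    F = config.population_freq_divergence

    truth = SyntheticTruth()
    rs_counter = 1
    for chrom in sorted(layout.chrom_lengths):
        L = layout.chrom_lengths[chrom]
        n = rng.poisson(config.variant_density * L / 1000.0)
        n = min(n, L)
        positions = np.sort(rng.choice(L, size=n, replace=False)) + 1
        chrom_genes = [g for g in layout.genes if g.interval.chrom == chrom]
        for pos in positions:
            ref, alt = rng.choice(NUCS, size=2, replace=False)
            p_anc = rng.uniform(config.maf_low, config.maf_high)
            cls, host, assoc = _true_function_class(
                int(pos), chrom, chrom_genes, config.near_gene_flank, rng
            )
            known = bool(rng.random() < config.fraction_known)
            rsid = f"rs{rs_counter}" if known else None
            if known:
                rs_counter += 1
            vt = VariantTruth(
                chrom=chrom, pos=int(pos), ref=str(ref), alt=str(alt),
                known=known, rsid=rsid, true_class=cls, expected_class=cls,
                host_gene=host, assoc_gene=assoc,
            )
            for pop in pops:
                if F > 0:
                    p_pop = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
                else:
                    p_pop = p_anc
                g = rng.binomial(2, p_pop, size=config.n_samples[pop])
                alt_count = int(g.sum())
                n_called = 2 * config.n_samples[pop]
                freq = alt_count / n_called
                vt.genotypes[pop] = g
                vt.pop[pop] = {
                    "drawn_freq": float(p_pop),
                    "alt_count": alt_count,
                    "n_called": n_called,
                    "alt_freq": freq,
                    "maf": compute_maf(freq),
                    "freq_class": classify_frequency(compute_maf(freq), config.maf_threshold),
                }
            truth.variants.append(vt)

    # known catalogue and expected class of novels via the neighbor rule
    catalogue = [
        KnownSnpRecord(v.rsid, v.chrom, v.pos, (v.ref, v.alt), v.true_class, v.assoc_gene)
        for v in truth.variants
        if v.known
    ]
    known_by_chrom: Dict[str, List[Tuple[int, Optional[str], str]]] = {}
    for v in truth.variants:
        if v.known and v.true_class != "NA":
            known_by_chrom.setdefault(v.chrom, []).append((v.pos, v.assoc_gene, v.true_class))
    for v in truth.variants:
        if not v.known:
            v.expected_class = _expected_novel_class(
                v.pos, known_by_chrom.get(v.chrom, []), config.near_gene_flank
            )

    _record_probe_hits(truth, layout)
    _record_tables(truth, layout, config)

    panels = {
        pop: PopulationPanel(
            pop,
            sample_ids[pop],
            [
                Variant(
                    chrom=v.chrom, pos=v.pos, ref_allele=v.ref, alt_allele=v.alt,
                    population=pop, alt_freq=v.pop[pop]["alt_freq"],
                    n_called=v.pop[pop]["n_called"],
                )
                for v in truth.variants
                if v.present(pop)
            ],
        )
        for pop in pops
    }
    return panels, catalogue, truth


def _record_probe_hits(truth: SyntheticTruth, layout: ArrayLayout) -> None:
    """Vectorized containment scan over all (variant, probe) pairs."""
    probes = list(layout.annotation.probes.values())
    by_chrom: Dict[str, list] = {}
    for p in probes:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    var_by_chrom: Dict[str, List[VariantTruth]] = {}
    for v in truth.variants:
        var_by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, plist in by_chrom.items():
        vlist = var_by_chrom.get(chrom, [])
        if not vlist:
            continue
        starts = np.array([p.interval.start1 for p in plist])
        ends = np.array([p.interval.end1 for p in plist])
        pos = np.array([v.pos for v in vlist])
        inside = (pos[:, None] >= starts[None, :]) & (pos[:, None] <= ends[None, :])
        vi, pi = np.nonzero(inside)
        for a, b in zip(vi, pi):
            probe = plist[b]
            v = vlist[a]
            if probe.interval.strand == "-":
                off = probe.interval.end1 - v.pos + 1
            else:
                off = v.pos - probe.interval.start1 + 1
            truth.probe_hits.setdefault(probe.probe_id, []).append((v.chrom, v.pos, int(off)))


def _record_tables(truth: SyntheticTruth, layout: ArrayLayout, config: SyntheticConfig) -> None:
    ann = layout.annotation
    lookup = truth.by_position()
    # distinct in-probe variants per probeset
    per_set: Dict[str, set] = {}
    for probe_id, hit_list in truth.probe_hits.items():
        pid = ann.probes[probe_id].probeset_id
        per_set.setdefault(pid, set()).update((c, p) for c, p, _ in hit_list)

    # prior catalogue: known in-probe SNP keys per probeset
    prior: Dict[str, set] = {}
    for pid, keys in per_set.items():
        known_keys = {k for k in keys if lookup[k].known}
        if known_keys:
            prior[pid] = known_keys
    truth.prior = {pid: frozenset(v) for pid, v in prior.items()}

    thr = config.maf_threshold
    for pop in config.n_samples:
        truth.tables[pop] = {}
        for mode in ("common", "all"):
            classes: Dict[str, str] = {}
            novelty: Dict[str, str] = {}
            affected: List[str] = []
            hist = {c: 0 for c in ("0", "1", "2", "3+")}
            reliability = {r: 0 for r in RELIABILITY_CLASSES}
            matrix = {
                r: {c: 0 for c in ("Novel", "Known", "Both")} for r in ("1", "2", "3+")
            }
            per_set_detail: Dict[str, dict] = {}
            for pid in sorted(ann.probesets):
                keys = [
                    k
                    for k in per_set.get(pid, ())
                    if lookup[k].present(pop)
                    and (mode == "all" or lookup[k].pop[pop]["freq_class"] == "common")
                ]
                n = len(keys)
                n_novel = sum(1 for k in keys if not lookup[k].known)
                n_known = n - n_novel
                n_rare_novel = sum(
                    1
                    for k in keys
                    if not lookup[k].known and lookup[k].pop[pop]["freq_class"] == "rare"
                )
                cc = count_class_of(n)
                hist[cc] += 1
                if n == 0:
                    nv = "none"
                elif n_novel and n_known:
                    nv = "both"
                elif n_novel:
                    nv = "novel"
                else:
                    nv = "known"
                classes[pid] = cc
                novelty[pid] = nv
                if n > 0:
                    affected.append(pid)
                    reliability[ann.probesets[pid].reliability] += 1
                    matrix[cc]["Both" if nv == "both" else ("Novel" if nv == "novel" else "Known")] += 1
                    per_set_detail[pid] = {
                        "n_novel": n_novel,
                        "n_known": n_known,
                        "n_rare_among_novel": n_rare_novel,
                    }
            truth.tables[pop][mode] = {
                "affected": affected,
                "count_class": classes,
                "novelty_class": novelty,
                "count_class_histogram": hist,
                "reliability": reliability,
                "novelty_matrix": matrix,
                "detail": per_set_detail,
            }

        # Table-1-style histogram: in-probe, common, expected assigned classes
        in_probe = {k for keys in per_set.values() for k in keys}
        hist_fc: Dict[str, int] = {}
        for k in sorted(in_probe):
            v = lookup[k]
            if v.present(pop) and v.pop[pop]["freq_class"] == "common":
                hist_fc[v.expected_class] = hist_fc.get(v.expected_class, 0) + 1
        truth.function_histogram[pop] = hist_fc


# ---------------------------------------------------------------------------
# expression with a planted hybridization artifact
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SyntheticConfig,
    layout: ArrayLayout,
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Probe log2 intensity = probeset baseline - artifact_delta x alt-allele
    dose (per variant inside the probe) + Gaussian noise.  No population
    mean effect is planted: between-population differences arise only
    through allele-frequency differences at in-probe variants."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    ann = layout.annotation
    pops = list(config.n_samples)
    samples = [f"{p}{i:03d}" for p in pops for i in range(config.n_samples[p])]
    populations = {f"{p}{i:03d}": p for p in pops for i in range(config.n_samples[p])}
    pop_slices = {}
    start = 0
    for p in pops:
        pop_slices[p] = slice(start, start + config.n_samples[p])
        start += config.n_samples[p]

    lookup = truth.by_position()
    baselines = {
        pid: rng.uniform(*config.baseline_range) for pid in sorted(ann.probesets)
    }
    probe_ids = sorted(ann.probes)
    values = np.zeros((len(probe_ids), len(samples)))
    for i, probe_id in enumerate(probe_ids):
        row = np.full(len(samples), baselines[ann.probes[probe_id].probeset_id])
        for chrom, pos, _off in truth.probe_hits.get(probe_id, ()):
            vt = lookup[(chrom, pos)]
            for p in pops:
                row[pop_slices[p]] = row[pop_slices[p]] - config.artifact_delta * vt.genotypes[p]
        values[i] = row
    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    df = pd.DataFrame(values, index=probe_ids, columns=samples)
    return ExpressionMatrix(df, populations)


def pick_targets(
    truth: SyntheticTruth,
    layout: ArrayLayout,
    rng: np.random.Generator,
    n_targets: int = 50,
) -> List[str]:
    """Probesets of interest for the audit: a mixture of probesets
    affected by novel SNPs in exactly one population and clean ones."""
    pops = list(truth.tables)
    lookup = truth.by_position()
    per_set: Dict[str, Dict[str, int]] = {}
    for probe_id, hit_list in truth.probe_hits.items():
        pid = layout.annotation.probes[probe_id].probeset_id
        for chrom, pos, _ in hit_list:
            v = lookup[(chrom, pos)]
            if v.known:
                continue
            for p in pops:
                if v.present(p):
                    per_set.setdefault(pid, {}).setdefault(p, 0)
                    per_set[pid][p] += 1
    one_pop = sorted(pid for pid, d in per_set.items() if len(d) == 1)
    clean = sorted(set(layout.annotation.probesets) - set(per_set))
    k1 = min(len(one_pop), n_targets // 2)
    chosen = list(rng.choice(one_pop, size=k1, replace=False)) if k1 else []
    k2 = min(len(clean), n_targets - k1)
    chosen += list(rng.choice(clean, size=k2, replace=False)) if k2 else []
    return sorted(map(str, chosen))


# ---------------------------------------------------------------------------
# ARMC10-like artifact re-test demo
# ---------------------------------------------------------------------------

#: Allele frequency of the planted population-specific demo variant.  The
#: demo mirrors the worst case the audit targets: a novel SNP common in one
#: panel and absent from the other.
DEMO_ALT_FREQ = 0.45


def simulate_artifact_probeset(
    config: SyntheticConfig,
    rng: np.random.Generator,
    artifact_delta: Optional[float] = None,
) -> Tuple[ExpressionMatrix, Probeset, List[ProbeHit]]:
    """One four-probe probeset with a variant planted in its first probe,
    common in the first population and absent from the second."""
    delta = config.artifact_delta if artifact_delta is None else artifact_delta
    pops = list(config.n_samples)
    k = config.probe_length
    chrom = "chrD"
    ps_start = 1001
    probe_ids = [f"PRD.{i}" for i in range(config.probes_per_probeset)]
    probes = {
        pid: Probe(
            pid,
            GenomicInterval.from_1based(chrom, ps_start + i * k, ps_start + (i + 1) * k - 1, "+"),
            "PSD.0",
        )
        for i, pid in enumerate(probe_ids)
    }
    probeset = Probeset(
        "PSD.0",
        GenomicInterval.from_1based(chrom, ps_start, ps_start + config.probes_per_probeset * k - 1, "+"),
        "TCD",
        "core",
        tuple(probe_ids),
    )
    pos = ps_start + 9  # offset 10, middle region
    doses = {pops[0]: rng.binomial(2, DEMO_ALT_FREQ, config.n_samples[pops[0]]),
             pops[1]: np.zeros(config.n_samples[pops[1]], dtype=int)}
    samples = [f"{p}{i:03d}" for p in pops for i in range(config.n_samples[p])]
    dose_row = np.concatenate([doses[p] for p in pops])
    baseline = 8.0
    values = np.full((len(probe_ids), len(samples)), baseline)
    values[0] = baseline - delta * dose_row
    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples),
        {f"{p}{i:03d}": p for p in pops for i in range(config.n_samples[p])},
    )
    off = 10
    hits = [
        ProbeHit(chrom, pos, pops[0], probe_ids[0], probeset.probeset_id, "TCD",
                 off, offset_bin(off), is_middle(off, k))
    ]
    return expr, probeset, hits


def artifact_retest_replicates(
    config: SyntheticConfig,
    n_replicates: int = 100,
    base_seed: Optional[int] = None,
    artifact_delta: Optional[float] = None,
    flavor: str = "pooled",
) -> dict:
    """Run the with/without re-test over seeded replicates.

    Returns p-value lists and the fraction of replicates reproducing the
    qualitative pattern p_with < 0.05 and p_without > 0.05.
    """
    from .splicing_impact import reassess_with_without

    seed = config.seed if base_seed is None else base_seed
    p_with, p_without = [], []
    for i in range(n_replicates):
        rng = np.random.default_rng([seed % (2**31), i])
        expr, probeset, hits = simulate_artifact_probeset(config, rng, artifact_delta)
        res = reassess_with_without(expr, probeset, hits, flavor=flavor)
        p_with.append(res.p_with)
        p_without.append(res.p_without)
    success = sum(
        1 for pw, po in zip(p_with, p_without) if pw < 0.05 and po is not None and po > 0.05
    )
    return {
        "p_with": p_with,
        "p_without": p_without,
        "success_fraction": success / n_replicates,
        "reject_with": sum(p < 0.05 for p in p_with) / n_replicates,
        "reject_without": sum(p is not None and p < 0.05 for p in p_without) / n_replicates,
    }


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class BundleData:
    config: SyntheticConfig
    layout: ArrayLayout
    panels: Dict[str, PopulationPanel]
    catalogue: List[KnownSnpRecord]
    truth: SyntheticTruth
    expression: ExpressionMatrix
    targets: List[str]


def generate_bundle(config: SyntheticConfig) -> BundleData:
    """Generate every fixture in memory, deterministically from the seed."""
    config.validate()
    layout = simulate_array(config, np.random.default_rng([config.seed % (2**31), 0]))
    panels, catalogue, truth = simulate_variants(
        config, layout, np.random.default_rng([config.seed % (2**31), 1])
    )
    expr = simulate_expression(
        config, layout, truth, np.random.default_rng([config.seed % (2**31), 2])
    )
    targets = pick_targets(truth, layout, np.random.default_rng([config.seed % (2**31), 3]))
    truth.targets = targets
    return BundleData(config, layout, panels, catalogue, truth, expr, targets)


def _write_vcf(path, population: str, sample_ids, variants: List[VariantTruth],
               chrom_lengths: Dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=probevar-synthetic\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for v in variants:
            gts = "\t".join(
                "0/0" if g == 0 else ("0/1" if g == 1 else "1/1")
                for g in v.genotypes[population]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_known_snp_table(records: List[KnownSnpRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\talleles\tfunction_class\tgene\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{r.rsid}\t{r.chrom}\t{r.pos}\t{r.alleles[0]}/{r.alleles[1]}\t"
                f"{r.function_class}\t{r.gene or ''}\n"
            )


def write_fixture_bundle(config: SyntheticConfig, out_dir) -> Dict[str, str]:
    """Write the full fixture bundle and a checksummed manifest.

    Returns the manifest as a dict of file name -> sha256.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    layout, truth = bundle.layout, bundle.truth
    write_array_annotation(layout.annotation, out / "probes.tsv", out / "probesets.tsv")
    write_gene_models(layout.genes, out / "genes.tsv")
    for pop, panel in bundle.panels.items():
        present = [v for v in truth.variants if v.present(pop)]
        _write_vcf(out / f"{pop}.vcf", pop, panel.sample_ids, present, layout.chrom_lengths)
    write_known_snp_table(bundle.catalogue, out / "known_snps.tsv")
    write_prior_catalogue(truth.prior, out / "prior_catalogue.tsv")
    bundle.expression.to_tsv(out / "expression.tsv", out / "sample_populations.tsv")
    with open(out / "targets.tsv", "w") as fh:
        fh.write("probeset_id\n")
        for t in bundle.targets:
            fh.write(t + "\n")
    truth.to_json(out / "truth.json")

    files = [
        "probes.tsv", "probesets.tsv", "genes.tsv",
        *[f"{p}.vcf" for p in bundle.panels],
        "known_snps.tsv", "prior_catalogue.tsv", "expression.tsv",
        "sample_populations.tsv", "targets.tsv", "truth.json",
    ]
    manifest = {}
    for name in files:
        manifest[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    with open(out / "manifest.txt", "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"config.{f.name}={getattr(config, f.name)}\n")
        for name in files:
            fh.write(f"sha256.{name}={manifest[name]}\n")
    return manifest
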