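"""dbSNP-style functional classes, host-gene imputation, and
neighbor-based functional imputation for novel variants.

Known variants keep their catalogue class verbatim.  A novel variant can
inherit a UTR or near-gene class when the nearest annotated neighbor on
*each* side carries the same class and the same host gene; for near-gene
classes both neighbors must additionally lie within a window (default
2000 bases) of the variant.  One-sided evidence is never enough, and
coding classes are never imputed — they require codon context that a
positional rule cannot supply.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .array_model import GenomicInterval
from .variant_panel import (
    DEFAULT_MAF_THRESHOLD,
    KnownSnpRecord,
    PopulationPanel,
    Variant,
)

FUNCTION_CLASSES = (
    "coding-synonymous",
    "frameshift",
    "intron",
    "missense",
    "near-gene-3",
    "near-gene-5",
    "nonsense",
    "reference",
    "splice-3",
    "splice-5",
    "utr-3",
    "utr-5",
    "NA",
)

NA = "NA"

#: Classes a novel variant may inherit from flanking annotated neighbors.
IMPUTABLE_UTR = ("utr-5", "utr-3")
IMPUTABLE_NEAR_GENE = ("near-gene-5", "near-gene-3")

DEFAULT_NEAR_GENE_WINDOW = 2000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    exons: Tuple[GenomicInterval, ...] = ()
    utr5: Optional[GenomicInterval] = None
    utr3: Optional[GenomicInterval] = None

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class AnnotatedNeighbor:
    """A positionally annotated SNP usable as imputation evidence."""

    pos: int
    gene: Optional[str]
    function_class: str

    def __post_init__(self) -> None:
        if self.function_class == NA:
            raise ValueError("neighbor function class must not be NA")


class GeneIndex:
    """Interval index over gene models, per chromosome."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: Dict[str, IntervalTree] = {}
        self.genes: Dict[str, GeneModel] = {}
        for g in genes:
            self.genes[g.gene_id] = g
            tree = self._trees.setdefault(g.interval.chrom, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g)

    def overlapping(self, chrom: str, pos1: int) -> List[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos1 - 1)]
        # deterministic primary: smallest span, id as tie-break
        hits.sort(key=lambda g: (g.interval.length, g.gene_id))
        return hits


def impute_host_gene(variant: Variant, genes: GeneIndex) -> List[str]:
    """All genes containing the variant, smallest span first.

    Sets ``variant.host_gene`` to the primary candidate (or ``None``) and
    returns the full candidate list.
    """
    candidates = [g.gene_id for g in genes.overlapping(variant.chrom, variant.pos)]
    variant.host_gene = candidates[0] if candidates else None
    return candidates


def impute_function_from_neighbors(
    pos: int,
    neighbors: Sequence[AnnotatedNeighbor],
    near_gene_window: int = DEFAULT_NEAR_GENE_WINDOW,
) -> str:
    """Two-sided nearest-neighbor imputation of UTR / near-gene classes.

    ``neighbors`` must be sorted by position (same chromosome as the
    variant).  The nearest neighbor strictly to the left and strictly to
    the right must agree on class and gene; near-gene classes require
    both to lie within ``near_gene_window`` bases of the variant.
    """
    positions = [n.pos for n in neighbors]
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("neighbor list must be sorted by position")
    i = bisect_left(positions, pos)
    left = None
    j = i - 1
    while j >= 0:
        if positions[j] < pos:
            left = neighbors[j]
            break
        j -= 1
    right = None
    j = i
    while j < len(neighbors):
        if positions[j] > pos:
            right = neighbors[j]
            break
        j += 1
    if left is None or right is None:
        return NA
    if left.function_class != right.function_class or left.gene != right.gene or left.gene is None:
        return NA
    cls = left.function_class
    if cls in IMPUTABLE_UTR:
        return cls
    if cls in IMPUTABLE_NEAR_GENE:
        if (pos - left.pos) <= near_gene_window and (right.pos - pos) <= near_gene_window:
            return cls
        return NA
    return NA


def build_neighbor_index(records: Iterable[KnownSnpRecord]) -> Dict[str, List[AnnotatedNeighbor]]:
    """Per-chromosome sorted neighbor lists from catalogue records with a class."""
    by_chrom: Dict[str, List[AnnotatedNeighbor]] = {}
    for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
        if r.function_class == NA:
            continue
        by_chrom.setdefault(r.chrom, []).append(
            AnnotatedNeighbor(r.pos, r.gene, r.function_class)
        )
    return by_chrom


def assign_function(
    variant: Variant,
    catalogue: Mapping[Tuple[str, int], KnownSnpRecord],
    genes: GeneIndex,
    neighbors: Mapping[str, Sequence[AnnotatedNeighbor]],
    near_gene_window: int = DEFAULT_NEAR_GENE_WINDOW,
) -> str:
    """Assign a function class; host gene is recorded either way."""
    impute_host_gene(variant, genes)
    if variant.known:
        rec = catalogue.get(variant.key)
        variant.function_class = rec.function_class if rec is not None else (variant.function_class or NA)
    else:
        variant.function_class = impute_function_from_neighbors(
            variant.pos, neighbors.get(variant.chrom, ()), near_gene_window
        )
    return variant.function_class


def annotate_panel_functions(
    panel: PopulationPanel,
    catalogue: Mapping[Tuple[str, int], KnownSnpRecord],
    genes: GeneIndex,
    neighbors: Mapping[str, Sequence[AnnotatedNeighbor]],
    near_gene_window: int = DEFAULT_NEAR_GENE_WINDOW,
) -> PopulationPanel:
    for v in panel.variants:
        assign_function(v, catalogue, genes, neighbors, near_gene_window)
    return panel


def tabulate_function_classes(
    variants: Iterable[Variant],
    maf_filter: Optional[str] = None,
    threshold: float = DEFAULT_MAF_THRESHOLD,
) -> Dict[str, int]:
    """Count variants per function class, optionally restricted by MAF class.

    All classes appear in the result (zero counts included) and the counts
    sum to the size of the filtered variant set.
    """
    counts = Counter()
    for v in variants:
        if maf_filter is not None and v.freq_class(threshold) != maf_filter:
            continue
        counts[v.function_class or NA] += 1
    return {c: counts.get(c, 0) for c in FUNCTION_CLASSES}


# ---------------------------------------------------------------------------
# gene-model I/O: flat TSV with one row per feature
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "feature"]


def read_gene_models(path) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    genes: List[GeneModel] = []
    for gid, sub in df.groupby("gene_id", sort=True):
        iv = None
        exons = []
        utr5 = utr3 = None
        for row in sub.itertuples(index=False):
            g = GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end), row.strand)
            if row.feature == "gene":
                iv = g
            elif row.feature == "exon":
                exons.append(g)
            elif row.feature == "utr5":
                utr5 = g
            elif row.feature == "utr3":
                utr3 = g
        if iv is None:
            raise ValueError(f"{path}: gene {gid} has no 'gene' feature row")
        exons.sort(key=lambda e: e.start)
        genes.append(GeneModel(str(gid), iv, tuple(exons), utr5, utr3))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")

        def row(g: GeneModel, iv: GenomicInterval, feature: str) -> str:
            return "\t".join(
                [g.gene_id, iv.chrom, str(iv.start1), str(iv.end1), g.strand, feature]
            )

        for g in genes:
            fh.write(row(g, g.interval, "gene") + "\n")
            for e in g.exons:
                fh.write(row(g, e, "exon") + "\n")
            if g.utr5 is not None:
                fh.write(row(g, g.utr5, "utr5") + "\n")
            if g.utr3 is not None:
                fh.write(row(g, g.utr3, "utr3") + "\n")
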