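"""Per-population variant panels: VCF intake, allele frequencies, MAF
classes, and known/novel status against a dbSNP-style catalogue.

Frequencies are computed per population from called genotypes only
(missing alleles excluded from the denominator), with no pooling across
populations and no relatedness correction.  A variant is *common* when
its minor allele frequency strictly exceeds the threshold (default 5%);
the boundary value folds into *rare*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: MAF above which a variant is called common (strict inequality).
DEFAULT_MAF_THRESHOLD = 0.05


class VcfFormatError(ValueError):
    pass


def compute_maf(alt_freq: float) -> float:
    """Minor allele frequency: ``min(alt_freq, 1 - alt_freq)``."""
    if not 0.0 <= alt_freq <= 1.0:
        raise ValueError(f"alt_freq must lie in [0, 1], got {alt_freq}")
    return min(alt_freq, 1.0 - alt_freq)


def classify_frequency(maf: float, threshold: float = DEFAULT_MAF_THRESHOLD) -> str:
    """'common' iff ``maf > threshold`` (strict), else 'rare'."""
    if not 0.0 <= maf <= 0.5 + 1e-12:
        raise ValueError(f"maf must lie in [0, 0.5], got {maf}")
    return "common" if maf > threshold else "rare"


@dataclass
class Variant:
    """One biallelic SNV observed in one population panel."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    population: str
    alt_freq: float
    n_called: int
    known: bool = False
    rsid: Optional[str] = None
    function_class: Optional[str] = None
    host_gene: Optional[str] = None
    allele_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alleles must be single nucleotides, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"{self.chrom}:{self.pos}: alt_freq {self.alt_freq} out of range")

    @property
    def maf(self) -> float:
        return compute_maf(self.alt_freq)

    @property
    def key(self) -> Tuple[str, int]:
        return (self.chrom, self.pos)

    def freq_class(self, threshold: float = DEFAULT_MAF_THRESHOLD) -> str:
        return classify_frequency(self.maf, threshold)


@dataclass(frozen=True)
class KnownSnpRecord:
    """One row of the known-SNP catalogue (rsid, position, alleles, class)."""

    rsid: str
    chrom: str
    pos: int
    alleles: Tuple[str, str]
    function_class: str = "NA"
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")


@dataclass
class PopulationPanel:
    population: str
    sample_ids: List[str]
    variants: List[Variant] = field(default_factory=list)
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError("panel must contain at least one sample")
        self.variants.sort(key=lambda v: (v.chrom, v.pos, v.alt_allele))

    def by_position(self) -> Dict[Tuple[str, int], Variant]:
        return {v.key: v for v in self.variants}


def read_population_vcf(path, population: str, pass_only: bool = False) -> PopulationPanel:
    """Read diploid GT genotypes from a VCF into a :class:`PopulationPanel`.

    One :class:`Variant` is emitted per biallelic SNV; multi-allelic SNV
    records are split into one variant per alternate allele (sharing the
    position and the called-allele denominator).  Indels, symbolic and
    multi-nucleotide records are skipped and counted.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample columns")
    if "GT" not in vcf.header.formats:
        raise VcfFormatError(f"{path}: VCF has no GT FORMAT field")

    variants: List[Variant] = []
    n_skipped = 0
    for rec in vcf:
        if pass_only and rec.filter.keys() not in ([], ["PASS"]):
            continue
        ref = rec.ref
        alts = rec.alts or ()
        # tally called alleles once per record; denominator shared by splits
        allele_counts: Dict[int, int] = {}
        n_called = 0
        for s in samples:
            gt = rec.samples[s].get("GT", (None,))
            for a in gt:
                if a is None:
                    continue
                n_called += 1
                allele_counts[a] = allele_counts.get(a, 0) + 1
        for j, alt in enumerate(alts, start=1):
            if ref is None or len(ref) != 1 or alt is None or len(alt) != 1 \
                    or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                n_skipped += 1
                continue
            if n_called == 0:
                n_skipped += 1
                continue
            variants.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    population=population,
                    alt_freq=allele_counts.get(j, 0) / n_called,
                    n_called=n_called,
                )
            )
    if n_skipped:
        logger.warning("%s: skipped %d non-SNV or uncalled allele records", path, n_skipped)
    return PopulationPanel(population, samples, variants, n_skipped)


def read_known_snp_table(path) -> List[KnownSnpRecord]:
    """Read the known-SNP catalogue TSV: rsid, chrom, pos, alleles, function_class, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("rsid", "chrom", "pos", "alleles"):
        if col not in df.columns:
            raise VcfFormatError(f"{path}: missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        alleles = tuple(row.alleles.split("/"))
        if len(alleles) != 2:
            raise VcfFormatError(f"{path}: alleles must be 'X/Y', got {row.alleles!r}")
        fc = getattr(row, "function_class", None)
        gene = getattr(row, "gene", None)
        records.append(
            KnownSnpRecord(
                rsid=row.rsid,
                chrom=row.chrom,
                pos=int(row.pos),
                alleles=alleles,  # type: ignore[arg-type]
                function_class="NA" if fc is None or pd.isna(fc) else fc,
                gene=None if gene is None or pd.isna(gene) else gene,
            )
        )
    return records


def catalogue_by_position(records: Iterable[KnownSnpRecord]) -> Dict[Tuple[str, int], KnownSnpRecord]:
    return {(r.chrom, r.pos): r for r in records}


def annotate_known_status(
    panel: PopulationPanel,
    catalogue: Mapping[Tuple[str, int], KnownSnpRecord],
) -> PopulationPanel:
    """Mark variants known/novel by positional match against the catalogue.

    Matching is by (chrom, pos) only; an allele disagreement between the
    call set and the catalogue is flagged but does not revoke known status.
    The catalogue rsid and function class are copied onto matches.
    """
    for v in panel.variants:
        rec = catalogue.get(v.key)
        if rec is None:
            v.known = False
            continue
        v.known = True
        v.rsid = rec.rsid
        v.function_class = rec.function_class
        if {v.ref_allele, v.alt_allele} != set(rec.alleles):
            v.allele_mismatch = True
    return panel


def write_variant_table(panel: PopulationPanel, path, threshold: float = DEFAULT_MAF_THRESHOLD) -> None:
    cols = [
        "chrom", "pos", "ref", "alt", "population", "alt_freq", "maf",
        "freq_class", "n_called", "known", "rsid", "function_class", "host_gene",
    ]
    with open(path, "w") as fh:
        fh.write(f"# population={panel.population} maf_threshold={threshold}\n")
        fh.write("\t".join(cols) + "\n")
        for v in panel.variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom, str(v.pos), v.ref_allele, v.alt_allele, v.population,
                        f"{v.alt_freq:.6g}", f"{v.maf:.6g}", v.freq_class(threshold),
                        str(v.n_called), str(int(v.known)), v.rsid or "",
                        v.function_class or "NA", v.host_gene or "",
                    ]
                )
                + "\n"
            )
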