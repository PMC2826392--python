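"""Coordinate model and I/O for exon-array annotations.

The array is modelled at three levels: 25-mer *probes*, exon-level
*probesets* (typically four probes each), and gene-level *transcript
clusters*.  Coordinates at the I/O boundary are 1-based inclusive, the
convention used by vendor annotation files and genome browsers; internally
everything is 0-based half-open so that interval arithmetic has a single
conversion point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: Default probe length (nt) of the short-oligonucleotide arrays we model.
DEFAULT_PROBE_LENGTH = 25

RELIABILITY_CLASSES = ("core", "extended", "full")


class AnnotationFormatError(ValueError):
    """A required column or field is missing or malformed."""


class AnnotationIntegrityError(ValueError):
    """Cross-references between probes/probesets/clusters are broken."""


@dataclass(frozen=True)
class GenomicInterval:
    """A contiguous genomic span, stored 0-based half-open.

    Use :meth:`from_1based` when constructing from browser-style
    coordinates (1-based, inclusive ends) and the ``start1``/``end1``
    properties when writing them back out.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end} "
                "(end must exceed start in half-open coordinates)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @classmethod
    def from_1based(cls, chrom: str, start: int, end: int, strand: str = ".") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (``start <= end``)."""
        return cls(chrom, start - 1, end, strand)

    @property
    def start1(self) -> int:
        """1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos1: int) -> bool:
        """Whether the 1-based position lies inside the interval."""
        return self.start1 <= pos1 <= self.end1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Probe:
    probe_id: str
    interval: GenomicInterval
    probeset_id: str
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.interval.length:
            raise ValueError(
                f"probe {self.probe_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.interval.length}"
            )


@dataclass(frozen=True)
class Probeset:
    probeset_id: str
    interval: GenomicInterval
    transcript_cluster_id: str
    reliability: str = "core"
    probe_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.reliability not in RELIABILITY_CLASSES:
            raise ValueError(
                f"probeset {self.probeset_id}: reliability must be one of "
                f"{RELIABILITY_CLASSES}, got {self.reliability!r}"
            )


@dataclass(frozen=True)
class TranscriptCluster:
    cluster_id: str
    interval: GenomicInterval
    gene_symbol: Optional[str] = None
    probeset_ids: tuple = ()


@dataclass
class ArrayAnnotation:
    """Keyed collections of probes, probesets and transcript clusters.

    ``duplicate_probe_ids`` and ``n_skipped_probes`` record anomalies met
    while reading; :func:`validate_annotation` reports them alongside
    structural violations.
    """

    probes: dict = field(default_factory=dict)
    probesets: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)
    genome_build: str = "synthetic"
    duplicate_probe_ids: tuple = ()
    n_skipped_probes: int = 0

    def cluster_of_probeset(self, probeset_id: str) -> str:
        return self.probesets[probeset_id].transcript_cluster_id


@dataclass
class ValidationReport:
    n_probes: int
    n_probesets: int
    n_clusters: int
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


PROBE_COLUMNS = ["probe_id", "probeset_id", "chrom", "start", "stop", "strand"]
PROBESET_COLUMNS = [
    "probeset_id",
    "transcript_cluster_id",
    "chrom",
    "start",
    "stop",
    "strand",
    "reliability",
]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"{path}: missing column(s) {missing}")


def read_array_annotation(
    probe_path,
    probeset_path,
    dialect: str = "tsv",
    probe_length: int = DEFAULT_PROBE_LENGTH,
    genome_build: str = "unknown",
) -> ArrayAnnotation:
    """Read probe and probeset tables (tab-separated, 1-based inclusive).

    Probes whose span differs from ``probe_length`` (e.g. control probes)
    are skipped with a logged warning and counted in
    ``ArrayAnnotation.n_skipped_probes``.  Reliability defaults to ``core``
    when the column is absent so downstream breakdowns stay computable.
    """
    if dialect != "tsv":
        raise AnnotationFormatError(f"unknown annotation dialect {dialect!r}")
    probes_df = pd.read_csv(probe_path, sep="\t", dtype=str, comment="#")
    probesets_df = pd.read_csv(probeset_path, sep="\t", dtype=str, comment="#")
    _require_columns(probes_df, PROBE_COLUMNS, probe_path)
    _require_columns(probesets_df, [c for c in PROBESET_COLUMNS if c != "reliability"], probeset_path)
    if probes_df.empty:
        raise AnnotationIntegrityError(f"{probe_path}: probe table is empty")

    probesets: dict = {}
    cluster_members: dict = {}
    for row in probesets_df.itertuples(index=False):
        iv = GenomicInterval.from_1based(row.chrom, int(row.start), int(row.stop), row.strand)
        reliability = getattr(row, "reliability", None)
        if reliability is None or pd.isna(reliability) or reliability == "":
            reliability = "core"
        ps = Probeset(row.probeset_id, iv, row.transcript_cluster_id, reliability)
        probesets[ps.probeset_id] = ps
        cluster_members.setdefault(row.transcript_cluster_id, []).append(ps.probeset_id)

    probes: dict = {}
    probes_by_set: dict = {ps: [] for ps in probesets}
    duplicates = []
    n_skipped = 0
    orphans = []
    for row in probes_df.itertuples(index=False):
        iv = GenomicInterval.from_1based(row.chrom, int(row.start), int(row.stop), row.strand)
        if iv.length != probe_length:
            n_skipped += 1
            continue
        if row.probeset_id not in probesets:
            orphans.append(row.probe_id)
            continue
        seq = getattr(row, "sequence", None)
        if isinstance(seq, float):  # pandas NaN
            seq = None
        probe = Probe(row.probe_id, iv, row.probeset_id, seq)
        if probe.probe_id in probes:
            duplicates.append(probe.probe_id)
        probes[probe.probe_id] = probe
        probes_by_set[probe.probeset_id].append(probe.probe_id)
    if orphans:
        raise AnnotationIntegrityError(
            f"{probe_path}: probes reference unknown probesets: {orphans[:10]}"
        )
    if n_skipped:
        logger.warning("skipped %d probes with length != %d", n_skipped, probe_length)

    # attach probe memberships and build clusters from probeset spans
    for pid, members in probes_by_set.items():
        ps = probesets[pid]
        probesets[pid] = Probeset(
            ps.probeset_id, ps.interval, ps.transcript_cluster_id, ps.reliability, tuple(members)
        )

    gene_col = "gene_symbol" in probesets_df.columns
    clusters: dict = {}
    for cid, member_ids in cluster_members.items():
        ivs = [probesets[m].interval for m in member_ids]
        chrom = ivs[0].chrom
        iv = GenomicInterval(chrom, min(i.start for i in ivs), max(i.end for i in ivs), ivs[0].strand)
        symbol = None
        if gene_col:
            sub = probesets_df[probesets_df.transcript_cluster_id == cid]
            vals = sub.gene_symbol.dropna().unique()
            symbol = vals[0] if len(vals) else None
        clusters[cid] = TranscriptCluster(cid, iv, symbol, tuple(member_ids))

    return ArrayAnnotation(
        probes=probes,
        probesets=probesets,
        clusters=clusters,
        genome_build=genome_build,
        duplicate_probe_ids=tuple(duplicates),
        n_skipped_probes=n_skipped,
    )


def write_array_annotation(ann: ArrayAnnotation, probe_path, probeset_path) -> None:
    """Write the two annotation tables, back-converting to 1-based inclusive."""
    any_seq = any(p.sequence for p in ann.probes.values())
    with open(probe_path, "w") as fh:
        cols = PROBE_COLUMNS + (["sequence"] if any_seq else [])
        fh.write("\t".join(cols) + "\n")
        for p in ann.probes.values():
            row = [
                p.probe_id,
                p.probeset_id,
                p.interval.chrom,
                str(p.interval.start1),
                str(p.interval.end1),
                p.interval.strand,
            ]
            if any_seq:
                row.append(p.sequence or "")
            fh.write("\t".join(row) + "\n")
    with open(probeset_path, "w") as fh:
        fh.write("\t".join(PROBESET_COLUMNS) + "\n")
        for ps in ann.probesets.values():
            fh.write(
                "\t".join(
                    [
                        ps.probeset_id,
                        ps.transcript_cluster_id,
                        ps.interval.chrom,
                        str(ps.interval.start1),
                        str(ps.interval.end1),
                        ps.interval.strand,
                        ps.reliability,
                    ]
                )
                + "\n"
            )


def export_probes_bed(ann: ArrayAnnotation, path) -> None:
    """Export probes in BED convention (0-based half-open)."""
    with open(path, "w") as fh:
        for p in ann.probes.values():
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.probe_id}\t0\t{iv.strand}\n"
            )


def validate_annotation(ann: ArrayAnnotation) -> ValidationReport:
    """Report every structural invariant violation; never raises."""
    report = ValidationReport(len(ann.probes), len(ann.probesets), len(ann.clusters))
    v = report.violations
    for dup in ann.duplicate_probe_ids:
        v.append(("duplicate_probe_id", dup, "probe id occurs more than once"))
    for p in ann.probes.values():
        ps = ann.probesets.get(p.probeset_id)
        if ps is None:
            v.append(("unknown_probeset", p.probe_id, f"references {p.probeset_id}"))
        elif not ps.interval.contains(p.interval):
            v.append(
                (
                    "probe_outside_probeset",
                    p.probe_id,
                    f"{p.interval.chrom}:{p.interval.start1}-{p.interval.end1} "
                    f"not within probeset {ps.probeset_id}",
                )
            )
    for ps in ann.probesets.values():
        cl = ann.clusters.get(ps.transcript_cluster_id)
        if cl is None:
            v.append(("unknown_cluster", ps.probeset_id, f"references {ps.transcript_cluster_id}"))
        elif ps.probeset_id not in cl.probeset_ids:
            v.append(("cluster_membership", ps.probeset_id, "not listed by its cluster"))
        if not ps.probe_ids:
            v.append(("empty_probeset", ps.probeset_id, "no probes"))
    for cl in ann.clusters.values():
        if not cl.probeset_ids:
            v.append(("empty_cluster", cl.cluster_id, "no probesets"))
    return report
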