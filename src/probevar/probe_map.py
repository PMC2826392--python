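"""Mapping variants onto probes by genomic position.

Overlap is strand-agnostic (a single-base variant is *in* a probe iff its
position lies in the probe's closed genomic interval); strand only affects
the within-probe offset, which is counted 1..k from the probe sequence's
5' end.  Offsets are binned 5 nt at a time (bin 1 = offsets 1-5, 5' side)
and a *middle* flag marks offsets 6..k-4 — the region where a mismatch
perturbs hybridization most (positions 6-21 of a 25-mer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from intervaltree import IntervalTree

from .array_model import ArrayAnnotation, DEFAULT_PROBE_LENGTH, Probe
from .variant_panel import DEFAULT_MAF_THRESHOLD, PopulationPanel


@dataclass(frozen=True)
class ProbeHit:
    """One (variant, probe) containment event."""

    chrom: str
    pos: int  # 1-based variant position
    population: str
    probe_id: str
    probeset_id: str
    cluster_id: str
    offset: int
    bin: int
    middle: bool


class HitIndex:
    """Point-in-interval index over the probes of an annotation."""

    def __init__(self, ann: ArrayAnnotation):
        self.ann = ann
        self._trees: Dict[str, IntervalTree] = {}
        for probe in ann.probes.values():
            iv = probe.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, probe)

    def query(self, chrom: str, pos1: int) -> List[Probe]:
        """Probes whose closed interval contains the 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        probes = [iv.data for iv in tree.at(pos1 - 1)]
        probes.sort(key=lambda p: p.probe_id)
        return probes


def build_probe_index(ann: ArrayAnnotation) -> HitIndex:
    return HitIndex(ann)


def probe_offset(pos: int, probe: Probe, genomic: bool = False) -> int:
    """1-based offset of a position from the probe's 5' end.

    Plus strand (and ``genomic=True``): ``pos - start + 1``; minus strand:
    ``end - pos + 1``.  Raises if the position is outside the probe.
    """
    iv = probe.interval
    if not iv.contains_pos(pos):
        raise ValueError(
            f"position {iv.chrom}:{pos} outside probe {probe.probe_id} "
            f"({iv.chrom}:{iv.start1}-{iv.end1})"
        )
    if iv.strand == "-" and not genomic:
        return iv.end1 - pos + 1
    return pos - iv.start1 + 1


def offset_bin(offset: int, bin_size: int = 5) -> int:
    return (offset - 1) // bin_size + 1


def is_middle(offset: int, probe_length: int = DEFAULT_PROBE_LENGTH) -> bool:
    """Middle region: offsets 6 .. k-4 (6-21 for a 25-mer)."""
    return 6 <= offset <= probe_length - 4


def map_variants_to_probes(
    panel: PopulationPanel,
    index: HitIndex,
    maf_filter: Optional[str] = None,
    threshold: float = DEFAULT_MAF_THRESHOLD,
    genomic_offset: bool = False,
) -> List[ProbeHit]:
    """One :class:`ProbeHit` per (variant, probe) containment pair.

    ``maf_filter`` of 'common' or 'rare' restricts the variant set; a
    variant inside two overlapping probes yields two hits.  Results are
    in stable (chrom, pos, probe_id) order.
    """
    ann = index.ann
    hits: List[ProbeHit] = []
    for v in panel.variants:
        if maf_filter is not None and v.freq_class(threshold) != maf_filter:
            continue
        for probe in index.query(v.chrom, v.pos):
            off = probe_offset(v.pos, probe, genomic=genomic_offset)
            hits.append(
                ProbeHit(
                    chrom=v.chrom,
                    pos=v.pos,
                    population=v.population,
                    probe_id=probe.probe_id,
                    probeset_id=probe.probeset_id,
                    cluster_id=ann.cluster_of_probeset(probe.probeset_id),
                    offset=off,
                    bin=offset_bin(off),
                    middle=is_middle(off, probe.interval.length),
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.pos, h.probe_id))
    return hits


@dataclass
class BinDistribution:
    """Counts of hits per 5-nt bin plus summary fractions."""

    counts: Dict[int, int] = field(default_factory=dict)
    n: int = 0
    frac_central: float = 0.0  # bins 2..(n_bins-1), offsets 6..k-5
    frac_middle: float = 0.0   # offsets 6..k-4


def position_distribution(
    hits: Iterable[ProbeHit],
    probe_length: int = DEFAULT_PROBE_LENGTH,
    bin_size: int = 5,
) -> BinDistribution:
    n_bins = (probe_length + bin_size - 1) // bin_size
    counts = {b: 0 for b in range(1, n_bins + 1)}
    n = 0
    central = 0
    middle = 0
    for h in hits:
        counts[h.bin] += 1
        n += 1
        if 2 <= h.bin <= n_bins - 1:
            central += 1
        if h.middle:
            middle += 1
    return BinDistribution(
        counts=counts,
        n=n,
        frac_central=central / n if n else 0.0,
        frac_middle=middle / n if n else 0.0,
    )


def write_probe_hits(hits: Iterable[ProbeHit], ann: ArrayAnnotation, path, header_note: str = "") -> None:
    """Probe-level hit table: cluster, probeset, probe coordinates, SNP
    position and its offset along the probe sequence."""
    cols = [
        "transcript_cluster_id", "probeset_id", "probe_id", "chrom",
        "probe_start", "probe_end", "strand", "snp_pos", "offset", "bin", "middle",
    ]
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            iv = ann.probes[h.probe_id].interval
            fh.write(
                "\t".join(
                    [
                        h.cluster_id, h.probeset_id, h.probe_id, h.chrom,
                        str(iv.start1), str(iv.end1), iv.strand,
                        str(h.pos), str(h.offset), str(h.bin), str(int(h.middle)),
                    ]
                )
                + "\n"
            )
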