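"""Worked example: the ARMC10 probeset with a population-specific novel SNP.

Probeset 3017096 (chr7:102526627-102527377, hg18) interrogates ARMC10
together with probesets 3017094, 3017095 and 3017088; a novel SNP at
chr7:102526628 in the CEU panel falls inside its probe
chr7:102526627-102526651.  The coordinates of probeset 3017096 and its
first probe are the published ones; the remaining probes and the
neighbor probesets are synthetic stand-ins laid out schematically so the
annotation is structurally complete.
"""

from __future__ import annotations

from typing import Dict

from .array_model import ArrayAnnotation, GenomicInterval, Probe, Probeset, TranscriptCluster
from .probe_map import build_probe_index, map_variants_to_probes
from .variant_panel import PopulationPanel, Variant

ARMC10_CLUSTER = "2954425"
ARMC10_PROBESET = "3017096"
ARMC10_SNP_POS = 102526628


def armc10_annotation() -> ArrayAnnotation:
    """Four-probeset annotation around the ARMC10 example region."""
    chrom = "chr7"

    def make_probeset(ps_id, start, end, probe_starts):
        probes = {}
        ids = []
        for i, s in enumerate(probe_starts):
            pid = f"{ps_id}_p{i + 1}"
            ids.append(pid)
            probes[pid] = Probe(
                pid, GenomicInterval.from_1based(chrom, s, s + 24, "+"), ps_id
            )
        ps = Probeset(
            ps_id, GenomicInterval.from_1based(chrom, start, end, "+"),
            ARMC10_CLUSTER, "core", tuple(ids),
        )
        return ps, probes

    layout = {
        # published span and first-probe start; remaining probes schematic
        "3017096": (102526627, 102527377, [102526627, 102526827, 102527027, 102527227]),
        # schematic neighbor probesets (synthetic stand-ins)
        "3017088": (102520000, 102520199, [102520000, 102520050, 102520100, 102520150]),
        "3017094": (102522000, 102522199, [102522000, 102522050, 102522100, 102522150]),
        "3017095": (102524000, 102524199, [102524000, 102524050, 102524100, 102524150]),
    }
    probes: Dict[str, Probe] = {}
    probesets: Dict[str, Probeset] = {}
    for ps_id, (start, end, starts) in layout.items():
        ps, ps_probes = make_probeset(ps_id, start, end, starts)
        probesets[ps_id] = ps
        probes.update(ps_probes)
    span = GenomicInterval.from_1based(chrom, 102520000, 102527377, "+")
    clusters = {
        ARMC10_CLUSTER: TranscriptCluster(ARMC10_CLUSTER, span, "ARMC10", tuple(sorted(probesets)))
    }
    return ArrayAnnotation(probes, probesets, clusters, genome_build="hg18")


def armc10_panel() -> PopulationPanel:
    """A one-variant CEU panel: the novel SNP at chr7:102526628."""
    v = Variant(
        chrom="chr7", pos=ARMC10_SNP_POS, ref_allele="A", alt_allele="G",
        population="CEU", alt_freq=0.10, n_called=114,
    )
    return PopulationPanel("CEU", [f"CEU{i:03d}" for i in range(57)], [v])


def armc10_report() -> dict:
    """Map the example SNP onto the example annotation and summarize."""
    ann = armc10_annotation()
    panel = armc10_panel()
    hits = map_variants_to_probes(panel, build_probe_index(ann))
    affected_probesets = sorted({h.probeset_id for h in hits})
    return {
        "affected_probesets": affected_probesets,
        "n_affected_probes": len({h.probe_id for h in hits}),
        "probe_id": hits[0].probe_id if hits else None,
        "offset": hits[0].offset if hits else None,
        "bin": hits[0].bin if hits else None,
        "middle": hits[0].middle if hits else None,
    }
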