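"""Aggregation of probe hits into the survey's headline tables.

A probeset is *affected* when at least one of its probes contains at
least one variant passing the active MAF filter; a variant hitting two
overlapping probes of the same probeset is counted once (counts are
distinct SNPs, not hits).  Probesets are classed by SNP count {0, 1, 2,
3+} and by novelty {novel, known, both, none}; per-cluster,
per-chromosome (with an exact binomial enrichment test) and
per-reliability breakdowns follow, along with a comparison against a
prior SNP-in-probe catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
from scipy.stats import binomtest

from .array_model import ArrayAnnotation, RELIABILITY_CLASSES
from .probe_map import ProbeHit
from .variant_panel import DEFAULT_MAF_THRESHOLD, PopulationPanel

COUNT_CLASSES = ("0", "1", "2", "3+")
NOVELTY_CLASSES = ("novel", "known", "both", "none")


def count_class_of(n: int) -> str:
    if n < 0:
        raise ValueError("negative count")
    return str(n) if n < 3 else "3+"


@dataclass
class ProbesetSummary:
    probeset_id: str
    population: str
    n_snps_total: int = 0
    n_snps_common: int = 0
    n_novel: int = 0
    n_known: int = 0
    n_rare_among_novel: int = 0
    count_class: str = "0"
    novelty_class: str = "none"
    affected_probe_ids: Tuple[str, ...] = ()
    novel_probe_ids: Tuple[str, ...] = ()
    snp_keys: Tuple[Tuple[str, int], ...] = ()
    novel_snp_keys: Tuple[Tuple[str, int], ...] = ()

    @property
    def affected(self) -> bool:
        return self.count_class != "0"


@dataclass
class ClusterSummary:
    cluster_id: str
    population: str
    n_affected_probesets: int
    n_total_probesets: int


@dataclass
class ChromosomeStats:
    chrom: str
    n_affected: int
    n_probesets: int
    expected_fraction: float
    p_value: Optional[float]
    p_bonferroni: Optional[float]


@dataclass
class ChromosomeDistribution:
    rows: Dict[str, ChromosomeStats] = field(default_factory=dict)
    total_affected: int = 0
    total_probesets: int = 0


class CatalogueIntegrityError(ValueError):
    pass


def summarize_probesets(
    hits: Iterable[ProbeHit],
    panel: PopulationPanel,
    ann: ArrayAnnotation,
    maf_filter: str = "common",
    threshold: float = DEFAULT_MAF_THRESHOLD,
) -> List[ProbesetSummary]:
    """Per-probeset summaries over every probeset in the annotation.

    ``maf_filter`` is 'common' (MAF strictly above the threshold) or
    'all'.  The count class, novelty class and novel/known/rare counts
    are computed over the filtered variant set; ``n_snps_total`` and
    ``n_snps_common`` are reported regardless of the filter.
    """
    if maf_filter not in ("common", "all"):
        raise ValueError("maf_filter must be 'common' or 'all'")
    lookup = panel.by_position()
    per_set: Dict[str, Dict[Tuple[str, int], set]] = {}
    for h in hits:
        if h.probeset_id not in ann.probesets:
            raise CatalogueIntegrityError(f"hit references unknown probeset {h.probeset_id}")
        per_set.setdefault(h.probeset_id, {}).setdefault((h.chrom, h.pos), set()).add(h.probe_id)

    summaries: List[ProbesetSummary] = []
    for pid in sorted(ann.probesets):
        variant_probes = per_set.get(pid, {})
        all_keys = sorted(variant_probes)
        common_keys = [k for k in all_keys if lookup[k].freq_class(threshold) == "common"]
        keys = common_keys if maf_filter == "common" else all_keys
        n_novel = n_known = n_rare_novel = 0
        novel_keys = []
        probes: set = set()
        novel_probes: set = set()
        for k in keys:
            v = lookup[k]
            probes |= variant_probes[k]
            if v.known:
                n_known += 1
            else:
                n_novel += 1
                novel_keys.append(k)
                novel_probes |= variant_probes[k]
                if v.freq_class(threshold) == "rare":
                    n_rare_novel += 1
        n = len(keys)
        if n == 0:
            novelty = "none"
        elif n_novel and n_known:
            novelty = "both"
        elif n_novel:
            novelty = "novel"
        else:
            novelty = "known"
        summaries.append(
            ProbesetSummary(
                probeset_id=pid,
                population=panel.population,
                n_snps_total=len(all_keys),
                n_snps_common=len(common_keys),
                n_novel=n_novel,
                n_known=n_known,
                n_rare_among_novel=n_rare_novel,
                count_class=count_class_of(n),
                novelty_class=novelty,
                affected_probe_ids=tuple(sorted(probes)),
                novel_probe_ids=tuple(sorted(novel_probes)),
                snp_keys=tuple(keys),
                novel_snp_keys=tuple(novel_keys),
            )
        )
    return summaries


def count_class_histogram(summaries: Iterable[ProbesetSummary]) -> Dict[str, int]:
    out = {c: 0 for c in COUNT_CLASSES}
    for s in summaries:
        out[s.count_class] += 1
    return out


def summarize_clusters(
    summaries: Iterable[ProbesetSummary], ann: ArrayAnnotation
) -> List[ClusterSummary]:
    by_id = {s.probeset_id: s for s in summaries}
    population = next(iter(by_id.values())).population if by_id else ""
    out = []
    for cid in sorted(ann.clusters):
        members = ann.clusters[cid].probeset_ids
        n_aff = sum(1 for m in members if m in by_id and by_id[m].affected)
        out.append(ClusterSummary(cid, population, n_aff, len(members)))
    return out


def breakdown_by_reliability(
    summaries: Iterable[ProbesetSummary], ann: ArrayAnnotation
) -> Dict[str, int]:
    out = {r: 0 for r in RELIABILITY_CLASSES}
    for s in summaries:
        if s.affected:
            out[ann.probesets[s.probeset_id].reliability] += 1
    return out


def chromosome_enrichment_test(
    summaries: Iterable[ProbesetSummary], ann: ArrayAnnotation
) -> ChromosomeDistribution:
    """Exact two-sided binomial test of affected-probeset counts per
    chromosome against the chromosome's share of all probesets, with
    Bonferroni-adjusted p-values alongside."""
    per_chrom_total: Dict[str, int] = {}
    for ps in ann.probesets.values():
        per_chrom_total[ps.interval.chrom] = per_chrom_total.get(ps.interval.chrom, 0) + 1
    per_chrom_affected = {c: 0 for c in per_chrom_total}
    total_affected = 0
    for s in summaries:
        if s.affected:
            total_affected += 1
            per_chrom_affected[ann.probesets[s.probeset_id].interval.chrom] += 1
    total = sum(per_chrom_total.values())
    m = len(per_chrom_total)
    dist = ChromosomeDistribution(total_affected=total_affected, total_probesets=total)
    for chrom in sorted(per_chrom_total):
        frac = per_chrom_total[chrom] / total
        if total_affected == 0:
            p = p_adj = None
        else:
            p = binomtest(per_chrom_affected[chrom], total_affected, frac).pvalue
            p_adj = min(1.0, p * m)
        dist.rows[chrom] = ChromosomeStats(
            chrom, per_chrom_affected[chrom], per_chrom_total[chrom], frac, p, p_adj
        )
    return dist


# ---------------------------------------------------------------------------
# prior-catalogue comparison
# ---------------------------------------------------------------------------

PriorCatalogue = Dict[str, FrozenSet[Tuple[str, int]]]


def read_prior_catalogue(path) -> PriorCatalogue:
    """TSV with columns probeset_id, chrom, pos — one prior SNP key per row."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("probeset_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: Dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.probeset_id, set()).add((row.chrom, int(row.pos)))
    return {k: frozenset(v) for k, v in out.items()}


def write_prior_catalogue(prior: PriorCatalogue, path) -> None:
    with open(path, "w") as fh:
        fh.write("probeset_id\tchrom\tpos\n")
        for pid in sorted(prior):
            for chrom, pos in sorted(prior[pid]):
                fh.write(f"{pid}\t{chrom}\t{pos}\n")


def compare_with_prior(
    summaries: Iterable[ProbesetSummary], prior: PriorCatalogue
) -> pd.DataFrame:
    """Cross-tabulate affected probesets: SNP-count class x prior status.

    Each affected probeset is 'Novel' when all of its SNPs are absent
    from the prior catalogue, 'Known' when all are present, and 'Both'
    otherwise.  By construction the 1-SNP row has Both = 0.
    """
    table = pd.DataFrame(
        0, index=["1", "2", "3+", "Total"], columns=["Novel", "Known", "Both", "Total"]
    )
    for s in summaries:
        if not s.affected:
            continue
        prior_keys = prior.get(s.probeset_id, frozenset())
        keys = set(s.snp_keys)
        n_old = len(keys & prior_keys)
        n_new = len(keys) - n_old
        col = "Both" if (n_old and n_new) else ("Novel" if n_new else "Known")
        table.loc[s.count_class, col] += 1
    table.loc["Total"] = table.loc[["1", "2", "3+"]].sum()
    table["Total"] = table[["Novel", "Known", "Both"]].sum(axis=1)
    return table


def union_across_populations(
    summaries_by_population: Mapping[str, Iterable[ProbesetSummary]]
) -> int:
    """Number of probesets affected in at least one population."""
    affected: set = set()
    for summaries in summaries_by_population.values():
        affected |= {s.probeset_id for s in summaries if s.affected}
    return len(affected)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_probeset_summaries(summaries: Iterable[ProbesetSummary], path, note: str = "") -> None:
    cols = [
        "probeset_id", "population", "n_snps_total", "n_snps_common", "n_novel",
        "n_known", "n_rare_among_novel", "count_class", "novelty_class",
        "affected_probe_ids",
    ]
    with open(path, "w") as fh:
        if note:
            fh.write(f"# {note}\n")
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            fh.write(
                "\t".join(
                    [
                        s.probeset_id, s.population, str(s.n_snps_total),
                        str(s.n_snps_common), str(s.n_novel), str(s.n_known),
                        str(s.n_rare_among_novel), s.count_class, s.novelty_class,
                        ",".join(s.affected_probe_ids),
                    ]
                )
                + "\n"
            )


def write_cluster_summaries(summaries: Iterable[ClusterSummary], path, note: str = "") -> None:
    with open(path, "w") as fh:
        if note:
            fh.write(f"# {note}\n")
        fh.write("cluster_id\tpopulation\tn_affected_probesets\tn_total_probesets\n")
        for c in summaries:
            fh.write(f"{c.cluster_id}\t{c.population}\t{c.n_affected_probesets}\t{c.n_total_probesets}\n")


def write_chromosome_distribution(dist: ChromosomeDistribution, path, note: str = "") -> None:
    with open(path, "w") as fh:
        if note:
            fh.write(f"# {note}\n")
        fh.write("chrom\tn_affected\tn_probesets\texpected_fraction\tp_value\tp_bonferroni\n")
        for chrom in sorted(dist.rows):
            r = dist.rows[chrom]
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            pb = "" if r.p_bonferroni is None else f"{r.p_bonferroni:.6g}"
            fh.write(f"{r.chrom}\t{r.n_affected}\t{r.n_probesets}\t{r.expected_fraction:.6g}\t{p}\t{pb}\n")
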