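"""Audit of probesets of interest for in-probe novel SNPs, and a
with/without re-test of a two-group comparison.

The audit is run in a worst-case mode: every novel SNP counts, common or
rare, because even a rare mismatch in one population can bias a
between-population contrast.  The re-test summarizes a probeset as the
per-sample mean (or median) of its probe log2 intensities, first over
all probes and then excluding SNP-containing probes; a probeset whose
probes are all SNP-containing is reported as not measurable rather than
given a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .array_model import ArrayAnnotation, Probeset
from .catalogue import ProbesetSummary
from .probe_map import ProbeHit


class NotMeasurableError(ValueError):
    """Every probe of the probeset is excluded; no expression estimate."""


@dataclass
class ExpressionMatrix:
    """Probe x sample grid of log2 intensities with population labels."""

    values: pd.DataFrame                 # index: probe ids, columns: sample ids
    populations: Dict[str, str]          # sample id -> population label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate probe or sample ids in expression matrix")
        unlabeled = [s for s in self.values.columns if s not in self.populations]
        if unlabeled:
            raise ValueError(f"samples without population label: {unlabeled[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def probe_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def to_tsv(self, matrix_path, population_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id", float_format="%.10g")
        with open(population_path, "w") as fh:
            fh.write("sample_id\tpopulation\n")
            for s in self.values.columns:
                fh.write(f"{s}\t{self.populations[s]}\n")

    @classmethod
    def from_tsv(cls, matrix_path, population_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
        popmap = pd.read_csv(population_path, sep="\t", dtype=str)
        populations = dict(zip(popmap.sample_id, popmap.population))
        return cls(values, populations)


@dataclass
class ImpactRecord:
    probeset_id: str
    population: str
    n_novel_snps: int
    n_rare_among_novel: int
    n_probes_total: int
    n_probes_affected: int

    @property
    def still_measurable(self) -> bool:
        return self.n_probes_affected < self.n_probes_total


@dataclass
class AuditResult:
    records: List[ImpactRecord] = field(default_factory=list)
    unknown_ids: List[str] = field(default_factory=list)
    n_targets: int = 0
    n_affected_targets: int = 0
    frac_targets_affected: float = 0.0
    frac_affected_one_novel: float = 0.0


def audit_probesets(
    targets: Sequence[str],
    summaries_by_population: Mapping[str, Iterable[ProbesetSummary]],
    ann: ArrayAnnotation,
) -> AuditResult:
    """Audit target probesets for novel in-probe SNPs, per population.

    ``summaries_by_population`` must be computed over all frequencies
    (worst case).  One record is emitted per (target, population) with at
    least one novel SNP; a target is *affected* when any population has
    one.  ``frac_affected_one_novel`` is the share of affected targets
    whose union of novel SNPs across populations is a single SNP.
    """
    indexed = {
        pop: {s.probeset_id: s for s in summaries}
        for pop, summaries in summaries_by_population.items()
    }
    result = AuditResult()
    novel_union: Dict[str, Set[Tuple[str, int]]] = {}
    known_targets = []
    for t in targets:
        if t not in ann.probesets:
            result.unknown_ids.append(t)
            continue
        known_targets.append(t)
        for pop in sorted(indexed):
            s = indexed[pop].get(t)
            if s is None or s.n_novel == 0:
                continue
            result.records.append(
                ImpactRecord(
                    probeset_id=t,
                    population=pop,
                    n_novel_snps=s.n_novel,
                    n_rare_among_novel=s.n_rare_among_novel,
                    n_probes_total=len(ann.probesets[t].probe_ids),
                    n_probes_affected=len(s.novel_probe_ids),
                )
            )
            novel_union.setdefault(t, set()).update(s.novel_snp_keys)
    result.n_targets = len(known_targets)
    result.n_affected_targets = len(novel_union)
    if known_targets:
        result.frac_targets_affected = result.n_affected_targets / len(known_targets)
    if novel_union:
        result.frac_affected_one_novel = sum(
            1 for keys in novel_union.values() if len(keys) == 1
        ) / len(novel_union)
    return result


def probeset_expression(
    expr: ExpressionMatrix,
    probeset: Probeset,
    excluded_probes: Iterable[str] = (),
    summarizer: str = "mean",
) -> pd.Series:
    """Per-sample probeset value from its non-excluded probes."""
    excluded = set(excluded_probes)
    kept = [p for p in probeset.probe_ids if p not in excluded]
    if not kept:
        raise NotMeasurableError(
            f"probeset {probeset.probeset_id}: every probe excluded"
        )
    missing = [p for p in kept if p not in expr.values.index]
    if missing:
        raise KeyError(f"probes absent from expression matrix: {missing[:5]}")
    block = expr.values.loc[kept]
    if summarizer == "mean":
        return block.mean(axis=0)
    if summarizer == "median":
        return block.median(axis=0)
    raise ValueError(f"unknown summarizer {summarizer!r}")


def two_group_test(
    values: pd.Series,
    labels: Mapping[str, str],
    flavor: str = "pooled",
) -> Tuple[float, float]:
    """Two-sample t-test between the two population groups.

    ``flavor`` is 'pooled' (equal-variance) or 'welch'.  Returns the
    statistic and the two-sided p-value.
    """
    groups: Dict[str, List[float]] = {}
    for sample, v in values.items():
        groups.setdefault(labels[sample], []).append(float(v))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups)}")
    a, b = (np.asarray(groups[g]) for g in sorted(groups))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    res = stats.ttest_ind(a, b, equal_var=(flavor == "pooled"))
    return float(res.statistic), float(res.pvalue)


@dataclass
class ReassessResult:
    probeset_id: str
    p_with: float
    p_without: Optional[float]      # None when not measurable
    t_with: float = float("nan")
    t_without: Optional[float] = None
    n_probes_excluded: int = 0

    @property
    def measurable_without(self) -> bool:
        return self.p_without is not None


def reassess_with_without(
    expr: ExpressionMatrix,
    probeset: Probeset,
    hits: Iterable[ProbeHit],
    flavor: str = "pooled",
    summarizer: str = "mean",
) -> ReassessResult:
    """Two-group test with all probes, then excluding SNP-containing probes."""
    excluded = {h.probe_id for h in hits if h.probeset_id == probeset.probeset_id}
    t_with, p_with = two_group_test(
        probeset_expression(expr, probeset, (), summarizer), expr.populations, flavor
    )
    try:
        t_wo, p_wo = two_group_test(
            probeset_expression(expr, probeset, excluded, summarizer), expr.populations, flavor
        )
    except NotMeasurableError:
        t_wo = p_wo = None
    return ReassessResult(
        probeset_id=probeset.probeset_id,
        p_with=p_with,
        p_without=p_wo,
        t_with=t_with,
        t_without=t_wo,
        n_probes_excluded=len(excluded),
    )


def write_audit(result: AuditResult, path, note: str = "") -> None:
    with open(path, "w") as fh:
        if note:
            fh.write(f"# {note}\n")
        fh.write(
            "probeset_id\tpopulation\tn_novel_snps\tn_rare_among_novel\t"
            "n_probes_total\tn_probes_affected\tstill_measurable\n"
        )
        for r in result.records:
            fh.write(
                f"{r.probeset_id}\t{r.population}\t{r.n_novel_snps}\t"
                f"{r.n_rare_among_novel}\t{r.n_probes_total}\t{r.n_probes_affected}\t"
                f"{int(r.still_measurable)}\n"
            )
        if result.unknown_ids:
            fh.write("# unknown ids: " + ",".join(result.unknown_ids) + "\n")
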