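"""Probeset/cluster/chromosome cataloguing and prior-catalogue comparison."""

import numpy as np
import pytest

from probevar.array_model import GenomicInterval, Probe, Probeset, TranscriptCluster, ArrayAnnotation
from probevar.catalogue import (
    breakdown_by_reliability,
    chromosome_enrichment_test,
    compare_with_prior,
    count_class_histogram,
    count_class_of,
    read_prior_catalogue,
    summarize_clusters,
    summarize_probesets,
    union_across_populations,
    write_prior_catalogue,
    ProbesetSummary,
)
from probevar.probe_map import build_probe_index, map_variants_to_probes
from probevar.variant_panel import PopulationPanel, Variant, annotate_known_status, catalogue_by_position


def grid_annotation(n_probesets=4, probes_per=2, chrom="chr1", start=1000, reliability=None):
    """Non-overlapping probesets of contiguous 25-mers on one chromosome."""
    probes, probesets = {}, {}
    cursor = start
    members_all = []
    for i in range(n_probesets):
        ids = []
        ps_id = f"ps{i}"
        for k in range(probes_per):
            pid = f"ps{i}_p{k}"
            probes[pid] = Probe(
                pid, GenomicInterval.from_1based(chrom, cursor, cursor + 24, "+"), ps_id
            )
            ids.append(pid)
            cursor += 25
        probesets[ps_id] = Probeset(
            ps_id,
            GenomicInterval.from_1based(chrom, cursor - 25 * probes_per, cursor - 1, "+"),
            "tc0",
            (reliability or ["core"] * n_probesets)[i],
            tuple(ids),
        )
        members_all.append(ps_id)
        cursor += 50
    clusters = {
        "tc0": TranscriptCluster(
            "tc0", GenomicInterval.from_1based(chrom, start, cursor, "+"), None, tuple(members_all)
        )
    }
    return ArrayAnnotation(probes, probesets, clusters)


def make_panel(specs, population="CEU"):
    """specs: list of (pos, alt_freq, known) on chr1."""
    variants = []
    for pos, freq, known in specs:
        v = Variant("chr1", pos, "A", "G", population, freq, 100)
        v.known = known
        variants.append(v)
    return PopulationPanel(population, ["s1"], variants)


def summarize(ann, panel, maf_filter="common"):
    hits = map_variants_to_probes(panel, build_probe_index(ann))
    return summarize_probesets(hits, panel, ann, maf_filter=maf_filter)


class TestSummarizeProbesets:
    def test_single_common_variant_gives_class_one(self):
        ann = grid_annotation()
        panel = make_panel([(1010, 0.3, True)])
        by_id = {s.probeset_id: s for s in summarize(ann, panel)}
        assert by_id["ps0"].count_class == "1"
        assert by_id["ps0"].novelty_class == "known"
        assert by_id["ps1"].count_class == "0"
        assert by_id["ps1"].novelty_class == "none"

    def test_variant_in_overlapping_probes_counted_once(self):
        """Two probes of one probeset sharing a variant -> one SNP, two probes."""
        probes = {
            "a": Probe("a", GenomicInterval.from_1based("chr1", 100, 124, "+"), "ps0"),
            "b": Probe("b", GenomicInterval.from_1based("chr1", 110, 134, "+"), "ps0"),
        }
        ps = Probeset("ps0", GenomicInterval.from_1based("chr1", 100, 134, "+"), "tc0",
                      "core", ("a", "b"))
        tc = TranscriptCluster("tc0", ps.interval, None, ("ps0",))
        ann = ArrayAnnotation(probes, {"ps0": ps}, {"tc0": tc})
        panel = make_panel([(115, 0.3, False)])
        s = summarize(ann, panel)[0]
        assert s.n_snps_total == 1
        assert s.count_class == "1"
        assert set(s.affected_probe_ids) == {"a", "b"}

    def test_rare_among_novel_and_filters(self):
        ann = grid_annotation()
        panel = make_panel([(1010, 0.3, False), (1015, 0.02, False), (1020, 0.4, True)])
        common = {s.probeset_id: s for s in summarize(ann, panel, "common")}
        assert common["ps0"].count_class == "2"
        assert common["ps0"].n_rare_among_novel == 0
        allf = {s.probeset_id: s for s in summarize(ann, panel, "all")}
        assert allf["ps0"].count_class == "3+"
        assert allf["ps0"].n_novel == 2
        assert allf["ps0"].n_rare_among_novel == 1
        assert allf["ps0"].novelty_class == "both"

    def test_planted_class_histogram_recovered(self, small_bundle):
        from probevar.catalogue import count_class_histogram

        ann = small_bundle.layout.annotation
        cat = catalogue_by_position(small_bundle.catalogue)
        index = build_probe_index(ann)
        for pop, panel in small_bundle.panels.items():
            annotate_known_status(panel, cat)
            hits = map_variants_to_probes(panel, index)
            for mode in ("common", "all"):
                summaries = summarize_probesets(hits, panel, ann, maf_filter=mode)
                expected = small_bundle.truth.tables[pop][mode]["count_class_histogram"]
                assert count_class_histogram(summaries) == expected

    def test_count_class_one_never_both(self, small_survey):
        for pop, by_mode in small_survey.summaries.items():
            for summaries in by_mode.values():
                for s in summaries:
                    if s.count_class == "1":
                        assert s.novelty_class != "both"
                    assert (s.novelty_class == "none") == (s.count_class == "0")


class TestClustersAndReliability:
    def test_clean_cluster_zero_affected(self):
        ann = grid_annotation()
        panel = make_panel([(1, 0.3, True)])  # hits nothing
        clusters = summarize_clusters(summarize(ann, panel), ann)
        assert clusters[0].n_affected_probesets == 0
        assert clusters[0].n_total_probesets == 4

    def test_cluster_conservation(self, small_survey):
        ann = small_survey.annotation
        for pop, by_mode in small_survey.summaries.items():
            summaries = by_mode["common"]
            clusters = summarize_clusters(summaries, ann)
            assert sum(c.n_affected_probesets for c in clusters) == sum(
                s.affected for s in summaries
            )

    def test_reliability_breakdown_sums_to_affected(self):
        ann = grid_annotation(reliability=["core", "extended", "full", "core"])
        panel = make_panel([(1010, 0.3, True), (1210, 0.2, False)])  # ps0 and ps2
        summaries = summarize(ann, panel)
        breakdown = breakdown_by_reliability(summaries, ann)
        assert breakdown == {"core": 1, "extended": 0, "full": 1}
        assert sum(breakdown.values()) == sum(s.affected for s in summaries)

    def test_planted_reliability_recovered(self, small_bundle, small_survey):
        for pop in small_bundle.panels:
            expected = small_bundle.truth.tables[pop]["common"]["reliability"]
            got = breakdown_by_reliability(
                small_survey.summaries[pop]["common"], small_survey.annotation
            )
            assert got == expected


class TestChromosomeEnrichment:
    def test_single_chromosome_p_one(self):
        ann = grid_annotation()
        panel = make_panel([(1010, 0.3, True)])
        dist = chromosome_enrichment_test(summarize(ann, panel), ann)
        assert dist.rows["chr1"].expected_fraction == 1.0
        assert dist.rows["chr1"].p_value == pytest.approx(1.0)

    def test_zero_affected_reports_absent(self):
        ann = grid_annotation()
        panel = make_panel([(1, 0.3, True)])
        dist = chromosome_enrichment_test(summarize(ann, panel), ann)
        assert dist.total_affected == 0
        assert all(r.p_value is None for r in dist.rows.values())

    def test_all_on_one_of_four_chromosomes_tiny_p(self):
        """100 affected probesets on one of 4 equal chromosomes: p < 1e-6."""
        from scipy.stats import binomtest

        p = binomtest(100, 100, 0.25).pvalue
        assert p < 1e-6
        # and the pipeline wiring agrees with the direct computation
        summaries = [
            ProbesetSummary(f"ps{i}", "CEU", count_class="1", novelty_class="novel")
            for i in range(100)
        ]
        probes, probesets, clusters = {}, {}, {}
        for c in range(4):
            chrom = f"chr{c + 1}"
            ids = []
            for i in range(100):
                ps_id = f"ps{c * 100 + i}"
                iv = GenomicInterval.from_1based(chrom, 1 + i * 100, 100 + i * 100, "+")
                probesets[ps_id] = Probeset(ps_id, iv, f"tc{c}", "core", ())
                ids.append(ps_id)
            clusters[f"tc{c}"] = TranscriptCluster(
                f"tc{c}", GenomicInterval.from_1based(chrom, 1, 100_000, "+"), None, tuple(ids)
            )
        ann = ArrayAnnotation(probes, probesets, clusters)
        dist = chromosome_enrichment_test(summaries, ann)  # all on chr1
        assert dist.rows["chr1"].p_value == pytest.approx(p)
        assert dist.rows["chr1"].p_value < 1e-6


class TestPriorComparison:
    def make_summary(self, pid, keys, novel_keys, population="CEU"):
        n = len(keys)
        return ProbesetSummary(
            pid, population,
            n_snps_total=n, count_class=count_class_of(n),
            novelty_class="novel", snp_keys=tuple(keys), novel_snp_keys=tuple(novel_keys),
        )

    def test_single_novel_snp_row_one_novel(self):
        s = self.make_summary("ps1", [("chr1", 50)], [("chr1", 50)])
        table = compare_with_prior([s], {})
        assert table.loc["1", "Novel"] == 1
        assert table.loc["1", "Both"] == 0
        assert table.loc["Total", "Total"] == 1

    def test_known_plus_novel_is_both(self):
        prior = {"ps1": frozenset({("chr1", 50)})}
        s = self.make_summary("ps1", [("chr1", 50), ("chr1", 60)], [("chr1", 60)])
        table = compare_with_prior([s], prior)
        assert table.loc["2", "Both"] == 1

    def test_planted_matrix_recovered(self, small_bundle, small_survey):
        prior = small_bundle.truth.prior
        for pop in small_bundle.panels:
            table = compare_with_prior(small_survey.summaries[pop]["all"], prior)
            expected = small_bundle.truth.tables[pop]["all"]["novelty_matrix"]
            for row in ("1", "2", "3+"):
                for col in ("Novel", "Known", "Both"):
                    assert table.loc[row, col] == expected[row][col]
            assert table.loc["1", "Both"] == 0
            # partition: Novel + Known + Both = Total in every row
            for row in ("1", "2", "3+", "Total"):
                assert (
                    table.loc[row, ["Novel", "Known", "Both"]].sum()
                    == table.loc[row, "Total"]
                )

    def test_prior_catalogue_round_trip(self, small_bundle, tmp_path):
        path = tmp_path / "prior.tsv"
        write_prior_catalogue(small_bundle.truth.prior, path)
        assert read_prior_catalogue(path) == small_bundle.truth.prior


class TestUnion:
    def affected(self, ids, population):
        return [
            ProbesetSummary(i, population, count_class="1", novelty_class="novel")
            for i in ids
        ]

    def test_disjoint_sets_sum(self):
        got = union_across_populations(
            {"CEU": self.affected(["a", "b"], "CEU"), "YRI": self.affected(["c"], "YRI")}
        )
        assert got == 3

    def test_identical_sets_single_count(self):
        got = union_across_populations(
            {"CEU": self.affected(["a", "b"], "CEU"), "YRI": self.affected(["a", "b"], "YRI")}
        )
        assert got == 2

    def test_random_overlap_matches_set_oracle(self):
        rng = np.random.default_rng(5)
        ids = [f"ps{i}" for i in range(50)]
        a = list(rng.choice(ids, size=20, replace=False))
        b = list(rng.choice(ids, size=25, replace=False))
        got = union_across_populations(
            {"CEU": self.affected(a, "CEU"), "YRI": self.affected(b, "YRI")}
        )
        assert got == len(set(a) | set(b))
        assert max(len(a), len(b)) <= got <= len(a) + len(b)
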