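"""Splicing-impact audit and the with/without re-test."""

import numpy as np
import pandas as pd
import pytest

from probevar.array_model import GenomicInterval, Probeset
from probevar.catalogue import ProbesetSummary, count_class_of
from probevar.probe_map import ProbeHit
from probevar.splicing_impact import (
    AuditResult,
    ExpressionMatrix,
    NotMeasurableError,
    audit_probesets,
    probeset_expression,
    reassess_with_without,
    two_group_test,
)


def make_expr(values, probe_ids, populations):
    samples = list(populations)
    return ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=samples), populations)


def four_probe_set(ps_id="ps0"):
    return Probeset(
        ps_id, GenomicInterval.from_1based("chr1", 100, 199, "+"), "tc0", "core",
        tuple(f"{ps_id}_p{k}" for k in range(4)),
    )


class TestProbesetExpression:
    def test_constant_matrix_gives_constant(self):
        ps = four_probe_set()
        expr = make_expr(np.full((4, 3), 7.0), list(ps.probe_ids), {"a": "X", "b": "X", "c": "Y"})
        out = probeset_expression(expr, ps)
        assert (out == 7.0).all()

    def test_exclusion_equals_bruteforce_row_mean(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(4, 20))
        ps = four_probe_set()
        populations = {f"s{i}": ("X" if i < 10 else "Y") for i in range(20)}
        expr = make_expr(values, list(ps.probe_ids), populations)
        out = probeset_expression(expr, ps, excluded_probes={"ps0_p1"})
        expected = values[[0, 2, 3]].mean(axis=0)
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_median_summarizer(self):
        ps = four_probe_set()
        values = np.array([[1.0], [2.0], [3.0], [10.0]])
        expr = make_expr(values, list(ps.probe_ids), {"a": "X"})
        assert probeset_expression(expr, ps, summarizer="median").iloc[0] == 2.5

    def test_all_excluded_not_measurable(self):
        ps = four_probe_set()
        expr = make_expr(np.zeros((4, 2)), list(ps.probe_ids), {"a": "X", "b": "Y"})
        with pytest.raises(NotMeasurableError):
            probeset_expression(expr, ps, excluded_probes=set(ps.probe_ids))


class TestTwoGroupTest:
    def test_identical_groups_stat_zero(self):
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           index=[f"s{i}" for i in range(6)])
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        stat, p = two_group_test(values, labels)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t(self):
        """{1,2,3} vs {4,5,6}: t = -3/sqrt(2/3), df = 4."""
        from scipy.stats import t as t_dist

        values = pd.Series([1, 2, 3, 4, 5, 6.0], index=[f"s{i}" for i in range(6)])
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        stat, p = two_group_test(values, labels)
        expected_t = -3.0 / np.sqrt(2 / 3)
        assert stat == pytest.approx(expected_t)
        assert p == pytest.approx(2 * t_dist.sf(abs(expected_t), df=4))

    def test_group_size_swap_leaves_abs_stat(self):
        values = pd.Series([1, 2, 3, 4, 5, 6.0], index=[f"s{i}" for i in range(6)])
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        flipped = {s: ("B" if g == "A" else "A") for s, g in labels.items()}
        assert abs(two_group_test(values, labels)[0]) == pytest.approx(
            abs(two_group_test(values, flipped)[0])
        )

    def test_needs_two_samples_per_group(self):
        values = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            two_group_test(values, {"a": "A", "b": "B", "c": "B"})


class TestReassess:
    def hit_on(self, probe_id, ps_id="ps0"):
        return ProbeHit("chr1", 110, "CEU", probe_id, ps_id, "tc0", 11, 3, True)

    def expr_for(self, ps, n_per_group=10, rng=None):
        rng = rng or np.random.default_rng(0)
        populations = {f"s{i}": ("X" if i < n_per_group else "Y") for i in range(2 * n_per_group)}
        values = rng.normal(8.0, 0.3, size=(4, 2 * n_per_group))
        return make_expr(values, list(ps.probe_ids), populations)

    def test_no_hits_identical_p(self):
        ps = four_probe_set()
        expr = self.expr_for(ps)
        res = reassess_with_without(expr, ps, [])
        assert res.p_without == res.p_with
        assert res.n_probes_excluded == 0

    def test_all_probes_hit_not_measurable(self):
        ps = four_probe_set()
        expr = self.expr_for(ps)
        res = reassess_with_without(expr, ps, [self.hit_on(p) for p in ps.probe_ids])
        assert res.p_without is None
        assert not res.measurable_without

    def test_invariant_to_probe_and_sample_order(self):
        ps = four_probe_set()
        expr = self.expr_for(ps)
        hits = [self.hit_on("ps0_p0")]
        res = reassess_with_without(expr, ps, hits)
        shuffled = ExpressionMatrix(
            expr.values.iloc[::-1, ::-1].copy(), expr.populations
        )
        res2 = reassess_with_without(shuffled, ps, hits)
        assert res2.p_with == pytest.approx(res.p_with)
        assert res2.p_without == pytest.approx(res.p_without)

    def test_planted_artifact_pattern(self):
        """An allele-dose artifact on one probe with a population-specific
        variant drives p_with below 0.05 and leaves p_without null in most
        seeded replicates."""
        from probevar.synthetic import SyntheticConfig, artifact_retest_replicates

        out = artifact_retest_replicates(SyntheticConfig(seed=21), n_replicates=40)
        assert out["success_fraction"] >= 0.8


class TestAudit:
    def summaries_for(self, population, affected):
        """affected: {probeset_id: (n_novel, n_rare, novel_keys, novel_probes)}"""
        out = []
        for pid, (n_novel, n_rare, keys, probes) in affected.items():
            out.append(
                ProbesetSummary(
                    pid, population, n_novel=n_novel, n_known=0,
                    n_rare_among_novel=n_rare,
                    count_class=count_class_of(n_novel), novelty_class="novel",
                    novel_snp_keys=tuple(keys), novel_probe_ids=tuple(probes),
                    snp_keys=tuple(keys),
                )
            )
        return out

    def test_audit_counts_and_fractions(self, small_bundle, small_survey):
        """Audit on planted targets matches the truth table's novel counts."""
        ann = small_survey.annotation
        truth = small_bundle.truth
        result = audit_probesets(
            truth.targets,
            {p: small_survey.summaries[p]["all"] for p in small_survey.summaries},
            ann,
        )
        assert not result.unknown_ids
        for rec in result.records:
            detail = truth.tables[rec.population]["all"]["detail"][rec.probeset_id]
            assert rec.n_novel_snps == detail["n_novel"]
            assert rec.n_rare_among_novel == detail["n_rare_among_novel"]
            assert rec.n_rare_among_novel <= rec.n_novel_snps
            assert rec.still_measurable == (rec.n_probes_affected < rec.n_probes_total)

    def test_planted_fraction_example(self):
        """50 targets, 8 affected, 6 with one novel SNP -> 16% and 75%."""
        from probevar.array_model import ArrayAnnotation, Probeset, TranscriptCluster

        probesets = {}
        for i in range(50):
            pid = f"t{i}"
            iv = GenomicInterval.from_1based("chr1", 1 + 200 * i, 100 + 200 * i, "+")
            probesets[pid] = Probeset(pid, iv, "tc0", "core", (f"{pid}_p0",))
        clusters = {"tc0": TranscriptCluster(
            "tc0", GenomicInterval.from_1based("chr1", 1, 100_000, "+"), None,
            tuple(probesets))}
        ann = ArrayAnnotation({}, probesets, clusters)
        affected = {}
        for i in range(8):
            n = 1 if i < 6 else 2
            keys = [("chr1", 10 + 200 * i + j) for j in range(n)]
            affected[f"t{i}"] = (n, 0, keys, [f"t{i}_p0"])
        result = audit_probesets(
            [f"t{i}" for i in range(50)],
            {"CEU": self.summaries_for("CEU", affected)},
            ann,
        )
        assert result.n_affected_targets == 8
        assert result.frac_targets_affected == pytest.approx(0.16)
        assert result.frac_affected_one_novel == pytest.approx(0.75)

    def test_unknown_target_listed_not_fatal(self, small_survey):
        result = audit_probesets(
            ["does-not-exist"],
            {p: small_survey.summaries[p]["all"] for p in small_survey.summaries},
            small_survey.annotation,
        )
        assert result.unknown_ids == ["does-not-exist"]
        assert result.records == []


def test_expression_matrix_round_trip(small_bundle, tmp_path):
    expr = small_bundle.expression
    m, p = tmp_path / "expr.tsv", tmp_path / "pops.tsv"
    expr.to_tsv(m, p)
    back = ExpressionMatrix.from_tsv(m, p)
    assert back.populations == expr.populations
    np.testing.assert_allclose(back.values.to_numpy(), expr.values.to_numpy(), atol=1e-5)
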