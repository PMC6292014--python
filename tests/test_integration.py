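import numpy as np
import pytest

from omicsfunnel.integration import (
    funnel_counts,
    integrate,
    intersect_case_variants,
    quality_stratify,
    verify_in_cohorts,
)
from omicsfunnel.io_core import (
    CohortError,
    DERecord,
    GenotypeCall,
    PathwaySet,
    SampleInfo,
    VariantKey,
    VariantRecord,
)


def variant(pos, sample="S1", dosage=1, gene=None, rsid=None, maf=None, gq=99, dp=40):
    return VariantRecord(
        key=VariantKey("1", pos, "A", "G"),
        rsid=rsid,
        gene=gene,
        maf=maf,
        calls={sample: GenotypeCall.from_dosage(sample, dosage, gq, dp)},
    )


def de_record(gene):
    return DERecord(gene, 2.0, 1.0, 1.0, 3.0, 0.001, 0.01, "OK")


class TestIntersect:
    def test_example_lists(self):
        lists = [
            [variant(1), variant(2), variant(3)],
            [variant(2, "S2"), variant(3, "S2"), variant(4, "S2")],
            [variant(2, "S3"), variant(3, "S3")],
        ]
        shared = intersect_case_variants(lists)
        assert [r.key.pos for r in shared] == [2, 3]
        assert set(shared[0].calls) == {"S1", "S2", "S3"}  # genotypes retained

    def test_idempotent_on_identical_lists(self):
        base = [variant(i) for i in range(1, 6)]
        shared = intersect_case_variants([base] * 6)
        assert [r.key for r in shared] == [r.key for r in base]

    def test_requires_two_lists(self):
        with pytest.raises(ValueError):
            intersect_case_variants([[variant(1)]])

    def test_matches_bruteforce_membership_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            lists = [
                [variant(int(p) + 1, f"S{i}") for p in rng.choice(50, size=20, replace=False)]
                for i in range(4)
            ]
            shared = {r.key for r in intersect_case_variants(lists)}
            key_lists = [{r.key for r in lst} for lst in lists]
            expected = {k for k in key_lists[0] if all(k in ks for ks in key_lists)}
            assert shared == expected
            for ks in key_lists:
                assert shared <= ks  # subset of every input


class TestQualityStratify:
    def test_all_high_quality_passes(self):
        passing, failing = quality_stratify([variant(1, gq=99, dp=40)])
        assert len(passing) == 1 and not failing

    def test_one_low_gq_call_fails_variant(self):
        record = variant(1, gq=5, dp=40)
        passing, failing = quality_stratify([record], min_gq=20)
        assert failing == [record]

    def test_zero_thresholds_pass_everything(self):
        records = [variant(1, gq=0, dp=0), variant(2, gq=99, dp=1)]
        passing, failing = quality_stratify(records, min_gq=0, min_dp=0)
        assert len(passing) == 2 and not failing

    def test_missing_values_policy(self):
        record = variant(1, gq=None, dp=None)
        assert quality_stratify([record])[0] == [record]
        assert quality_stratify([record], missing_passes=False)[1] == [record]


class TestIntegrate:
    PATHWAYS = [
        PathwaySet("P1", frozenset({"ECHS1", "DBT"})),
        PathwaySet("P2", frozenset({"ECHS1"})),
        PathwaySet("P3", frozenset({"ECHS1", "AUH"})),
    ]

    def test_candidate_collects_all_memberships(self):
        record = variant(1, gene="ECHS1", maf=0.005)
        (candidate,) = integrate([record], {"ECHS1": de_record("ECHS1")}, self.PATHWAYS)
        assert candidate.pathways == frozenset({"P1", "P2", "P3"})
        assert candidate.rare is True

    def test_gene_not_in_any_significant_pathway(self):
        record = variant(1, gene="BCAT2")
        assert integrate([record], {"BCAT2": de_record("BCAT2")}, self.PATHWAYS) == []

    def test_gene_not_retained_by_de_filter(self):
        record = variant(1, gene="ECHS1")
        assert integrate([record], {}, self.PATHWAYS) == []

    def test_rare_flag_undefined_without_maf(self):
        record = variant(1, gene="ECHS1", maf=None)
        (candidate,) = integrate([record], {"ECHS1": de_record("ECHS1")}, self.PATHWAYS)
        assert candidate.rare is None


def verification_cohort(case_dosages, control_dosages):
    samples, calls = [], {}
    for i, dosage in enumerate(case_dosages):
        sid = f"PED_{i}"
        samples.append(SampleInfo(sid, "case", "PED1", "verification"))
        calls[sid] = GenotypeCall.from_dosage(sid, dosage)
    for i, dosage in enumerate(control_dosages):
        sid = f"CTL_{i}"
        samples.append(SampleInfo(sid, "unknown" if i % 2 else "control", "HAPMAP", "verification"))
        calls[sid] = GenotypeCall.from_dosage(sid, dosage)
    record = VariantRecord(key=VariantKey("1", 1, "A", "G"), calls=calls)
    return record, samples


class TestVerifyInCohorts:
    def test_pedigree_only_homozygotes_are_putative_mutation(self):
        record, samples = verification_cohort([2, 2, 1, 0, 0], [0] * 10)
        status = verify_in_cohorts(record, "hom_alt", samples)
        assert status.verdict == "possible_putative_mutation"
        assert status.supporting_cohorts == ["PED1"]
        assert status.control_carriers == 0

    def test_present_in_controls_is_effect_modifier(self):
        record, samples = verification_cohort([1, 0, 0], [2, 1, 0, 0])
        status = verify_in_cohorts(record, "carrier", samples)
        assert status.verdict == "potential_putative_effect_modifier"
        assert status.control_carriers == 2

    def test_absent_everywhere_unsupported(self):
        record, samples = verification_cohort([0, 0], [0, 0])
        assert verify_in_cohorts(record, "carrier", samples).verdict == "unsupported"

    def test_empty_verification_set_rejected(self):
        record, _ = verification_cohort([1], [0])
        with pytest.raises(CohortError):
            verify_in_cohorts(record, "carrier", [])

    def test_mutation_verdict_never_with_control_carriers(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            record, samples = verification_cohort(
                list(rng.integers(0, 3, size=5)), list(rng.integers(0, 3, size=8))
            )
            status = verify_in_cohorts(record, "carrier", samples)
            if status.verdict == "possible_putative_mutation":
                assert status.control_carriers == 0 and status.supporting_cohorts


class TestFunnelCounts:
    def test_constructed_funnel(self):
        case_lists = [
            [variant(1, "S1", gene="ECHS1", rsid="rs1", maf=0.005), variant(2, "S1"), variant(3, "S1")],
            [variant(1, "S2", gene="ECHS1", rsid="rs1", maf=0.005), variant(2, "S2"), variant(4, "S2")],
        ]
        shared = intersect_case_variants(case_lists)
        retained = {"ECHS1": de_record("ECHS1")}
        candidates = integrate(shared, retained, [PathwaySet("P1", frozenset({"ECHS1"}))])
        counts = dict(funnel_counts(case_lists, shared, retained, candidates))
        assert counts == {
            "total": 4,
            "intersection": 2,
            "dbsnp_known": 1,
            "in_de_genes": 1,
            "rare": 1,
            "in_pathways": 1,
        }

    def test_empty_intersection_propagates_zero(self):
        case_lists = [[variant(1)], [variant(2, "S2")]]
        shared = intersect_case_variants(case_lists)
        counts = dict(funnel_counts(case_lists, shared, {}, []))
        assert counts["intersection"] == 0
        assert counts["dbsnp_known"] == counts["in_de_genes"] == counts["rare"] == 0
        assert counts["in_pathways"] == 0

    def test_monotone_along_parent_chains(self, default_cohort, default_bundle):
        counts = dict(default_bundle.funnel)
        assert counts["total"] >= counts["intersection"] >= counts["dbsnp_known"]
        assert counts["intersection"] >= counts["in_de_genes"]
        assert counts["in_de_genes"] >= counts["rare"]
        assert counts["in_de_genes"] >= counts["in_pathways"]
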