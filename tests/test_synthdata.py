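import hashlib
import os

import numpy as np
import pytest
from scipy.special import expit, logit

from omicsfunnel.de_pathway import filter_de
from omicsfunnel.synthdata import (
    SimulationConfig,
    assign_phenotypes,
    disease_probability,
    emit_cohort,
    hap_freqs_for_target,
    pure_interaction_offsets,
    simulate_case_control,
    simulate_de_table,
    simulate_genotypes,
    simulate_ld_pair,
    simulate_pathways,
)


def tree_digest(directory):
    h = hashlib.sha256()
    for root, _dirs, files in sorted(os.walk(directory)):
        for name in sorted(files):
            h.update(name.encode())
            h.update(open(os.path.join(root, name), "rb").read())
    return h.hexdigest()


class TestGenotypeSimulation:
    def test_hardy_weinberg_proportions(self):
        config = SimulationConfig(seed=3)
        genotypes = simulate_genotypes(config, n=10000)
        j = config.role_indices("mutation")[0]
        freq = config.variants[j].allele_freq
        expected = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2])
        observed = np.bincount(genotypes[:, j], minlength=3) / 10000
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert np.all(np.abs(observed - expected) <= 3 * se)

    def test_same_seed_identical_matrices(self):
        config = SimulationConfig(seed=9)
        a = simulate_genotypes(config, n=500)
        b = simulate_genotypes(config, n=500)
        assert np.array_equal(a, b)

    def test_perfect_ld_has_no_recombinant_haplotypes(self):
        _ga, _gb, freqs, counts = simulate_ld_pair(
            500, 0.3, 0.2, 1.0, np.random.default_rng(1)
        )
        assert freqs[2] == pytest.approx(0.0)  # aB class absent by construction
        assert counts[2] == 0

    def test_infeasible_dprime_reports_bound(self):
        with pytest.raises(ValueError, match="infeasible"):
            hap_freqs_for_target(0.3, 0.2, 1.5)
        with pytest.raises(ValueError):
            hap_freqs_for_target(0.0, 0.2, 0.5)


class TestPenetranceModel:
    def test_modifier_marginals_exactly_balanced(self):
        config = SimulationConfig()
        ja, jb = config.role_indices("modifier_pair_member")[:2]
        fa = 1 - (1 - config.variants[ja].allele_freq) ** 2
        fb = 1 - (1 - config.variants[jb].allele_freq) ** 2
        off_a, off_b = pure_interaction_offsets(
            config.penetrance, config.interaction_effect, fa, fb
        )
        b0 = float(logit(config.penetrance))
        bi = np.log(config.interaction_effect)
        # population risk conditional on carrying A equals risk without A
        risk_with_a = fb * expit(b0 + off_a + off_b + bi) + (1 - fb) * expit(b0 + off_a)
        risk_without_a = fb * expit(b0 + off_b) + (1 - fb) * expit(b0)
        assert risk_with_a == pytest.approx(risk_without_a, abs=1e-12)

    def test_null_effects_give_baseline_penetrance(self):
        config = SimulationConfig(seed=2, mutation_effect=1.0, interaction_effect=1.0)
        genotypes = simulate_genotypes(config, n=20000)
        p = disease_probability(genotypes, config)
        assert np.all(p == pytest.approx(config.penetrance))
        labels = assign_phenotypes(genotypes, config, np.random.default_rng(2))
        assert labels.mean() == pytest.approx(config.penetrance, abs=0.01)

    def test_mutation_genotype_raises_risk(self):
        config = SimulationConfig()
        genotypes = simulate_genotypes(config, n=5000)
        p = disease_probability(genotypes, config)
        j = config.role_indices("mutation")[0]
        has = genotypes[:, j] == 2
        assert p[has].mean() > 3 * p[~has].mean()

    def test_ascertainment_reaches_exact_counts(self):
        config = SimulationConfig(seed=4, n_cases=100, n_controls=80)
        genotypes, phenotypes = simulate_case_control(config)
        assert genotypes.shape[0] == 180
        assert (phenotypes == "case").sum() == 100


class TestDeTable:
    def test_planted_genes_dominate_significant_set(self):
        config = SimulationConfig(seed=5)
        records, planted = simulate_de_table(config)
        retained = set(filter_de(records))
        assert set(planted) <= retained
        assert len(retained - set(planted)) <= 5

    def test_null_fold_change_controls_fdr(self):
        false_calls = 0
        total_calls = 0
        for seed in range(8):
            config = SimulationConfig(seed=seed, fold_change=1.0)
            records, _ = simulate_de_table(config)
            called = [r for r in records if r.q < 0.05 and r.status == "OK"]
            false_calls += len(called)
            total_calls += len(records)
        assert false_calls / max(total_calls, 1) < 0.01  # nothing planted, few calls

    def test_lowdata_rows_flagged(self):
        config = SimulationConfig(seed=6)
        records, _ = simulate_de_table(config)
        statuses = {r.gene: r.status for r in records}
        for gene in config.lowdata_genes():
            assert statuses[gene] == "LOWDATA"


class TestPathways:
    def test_hub_membership_by_construction(self):
        config = SimulationConfig(seed=7)
        sets = simulate_pathways(config)
        containing = [s.name for s in sets if config.hub_gene in s.genes]
        assert len(containing) == config.hub_membership
        assert len(sets) == config.n_sets
        for s in sets:
            assert len(s.genes) == config.set_size

    def test_variant_genes_covered_by_hub_sets(self):
        config = SimulationConfig(seed=8)
        sets = simulate_pathways(config)
        union = set().union(*(s.genes for s in sets[: config.hub_membership]))
        planted = set(config.planted_de_genes())
        for spec in config.variants:
            if spec.gene in planted:
                assert spec.gene in union


class TestEmitCohort:
    def test_two_seeds_differ_same_schema(self, tmp_path):
        m1, _ = emit_cohort(SimulationConfig(seed=1), tmp_path / "a")
        m2, _ = emit_cohort(SimulationConfig(seed=2), tmp_path / "b")
        assert set(m1) == set(m2)
        assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "b")

    def test_same_seed_byte_identical(self, tmp_path):
        emit_cohort(SimulationConfig(seed=3), tmp_path / "a")
        emit_cohort(SimulationConfig(seed=3), tmp_path / "b")
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_emitted_files_parse_without_warnings(self, default_cohort):
        import warnings

        from omicsfunnel.io_core import read_de_table, read_gmt, read_sample_sheet, read_vcf

        _config, manifest, _truth = default_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            samples = read_sample_sheet(manifest["sample_sheet"])
            read_de_table(manifest["de_table"])
            read_gmt(manifest["gmt"])
            read_vcf(manifest["verification_vcf"], samples)
            for path in manifest["discovery_vcfs"]:
                read_vcf(path, samples)

    def test_truth_funnel_matches_pipeline_recount(self, default_cohort, default_bundle):
        _config, _manifest, truth = default_cohort
        assert dict(default_bundle.funnel) == truth.funnel
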