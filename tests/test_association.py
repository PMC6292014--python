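import numpy as np
import pytest
from scipy import stats as sps

from omicsfunnel.association import (
    ContingencyTable,
    DegenerateTableError,
    bh_adjust,
    build_joint_table,
    build_table,
    chi2_gof,
    chi2_independence,
    classify_variants,
)
from omicsfunnel.io_core import CohortError
from omicsfunnel.synthdata import SimulationConfig, simulate_case_control


def table(counts, construction="carrier"):
    counts = np.asarray(counts)
    rows = tuple(f"r{i}" for i in range(counts.shape[0]))
    cols = tuple(f"c{i}" for i in range(counts.shape[1]))
    return ContingencyTable(rows, cols, counts, construction)


def random_table(rng, max_shape=(5, 4)):
    r = int(rng.integers(2, max_shape[0] + 1))
    c = int(rng.integers(2, max_shape[1] + 1))
    while True:
        counts = rng.integers(0, 40, size=(r, c))
        if counts.sum() and (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
            return counts


class TestChi2Independence:
    def test_proportional_table_is_exactly_zero(self):
        result = chi2_independence(table([[10, 10], [10, 10]]))
        assert result.statistic == 0.0 and result.p == 1.0
        assert result.test == "pearson_chi2_yates"  # correction clamped at |O-E|=0

    def test_hand_values_plain_and_yates(self):
        plain = chi2_independence(table([[5, 0], [0, 5]]), yates="off")
        assert plain.statistic == pytest.approx(10.0)  # N(ad-bc)^2 / (r1 r2 c1 c2)
        corrected = chi2_independence(table([[5, 0], [0, 5]]), yates="on")
        assert corrected.statistic == pytest.approx(6.4)  # 4 * (2.5-0.5)^2 / 2.5

    @pytest.mark.parametrize("correction", [True, False])
    def test_matches_reference_on_random_tables(self, correction):
        rng = np.random.default_rng(2024 + correction)
        for _ in range(300):
            counts = random_table(rng)
            yates = "auto" if correction else "off"
            mine = chi2_independence(table(counts), yates=yates)
            use_corr = correction and counts.shape == (2, 2)
            ref_stat, ref_p, ref_df, _ = sps.chi2_contingency(counts, correction=use_corr)
            assert mine.statistic == pytest.approx(ref_stat, abs=1e-10)
            assert mine.p == pytest.approx(ref_p, abs=1e-10)
            assert mine.df == ref_df

    def test_zero_margin_names_it(self):
        with pytest.raises(DegenerateTableError, match="r1"):
            chi2_independence(table([[3, 4], [0, 0]]))

    def test_expected_warning_flag(self):
        assert chi2_independence(table([[2, 1], [1, 2]])).expected_warning
        assert not chi2_independence(table([[50, 50], [50, 50]])).expected_warning


class TestChi2Gof:
    def test_uniform_fit(self):
        result = chi2_gof([25, 25, 25, 25], [0.25] * 4)
        assert result.statistic == 0.0 and result.p == 1.0 and result.df == 3

    def test_direct_formula(self):
        result = chi2_gof([30, 20], [0.5, 0.5])
        assert result.statistic == pytest.approx(2.0) and result.df == 1
        ref = sps.chisquare([30, 20], [25, 25])
        assert result.p == pytest.approx(ref.pvalue)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateTableError):
            chi2_gof([10], [1.0])
        with pytest.raises(ValueError):
            chi2_gof([10, 5], [1.0, 0.0])
        with pytest.raises(ValueError):
            chi2_gof([10, 5], [0.7, 0.7])


class TestBuildTable:
    GENOTYPES = [2, 2, 2, 1]
    PHENOTYPES = ["case", "case", "case", "control"]

    def test_genotype_mode_tabulation(self):
        t = build_table(self.GENOTYPES, self.PHENOTYPES, "genotype")
        assert t.row_labels == ("het", "hom_alt")
        assert t.counts.tolist() == [[0, 1], [3, 0]]

    def test_stratum_mode(self):
        t = build_table(self.GENOTYPES, self.PHENOTYPES, "stratum", focus_genotype="hom_alt")
        assert t.counts.tolist() == [[3, 0], [0, 1]]

    def test_carrier_mode_and_missing_excluded(self):
        t = build_table([2, 1, 0, None, 0], ["case", "case", "control", "case", "control"], "carrier")
        assert t.counts.tolist() == [[2, 0], [0, 2]]

    def test_margins_match_tally_oracle(self):
        rng = np.random.default_rng(7)
        genotypes = rng.integers(0, 3, size=200)
        phenotypes = rng.choice(["case", "control"], size=200)
        t = build_table(genotypes, phenotypes, "genotype")
        for i, label in enumerate(t.row_labels):
            dosage = ("hom_ref", "het", "hom_alt").index(label)
            assert t.counts[i].sum() == (genotypes == dosage).sum()
        assert t.counts.sum(axis=0).tolist() == [
            (phenotypes == "case").sum(),
            (phenotypes == "control").sum(),
        ]

    def test_all_missing_errors(self):
        with pytest.raises(DegenerateTableError):
            build_table([None, None], ["case", "control"], "carrier")


class TestBuildJointTable:
    def test_identical_vectors_give_diagonal_dependence(self):
        g = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]
        t = build_joint_table(g, g)
        assert np.all(t.counts[~np.eye(3, dtype=bool).reshape(t.counts.shape)] == 0)
        assert chi2_independence(t, yates="off").statistic > 0

    def test_joint_disease_df_after_dropping_empty(self):
        ga = [0, 0, 1, 1, 0, 0, 1, 1]
        gb = [0, 1, 0, 1, 0, 1, 0, 1]
        ph = ["case", "case", "case", "case", "control", "control", "control", "control"]
        t = build_joint_table(ga, gb, ph)
        assert t.counts.shape == (4, 2)
        assert chi2_independence(t, yates="off").df == 3

    def test_pairwise_complete(self):
        t = build_joint_table([0, 1, None], [0, None, 1])
        assert t.counts.sum() == 1
        with pytest.raises(DegenerateTableError):
            build_joint_table([None, 0], [1, None])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(99)
        pvalues = []
        for _ in range(400):
            ga = rng.binomial(2, 0.4, size=300)
            gb = rng.binomial(2, 0.4, size=300)
            pvalues.append(chi2_independence(build_joint_table(ga, gb), yates="off").p)
        assert sps.kstest(pvalues, "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_properties_and_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(50)
        adjusted = bh_adjust(p)
        assert np.all(adjusted >= p) and np.all(adjusted <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
        reference = multipletests(p, method="fdr_bh")[1]
        assert adjusted == pytest.approx(reference)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def classified_cohort():
    config = SimulationConfig(seed=13)
    genotypes, phenotypes = simulate_case_control(config)
    vectors = {v.name: genotypes[:, j] for j, v in enumerate(config.variants)}
    return config, classify_variants(vectors, phenotypes)


class TestClassifyVariants:

    def test_verdicts_mutually_exclusive_and_consistent(self, classified_cohort):
        _config, results = classified_cohort
        for r in results:
            assert r.verdict in ("putative_mutation", "putative_effect_modifier", "unclassified")
            if r.verdict == "putative_mutation":
                assert r.direct_test.p < r.alpha
            elif r.verdict == "putative_effect_modifier":
                assert r.direct_test is None or r.direct_test.p >= r.alpha
                assert r.interaction_test.p < r.alpha
                assert r.joint_disease_test.p < r.alpha
                assert r.best_partner is not None
            else:
                assert r.best_partner is None

    def test_direct_battery_reported(self, classified_cohort):
        _config, results = classified_cohort
        for r in results:
            assert "genotype" in r.direct_tests or r.direct_test is None
            assert r.direct_p_bh is None or r.direct_p_bh >= r.direct_test.p

    def test_planted_recovery_over_seeds(self):
        hits = {"mutation": 0, "moda": 0, "modb": 0}
        n_seeds = 10
        for seed in range(100, 100 + n_seeds):
            config = SimulationConfig(seed=seed)
            genotypes, phenotypes = simulate_case_control(config)
            vectors = {v.name: genotypes[:, j] for j, v in enumerate(config.variants)}
            verdicts = {r.variant: r for r in classify_variants(vectors, phenotypes)}
            hits["mutation"] += verdicts["VAR_MUT"].verdict == "putative_mutation"
            moda, modb = verdicts["VAR_MODA"], verdicts["VAR_MODB"]
            hits["moda"] += moda.verdict == "putative_effect_modifier"
            hits["modb"] += modb.verdict == "putative_effect_modifier"
            # restricted to the pair, each modifier names the other
            pair = classify_variants(
                vectors, phenotypes, partner_set=["VAR_MODA", "VAR_MODB"]
            )
            pair = {r.variant: r for r in pair}
            if (
                pair["VAR_MODA"].verdict
                == pair["VAR_MODB"].verdict
                == "putative_effect_modifier"
            ):
                assert pair["VAR_MODA"].best_partner == "VAR_MODB"
                assert pair["VAR_MODB"].best_partner == "VAR_MODA"
        assert hits["mutation"] == n_seeds
        assert hits["moda"] >= 7 and hits["modb"] >= 7

    def test_requires_both_phenotype_classes(self):
        with pytest.raises(CohortError):
            classify_variants({"v": [0, 1, 2]}, ["case", "case", "case"])
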