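"""Cohort analytics: disease-volume classification, tumor/plasma concordance,
contingency construction, and the statistical tests against independent oracles."""

import math

import numpy as np
import pytest

from conftest import reads_frame  # noqa: F401  (shared pytest plugins)
from oracles import fisher_two_sided, pooled_t_p, rank_sum_exact_p
from panelkit.cohort import (
    ContingencyTable2x2,
    build_contingency,
    classify_concordance,
    classify_volume,
    concordance_summary,
    fisher_exact_2x2,
    gene_frequencies,
    pearson_corr,
    two_sample_t,
    wilcoxon_rank_sum,
)
from panelkit.panel import PatientRecord, VariantRecord
from panelkit.simulate import make_association_cohort, make_matched_cohort


class TestClassifyVolume:
    @pytest.mark.parametrize(
        "bone,extra,visceral,expected",
        [
            (5, True, False, "high"),   # >=4 bone mets, one outside pelvis/spine
            (2, False, True, "high"),   # visceral alone suffices
            (3, False, False, "low"),   # criteria not met
            (4, False, False, "low"),   # 4 bone mets but none outside pelvis/spine
        ],
    )
    def test_definition(self, bone, extra, visceral, expected):
        assert classify_volume(bone, extra, visceral) == expected

    def test_missing_inputs_missing_classification(self):
        assert classify_volume(None, True, False) is None

    def test_monotone_in_visceral(self):
        for bone in range(0, 8):
            for extra in (False, True):
                without = classify_volume(bone, extra, False)
                with_v = classify_volume(bone, extra, True)
                assert not (without == "high" and with_v == "low")


def _variant(pos, chrom="chr1", gene="TP53"):
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", gene=gene, af=0.05)


class TestClassifyConcordance:
    def patient(self, tumor, plasma, cfdna=12.0):
        return PatientRecord(patient_id="P1", cfdna_ng_ml=cfdna,
                             tumor_variants=tumor, plasma_variants=plasma)

    def test_shared_panel_variant_is_concordant(self, panel273, loci273):
        locus = loci273["TP53_001"]
        v = VariantRecord(chrom=locus.chrom, pos=locus.pos, ref=locus.ref,
                          alt="ACGT"[("ACGT".index(locus.ref) + 1) % 4], gene="TP53")
        other = _variant(pos=999_999_999, gene="BRCA2")
        rec = classify_concordance(self.patient([v], [v, other]), panel273)
        assert rec.category == "concordant"

    def test_tumor_variant_outside_panel_is_no_target(self, panel273):
        rec = classify_concordance(self.patient([_variant(7)], []), panel273)
        assert rec.category == "no_target_mutation"

    def test_panel_variant_missing_from_plasma_is_discordant(self, panel273, loci273):
        locus = loci273["SPOP_001"]
        v = VariantRecord(chrom=locus.chrom, pos=locus.pos, ref=locus.ref,
                          alt="ACGT"[("ACGT".index(locus.ref) + 1) % 4], gene="SPOP")
        rec = classify_concordance(self.patient([v], []), panel273)
        assert rec.category == "discordant"

    def test_low_cfdna_excluded(self, panel273):
        rec = classify_concordance(self.patient([], [], cfdna=1.5), panel273)
        assert rec.category == "excluded_low_cfdna"

    def test_unmatched_patient_rejected(self, panel273):
        p = PatientRecord(patient_id="P1", plasma_variants=[])
        with pytest.raises(ValueError, match="matched"):
            classify_concordance(p, panel273)


class TestConcordanceSummary:
    def test_replica_cohort_reproduces_published_counts(self, panel273):
        patients = make_matched_cohort(panel273)
        records = [classify_concordance(p, panel273) for p in patients]
        strata = {p.patient_id: p.hormonal_status for p in patients}
        table, rate = concordance_summary(records, strata)
        assert table.loc["mCRPC", ["no_target_mutation", "concordant", "discordant"]].tolist() == [5, 17, 0]
        assert table.loc["mCSPC", ["no_target_mutation", "concordant", "discordant"]].tolist() == [9, 4, 7]
        assert rate == pytest.approx(21 / 28)

    def test_categories_partition_cohort(self, panel273):
        patients = make_matched_cohort(panel273)
        records = [classify_concordance(p, panel273) for p in patients]
        table, _ = concordance_summary(records)
        assert int(table.to_numpy().sum()) == len(patients) == 42

    def test_all_concordant(self):
        from panelkit.cohort import ConcordanceRecord

        records = [ConcordanceRecord(f"P{i}", "concordant") for i in range(5)]
        _, rate = concordance_summary(records)
        assert rate == 1.0

    def test_rate_undefined_without_informative_patients(self):
        from panelkit.cohort import ConcordanceRecord

        records = [ConcordanceRecord("P1", "no_target_mutation")]
        _, rate = concordance_summary(records)
        assert rate is None

    def test_empty_input(self):
        table, rate = concordance_summary([])
        assert rate is None and table.empty


class TestBuildContingency:
    def _cohort(self, rows):
        """rows: list of (psa, positive) pairs."""
        v = _variant(1_000_050)
        return [
            PatientRecord(patient_id=f"P{i}", psa_ng_ml=psa,
                          plasma_variants=[v] if pos else [])
            for i, (psa, pos) in enumerate(rows)
        ]

    def test_psa_grouping_reproduces_published_row(self):
        rows = [(1.0, True)] * 3 + [(1.0, False)] * 5 + [(50.0, True)] * 40 + [(50.0, False)] * 10
        table = build_contingency(self._cohort(rows), "psa_cutoff")
        assert table.counts == [[3, 5], [40, 10]]
        assert table.total == 58

    def test_boundary_psa_goes_to_high(self):
        rows = [(4.0, True), (3.999, False)]
        table = build_contingency(self._cohort(rows), "psa_cutoff")
        assert table.counts == [[0, 1], [1, 0]]

    def test_missing_grouping_variable_excluded(self):
        patients = self._cohort([(1.0, True), (50.0, False)])
        patients.append(PatientRecord(patient_id="PX", plasma_variants=[]))
        table = build_contingency(patients, "psa_cutoff")
        assert table.total == 2

    def test_empty_level_is_error(self):
        with pytest.raises(ValueError, match="no patients"):
            build_contingency(self._cohort([(50.0, True)] * 4), "psa_cutoff")

    def test_all_negative_column(self):
        rows = [(1.0, False)] * 3 + [(50.0, False)] * 3
        table = build_contingency(self._cohort(rows), "psa_cutoff")
        assert table.counts == [[0, 3], [0, 3]]


class TestFisherExact:
    def test_degenerate_column(self):
        assert fisher_exact_2x2([[0, 5], [0, 10]]) == pytest.approx(1.0)

    def test_row_and_column_swap_invariance(self):
        p = fisher_exact_2x2([[3, 5], [40, 10]])
        assert fisher_exact_2x2([[40, 10], [3, 5]]) == pytest.approx(p)
        assert fisher_exact_2x2([[5, 3], [10, 40]]) == pytest.approx(p)

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
            if a + b + c + d == 0:
                continue
            table = [[a, b], [c, d]]
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_two_sided(table), rel=1e-7
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p, n = pearson_corr(x, x)
        assert r == pytest.approx(1.0)
        r, _, _ = pearson_corr(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, None, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, None, 10.0]
        r, p, n = pearson_corr(x, y)
        assert n == 3
        assert r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_parameter_recovery_at_cohort_scale(self):
        """Mean sample r over seeded bivariate draws (true rho 0.33, n 62)
        stays within 0.05 of the generating correlation."""
        rho, n, reps = 0.33, 62, 500
        rng = np.random.default_rng(2024)
        rs = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n)
            rs.append(pearson_corr(list(x), list(y))[0])
        assert abs(np.mean(rs) - rho) < 0.05


class TestRankSum:
    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        p = wilcoxon_rank_sum([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert p == pytest.approx(2 / 252)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = list(np.round(rng.normal(0, 1, 5), 6))
            y = list(np.round(rng.normal(0.8, 1, 4), 6))
            assert wilcoxon_rank_sum(x, y) == pytest.approx(rank_sum_exact_p(x, y), rel=1e-9)

    def test_detects_one_sd_shift_at_cohort_sizes(self):
        rng = np.random.default_rng(5)
        reps = 150
        hits = 0
        for _ in range(reps):
            a = rng.normal(0, 1, 40)
            b = rng.normal(1.0, 1, 26)
            hits += wilcoxon_rank_sum(a, b) < 0.05
        # true power ~0.96; bound leaves ~3 MC sigma of slack at 150 reps
        assert hits / reps >= 0.90


class TestTwoSampleT:
    def test_identical_constant_samples(self):
        assert two_sample_t([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_agrees_with_pooled_t_under_equal_variance(self):
        rng = np.random.default_rng(21)
        a = list(rng.normal(0, 1, 30))
        b = list(rng.normal(0.4, 1, 30))
        welch = two_sample_t(a, b)
        pooled = pooled_t_p(a, b)
        assert welch == pytest.approx(pooled, rel=0.05)

    def test_large_separation(self):
        a = list(np.random.default_rng(1).normal(0, 0.1, 20))
        b = [v + 50 for v in a]
        assert two_sample_t(a, b) < 1e-12


class TestGeneFrequencies:
    def test_fraction_over_positive_patients(self):
        tp53 = _variant(100, gene="TP53")
        spop = _variant(200, gene="SPOP")
        patients = [
            PatientRecord(patient_id=f"P{i}", plasma_variants=[tp53])
            for i in range(30)
        ] + [
            PatientRecord(patient_id=f"Q{i}", plasma_variants=[spop])
            for i in range(18)
        ] + [
            PatientRecord(patient_id=f"N{i}", plasma_variants=[]) for i in range(10)
        ]
        df = gene_frequencies(patients).set_index("gene")
        assert df.loc["TP53", "patients"] == 30
        assert df.loc["TP53", "fraction"] == pytest.approx(30 / 48)

    def test_multi_hit_counted_once_and_flagged(self):
        v1, v2 = _variant(100, gene="TP53"), _variant(105, gene="TP53")
        patients = [PatientRecord(patient_id="P1", plasma_variants=[v1, v2])]
        df = gene_frequencies(patients).set_index("gene")
        assert df.loc["TP53", "patients"] == 1
        assert df.loc["TP53", "multi_hit_patients"] == 1

    def test_empty_cohort(self):
        assert gene_frequencies([]).empty


class TestAssociationRecovery:
    def test_psa_positivity_rejection_rate_matches_exact_power(self):
        """Monte-Carlo rejection rate of Fisher's test on generated cohorts at
        the published effect size matches the exactly-enumerated power."""
        from scipy.stats import binom

        n_low, n_high, p_low, p_high = 8, 50, 0.375, 0.80
        power = 0.0
        for a in range(n_low + 1):
            pa = binom.pmf(a, n_low, p_low)
            for b in range(n_high + 1):
                if fisher_two_sided([[a, n_low - a], [b, n_high - b]]) < 0.05:
                    power += pa * binom.pmf(b, n_high, p_high)

        reps = 200
        hits = 0
        for seed in range(reps):
            cohort = make_association_cohort(seed)
            table = build_contingency(cohort, "psa_cutoff")
            hits += fisher_exact_2x2(table) < 0.05
        rate = hits / reps
        sigma = math.sqrt(power * (1 - power) / reps)
        assert abs(rate - power) < 3 * sigma + 1e-9
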