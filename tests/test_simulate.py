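"""Synthetic-data generator: mass arithmetic, spike-standard truth, molecule and
read simulation moments, coverage profiles, dataset emission and determinism."""

import filecmp
import math

import numpy as np
import pytest

from panelkit.panel import VariantRecord, locus_map
from panelkit.simulate import (
    SPIKE_AR_COPIES,
    SPIKE_MASS_NG,
    HealthyDonorScenario,
    SimulationConfig,
    SpikeStandardScenario,
    WildTypeScenario,
    copy_mixture_factor,
    emit_dataset,
    make_spike_standard,
    mass_to_genome_equivalents,
    parse_scenario,
    read_reads_tsv,
    simulate_coverage_profile,
    simulate_molecules,
    simulate_reads,
    spike_variants,
)


class TestMassToGenomeEquivalents:
    @pytest.mark.parametrize(
        "mass,expected",
        [(0.0, 0), (20.0, 6060), (22.0, 6666)],  # floor(1000 * ng / 3.3)
    )
    def test_hand_arithmetic(self, mass, expected):
        assert mass_to_genome_equivalents(mass, 3.3) == expected

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            mass_to_genome_equivalents(-1.0)


class TestSpikeStandard:
    def test_four_variants_at_target_af(self):
        truth = make_spike_standard(0.005)
        assert len(truth.variants) == 4
        assert all(af == 0.005 for _, af in truth.variants)
        assert {v.protein_change for v, _ in truth.variants} == {
            "p.T878A", "p.K715*", "p.R248W", "p.V274F",
        }
        assert truth.total_mass_ng == SPIKE_MASS_NG

    def test_cell_line_fractions_sum_with_wild_type(self):
        truth = make_spike_standard(0.10)
        assert all(f == pytest.approx(0.10) for f in truth.cell_line_fractions.values())
        assert truth.wild_type_fraction == pytest.approx(0.70)
        assert truth.ar_amplified_line in truth.cell_line_fractions

    def test_unsupported_level_rejected(self):
        with pytest.raises(ValueError):
            make_spike_standard(0.02)

    def test_deterministic(self):
        assert make_spike_standard(0.01, seed=1) == make_spike_standard(0.01, seed=1)

    def test_variants_sit_on_panel_loci(self, panel273, loci273):
        for v in spike_variants(panel273):
            amp = panel273.find_amplicon(v.chrom, v.pos)
            assert amp is not None and amp.gene == v.gene
            assert loci273[amp.id].ref == v.ref


class TestSimulateMolecules:
    def test_molecule_counts_match_binomial_moments(self, panel273):
        config = SimulationConfig(seed=7, mass_ng=22.0)
        mols = simulate_molecules(panel273, (), config)
        per_amp = mols.groupby("amplicon_id", observed=True).size()
        ge, eff = 6666, 0.5
        mean, sd = ge * eff, math.sqrt(ge * eff * (1 - eff))
        assert abs(per_amp.mean() - mean) < 3 * sd / math.sqrt(273)
        assert np.all(np.abs(per_amp - mean) < 5 * sd)

    def test_zero_af_yields_no_alternate_molecules(self, small_panel, small_refs):
        variants = [(v, 0.0) for v in _small_panel_variants(small_panel)]
        config = SimulationConfig(seed=3, mass_ng=2.0)
        mols = simulate_molecules(small_panel, variants, config)
        refs = mols["amplicon_id"].map(small_refs)
        assert (mols["allele"].astype(str) == refs.astype(str)).all()

    def test_ar_copy_gain_inflates_molecule_count_by_mixture_factor(self, panel273):
        config = SimulationConfig(seed=5, mass_ng=22.0, tumor_fraction=0.1,
                                  ar_copies_in_tumor=22)
        assert copy_mixture_factor(0.1, 22) == pytest.approx(2.0)
        mols = simulate_molecules(panel273, (), config)
        genes = {a.id: a.gene for a in panel273.amplicons}
        per_amp = mols.groupby("amplicon_id", observed=True).size()
        is_ar = per_amp.index.map(lambda a: genes[a] == "AR")
        ratio = per_amp[is_ar].mean() / per_amp[~is_ar].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_truth_af_recovery_over_replicates(self, small_panel, small_refs):
        """Pooled alternate-molecule fraction stays within 3 binomial sigma of
        the 10% target over 50 seeded replicates."""
        variants = [(v, 0.10) for v in _small_panel_variants(small_panel)]
        alt_keys = {(small_panel.find_amplicon(v.chrom, v.pos).id, v.alt) for v, _ in variants}
        n_alt = n_tot = 0
        for seed in range(50):
            config = SimulationConfig(seed=seed, mass_ng=2.0)
            mols = simulate_molecules(small_panel, variants, config)
            on_variant = mols["amplicon_id"].isin({k[0] for k in alt_keys})
            sub = mols[on_variant]
            n_tot += len(sub)
            alt = sub.apply(lambda r: (str(r["amplicon_id"]), str(r["allele"])) in alt_keys, axis=1)
            n_alt += int(alt.sum())
        p_hat = n_alt / n_tot
        sigma = math.sqrt(0.10 * 0.90 / n_tot)
        assert abs(p_hat - 0.10) < 3 * sigma


def _small_panel_variants(small_panel):
    loci = locus_map(small_panel)
    out = []
    for amp in small_panel.amplicons[:3]:
        locus = loci[amp.id]
        alt = "ACGT"[("ACGT".index(locus.ref) + 1) % 4]
        out.append(VariantRecord(chrom=locus.chrom, pos=locus.pos, ref=locus.ref,
                                 alt=alt, gene=amp.gene))
    return out


class TestSimulateReads:
    def test_zero_error_rate_preserves_alleles(self, small_panel):
        config = SimulationConfig(seed=11, mass_ng=1.0, per_base_error_rate=0.0)
        mols = simulate_molecules(small_panel, (), config)
        reads = simulate_reads(mols, config)
        by_umi = dict(zip(mols["umi"], mols["allele"].astype(str)))
        assert (reads["allele"].astype(str) == reads["umi"].map(by_umi)).all()

    def test_umi_conservation(self, small_panel):
        config = SimulationConfig(seed=13, mass_ng=1.0)
        mols = simulate_molecules(small_panel, (), config)
        reads = simulate_reads(mols, config)
        assert reads["umi"].nunique() == len(mols)
        assert len(reads) >= len(mols)  # every molecule yields >= 1 read

    def test_family_size_median_reaches_qc_floor(self, small_panel):
        # 1 + Poisson(8) has median 9; with hundreds of molecules the sample
        # median should not fall below 8
        for seed in range(5):
            config = SimulationConfig(seed=seed, mass_ng=2.0)
            mols = simulate_molecules(small_panel, (), config)
            reads = simulate_reads(mols, config)
            sizes = reads.groupby("umi", observed=True).size()
            assert sizes.median() >= 8

    def test_empty_molecules_empty_reads(self, small_panel):
        config = SimulationConfig(seed=1, mass_ng=0.0)
        mols = simulate_molecules(small_panel, (), config)
        reads = simulate_reads(mols, config)
        assert len(mols) == 0 and len(reads) == 0

    def test_strand_inherited_from_molecule(self, small_panel):
        config = SimulationConfig(seed=17, mass_ng=0.5)
        mols = simulate_molecules(small_panel, (), config)
        reads = simulate_reads(mols, config)
        strand_of = dict(zip(mols["umi"], mols["strand"].astype(str)))
        assert (reads["strand"].astype(str) == reads["umi"].map(strand_of)).all()


class TestCoverageProfile:
    def test_mean_depth_near_target(self, panel273):
        config = SimulationConfig(seed=19)
        cov = simulate_coverage_profile(panel273, config)
        depths = np.array(list(cov.rows.values()), dtype=float)
        assert abs(depths.mean() - 50_000) / 50_000 < 0.02

    def test_no_tumor_no_ar_shift(self, panel273):
        config = SimulationConfig(seed=23, tumor_fraction=0.0)
        cov = simulate_coverage_profile(panel273, config)
        genes = {a.id: a.gene for a in panel273.amplicons}
        ar = [n for a, n in cov.rows.items() if genes[a] == "AR"]
        other = [n for a, n in cov.rows.items() if genes[a] != "AR"]
        assert np.mean(ar) / np.mean(other) == pytest.approx(1.0, rel=0.1)

    def test_copy_mixture_scales_ar_depth(self, panel273):
        config = SimulationConfig(seed=29, tumor_fraction=0.1, ar_copies_in_tumor=22)
        cov = simulate_coverage_profile(panel273, config)
        genes = {a.id: a.gene for a in panel273.amplicons}
        ar = [n for a, n in cov.rows.items() if genes[a] == "AR"]
        other = [n for a, n in cov.rows.items() if genes[a] != "AR"]
        assert np.mean(ar) / np.mean(other) == pytest.approx(2.0, rel=0.1)


class TestEmitDataset:
    CONFIG_KW = dict(mass_ng=0.5)  # small datasets: the formats, not the scale

    def test_healthy_donor_truth_is_empty(self, tmp_path):
        from panelkit.panel import read_variants_vcf

        scenario = HealthyDonorScenario()
        config = SimulationConfig(seed=1, **self.CONFIG_KW)
        paths = emit_dataset(tmp_path / "hd", scenario, seed=1, config=config)
        assert read_variants_vcf(paths["truth"]) == []

    def test_spike_truth_has_four_records(self, tmp_path):
        from panelkit.panel import read_variants_vcf

        scenario = SpikeStandardScenario(af=0.10)
        config = SimulationConfig(seed=1, tumor_fraction=0.10,
                                  ar_copies_in_tumor=SPIKE_AR_COPIES, **self.CONFIG_KW)
        paths = emit_dataset(tmp_path / "spike", scenario, seed=1, config=config)
        records = read_variants_vcf(paths["truth"])
        assert len(records) == 4
        assert all(r.af == 0.10 for r in records)

    def test_same_seed_byte_identical(self, tmp_path):
        scenario = WildTypeScenario()
        config = SimulationConfig(seed=42, **self.CONFIG_KW)
        p1 = emit_dataset(tmp_path / "a", scenario, seed=42, config=config)
        p2 = emit_dataset(tmp_path / "b", scenario, seed=42, config=config)
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_refuses_nonempty_dir(self, tmp_path):
        out = tmp_path / "occupied"
        out.mkdir()
        (out / "keep.txt").write_text("x")
        with pytest.raises(FileExistsError):
            emit_dataset(out, WildTypeScenario(), seed=1,
                         config=SimulationConfig(seed=1, **self.CONFIG_KW))

    def test_reads_tsv_round_trip_grouping_columns(self, tmp_path):
        config = SimulationConfig(seed=3, **self.CONFIG_KW)
        paths = emit_dataset(tmp_path / "wt", WildTypeScenario(), seed=3, config=config)
        reads = read_reads_tsv(paths["reads"])
        assert list(reads.columns) == ["amplicon_id", "umi", "strand", "allele"]
        assert len(reads) > 0


class TestScenarioParsing:
    @pytest.mark.parametrize("token,cls_name", [
        ("spike:0.005", "SpikeStandardScenario"),
        ("healthy_donor", "HealthyDonorScenario"),
        ("wild_type", "WildTypeScenario"),
    ])
    def test_known_tokens(self, token, cls_name):
        assert type(parse_scenario(token)).__name__ == cls_name

    def test_unknown_token(self):
        with pytest.raises(ValueError):
            parse_scenario("plasma?nope")


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"mass_ng": -1}, {"conversion_efficiency": 0.0}, {"conversion_efficiency": 1.5},
        {"tumor_fraction": 1.5}, {"ar_copies_in_tumor": 1}, {"per_base_error_rate": 1.0},
        {"reads_per_family_mean": 0.5},
    ])
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, **kw)
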