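"""Synthetic data generator: spike-in allele-fraction standards, plasma samples
with a stated tumor fraction and AR copy number, matched tumor variant lists,
and per-amplicon coverage profiles — all with known truth and explicit seeds.

The generator works at the level the downstream rules operate on: one
interrogated locus per amplicon, single-base allele tokens, UMI-tagged reads
with per-read error. It does not synthesize base-level sequences.

Model in brief: a DNA mass is converted to haploid genome equivalents (GE,
3.3 pg each); each amplicon independently samples Binomial(GE, conversion
efficiency) input molecules; a molecule at a variant locus carries the
alternate allele with probability equal to the variant's target allele
fraction; each molecule yields 1 + Poisson(mean - 1) reads sharing its UMI and
strand, and every read's allele flips to a random wrong base with the per-base
error rate. AR amplicons are scaled by the diploid copy mixture
((1 - tf) * 2 + tf * c) / 2 for tumor fraction tf carrying c AR copies; the
alternate-allele probability at AR loci is diluted by the same factor, since
the gained copies carry the reference allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import (
    AmpliconCoverage,
    Locus,
    PanelDesign,
    PatientRecord,
    VariantRecord,
    locus_map,
    replica_panel,
    write_coverage_csv,
    write_sample_metadata,
    write_variants_vcf,
)

__all__ = [
    "ALLELES",
    "SPIKE_AF_LEVELS",
    "SPIKE_MASS_NG",
    "SPIKE_AR_COPIES",
    "SimulationConfig",
    "SpikeTruth",
    "SpikeStandardScenario",
    "PlasmaPatientScenario",
    "HealthyDonorScenario",
    "WildTypeScenario",
    "SampleData",
    "mass_to_genome_equivalents",
    "copy_mixture_factor",
    "spike_variants",
    "make_spike_standard",
    "simulate_molecules",
    "simulate_reads",
    "simulate_coverage_profile",
    "simulate_sample",
    "emit_dataset",
    "parse_scenario",
    "read_reads_tsv",
    "make_matched_cohort",
    "make_association_cohort",
]

ALLELES = ("A", "C", "G", "T")
READ_COLUMNS = ("amplicon_id", "umi", "strand", "allele")

#: The four dilution levels of the spike-in validation series.
SPIKE_AF_LEVELS = (0.10, 0.01, 0.005, 0.001)
#: DNA input used to build each spike standard library (ng).
SPIKE_MASS_NG = 22.0
#: AR copy number of the amplified (VCaP-like) compartment. Derived from the
#: measured 10%-standard coverage ratio of 2.15: (2*2.15 - 1.8) / 0.1 = 25.
SPIKE_AR_COPIES = 25


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable simulator parameters. ``seed`` is mandatory."""

    seed: int
    mass_ng: float = SPIKE_MASS_NG
    pg_per_haploid_genome: float = 3.3
    conversion_efficiency: float = 0.5
    reads_per_family_mean: float = 9.0
    per_base_error_rate: float = 1e-3
    tumor_fraction: float = 0.0
    ar_copies_in_tumor: int = 2
    depth_target: float = 50_000.0
    depth_dispersion: float = 400.0  # NB size parameter; CV ~ 5% at depth_target

    def __post_init__(self) -> None:
        if self.mass_ng < 0:
            raise ValueError("mass_ng must be non-negative")
        if not 0 < self.conversion_efficiency <= 1:
            raise ValueError("conversion_efficiency must be in (0, 1]")
        if not 0 <= self.per_base_error_rate < 1:
            raise ValueError("per_base_error_rate must be in [0, 1)")
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.ar_copies_in_tumor < 2:
            raise ValueError("ar_copies_in_tumor must be >= 2")
        if self.reads_per_family_mean < 1:
            raise ValueError("reads_per_family_mean must be >= 1")


def mass_to_genome_equivalents(mass_ng: float, pg_per_haploid_genome: float = 3.3) -> int:
    """Haploid genome equivalents in a DNA mass: floor(ng * 1000 / pg)."""
    if mass_ng < 0:
        raise ValueError("mass_ng must be non-negative")
    if pg_per_haploid_genome <= 0:
        raise ValueError("pg_per_haploid_genome must be positive")
    return math.floor(mass_ng * 1000.0 / pg_per_haploid_genome)


def copy_mixture_factor(tumor_fraction: float, copies: int) -> float:
    """Expected coverage scaling of a gene at ``copies`` per tumor cell in a
    diploid background: ((1 - tf) * 2 + tf * copies) / 2."""
    return ((1.0 - tumor_fraction) * 2.0 + tumor_fraction * copies) / 2.0


# ---------------------------------------------------------------------------
# Spike standards
# ---------------------------------------------------------------------------

#: (gene, amplicon index within gene, protein change, cell line of origin)
_SPIKE_MUTATIONS = (
    ("AR", 1, "p.T878A", "LNCaP"),
    ("RB1", 1, "p.K715*", "DU145"),
    ("TP53", 1, "p.R248W", "VCaP"),
    ("TP53", 2, "p.V274F", "DU145"),
)

#: Cell line whose genome carries the AR amplification.
AR_AMPLIFIED_LINE = "VCaP"


def spike_variants(panel: PanelDesign | None = None) -> list[VariantRecord]:
    """The four cell-line mutations of the spike-in series, placed on the
    replica panel's loci (AR p.T878A, RB1 p.K715*, TP53 p.R248W, TP53 p.V274F)."""
    panel = panel if panel is not None else replica_panel()
    loci = locus_map(panel)
    out = []
    for gene, idx, pchange, _line in _SPIKE_MUTATIONS:
        locus = loci[f"{gene}_{idx:03d}"]
        alt = ALLELES[(ALLELES.index(locus.ref) + 1) % 4]
        out.append(
            VariantRecord(
                chrom=locus.chrom, pos=locus.pos, ref=locus.ref, alt=alt,
                gene=gene, protein_change=pchange,
            )
        )
    return out


@dataclass(frozen=True)
class SpikeTruth:
    """Ground truth of one spike-in standard."""

    variants: tuple[tuple[VariantRecord, float], ...]
    total_mass_ng: float
    cell_line_fractions: dict[str, float]
    ar_amplified_line: str = AR_AMPLIFIED_LINE

    @property
    def wild_type_fraction(self) -> float:
        return 1.0 - sum(self.cell_line_fractions.values())


def make_spike_standard(af: float, seed: int = 0) -> SpikeTruth:
    """Build the truth for a spike-in standard at one of the four AF levels.

    Each mutation is homozygous in its cell line, so a line's mass fraction in
    the mix equals the target AF of its mutations. The construction is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    if not any(math.isclose(af, level) for level in SPIKE_AF_LEVELS):
        raise ValueError(f"unsupported spike AF {af}; expected one of {SPIKE_AF_LEVELS}")
    variants = tuple((v, af) for v in spike_variants())
    fractions = {line: af for (_g, _i, _p, line) in _SPIKE_MUTATIONS}
    return SpikeTruth(
        variants=variants, total_mass_ng=SPIKE_MASS_NG, cell_line_fractions=fractions
    )


# ---------------------------------------------------------------------------
# Core simulators
# ---------------------------------------------------------------------------

def _ar_factor(config: SimulationConfig) -> float:
    if config.tumor_fraction > 0 and config.ar_copies_in_tumor > 2:
        return copy_mixture_factor(config.tumor_fraction, config.ar_copies_in_tumor)
    return 1.0


def simulate_molecules(
    panel: PanelDesign,
    truth_variants: Sequence[tuple[VariantRecord, float]],
    config: SimulationConfig,
    ar_gene: str = "AR",
) -> pd.DataFrame:
    """Simulate converted input molecules per amplicon.

    Returns a molecule table with columns amplicon_id, umi, strand, allele.
    UMIs are globally unique integers; strand is fixed per molecule.
    """
    rng = np.random.default_rng(config.seed)
    ge = mass_to_genome_equivalents(config.mass_ng, config.pg_per_haploid_genome)
    loci = locus_map(panel)
    factor = _ar_factor(config)

    amp_ids = list(panel.amplicon_ids)
    is_ar = np.array([panel.get(a).gene == ar_gene for a in amp_ids])
    pool = np.where(is_ar, np.round(ge * factor).astype(int), ge)
    n_mol = rng.binomial(pool, config.conversion_efficiency)
    total = int(n_mol.sum())

    amp_codes = np.repeat(np.arange(len(amp_ids), dtype=np.int32), n_mol)
    umi = np.arange(total, dtype=np.int64)
    strand = rng.integers(0, 2, total, dtype=np.int8)

    ref_code = np.array([ALLELES.index(loci[a].ref) for a in amp_ids], dtype=np.int8)
    allele = ref_code[amp_codes]

    # Alternate alleles at variant loci.
    offsets = np.concatenate([[0], np.cumsum(n_mol)])
    amp_index = {a: i for i, a in enumerate(amp_ids)}
    for variant, target_af in truth_variants:
        amp = panel.find_amplicon(variant.chrom, variant.pos)
        if amp is None:
            continue  # variant outside the panel: invisible to the assay
        i = amp_index[amp.id]
        p_alt = target_af / factor if is_ar[i] else target_af
        lo, hi = offsets[i], offsets[i + 1]
        hit = rng.random(hi - lo) < p_alt
        allele[lo:hi][hit] = ALLELES.index(variant.alt)

    return pd.DataFrame(
        {
            "amplicon_id": pd.Categorical.from_codes(amp_codes, categories=amp_ids),
            "umi": umi,
            "strand": pd.Categorical.from_codes(strand, categories=["F", "R"]),
            "allele": pd.Categorical.from_codes(allele, categories=list(ALLELES)),
        }
    )


def simulate_reads(molecules: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Expand molecules to UMI-tagged reads with per-read allele error.

    Read count per molecule is 1 + Poisson(reads_per_family_mean - 1); UMI and
    strand are inherited; a read's allele flips to one of the three other bases
    with probability per_base_error_rate.
    """
    if len(molecules) == 0:
        return _empty_reads()
    # separate stream from molecule generation, still fully seed-determined
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_reads = 1 + rng.poisson(config.reads_per_family_mean - 1.0, len(molecules))
    total = int(n_reads.sum())

    amp = np.repeat(molecules["amplicon_id"].cat.codes.to_numpy(), n_reads)
    umi = np.repeat(molecules["umi"].to_numpy(), n_reads)
    strand = np.repeat(molecules["strand"].cat.codes.to_numpy(), n_reads)
    allele = np.repeat(molecules["allele"].cat.codes.to_numpy(), n_reads).astype(np.int8)

    if config.per_base_error_rate > 0:
        err = rng.random(total) < config.per_base_error_rate
        n_err = int(err.sum())
        if n_err:
            allele[err] = (allele[err] + rng.integers(1, 4, n_err)) % 4

    return pd.DataFrame(
        {
            "amplicon_id": pd.Categorical.from_codes(
                amp, categories=molecules["amplicon_id"].cat.categories
            ),
            "umi": umi,
            "strand": pd.Categorical.from_codes(strand, categories=["F", "R"]),
            "allele": pd.Categorical.from_codes(allele, categories=list(ALLELES)),
        }
    )


def _empty_reads() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "amplicon_id": pd.Categorical([], categories=[]),
            "umi": pd.Series([], dtype=np.int64),
            "strand": pd.Categorical([], categories=["F", "R"]),
            "allele": pd.Categorical([], categories=list(ALLELES)),
        }
    )


def simulate_coverage_profile(
    panel: PanelDesign, config: SimulationConfig, sample_id: str = "sim", ar_gene: str = "AR"
) -> AmpliconCoverage:
    """Per-amplicon total read counts: negative binomial around the target depth,
    with AR amplicons scaled by the copy-mixture factor."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    factor = _ar_factor(config)
    rows = {}
    r = config.depth_dispersion
    for a in panel.amplicons:
        mu = config.depth_target * (factor if a.gene == ar_gene else 1.0)
        rows[a.id] = int(rng.negative_binomial(r, r / (r + mu)))
    return AmpliconCoverage(sample_id=sample_id, rows=rows)


# ---------------------------------------------------------------------------
# Scenarios and dataset emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeStandardScenario:
    af: float

    @property
    def name(self) -> str:
        return f"spike_{self.af:g}"


@dataclass(frozen=True)
class PlasmaPatientScenario:
    patient_id: str
    variants: tuple[tuple[VariantRecord, float], ...] = ()
    tumor_fraction: float = 0.0
    ar_copies: int = 2
    tumor_variants: tuple[VariantRecord, ...] | None = None

    @property
    def name(self) -> str:
        return f"plasma_{self.patient_id}"


@dataclass(frozen=True)
class HealthyDonorScenario:
    name: str = "healthy_donor"


@dataclass(frozen=True)
class WildTypeScenario:
    name: str = "wild_type"


Scenario = SpikeStandardScenario | PlasmaPatientScenario | HealthyDonorScenario | WildTypeScenario


def parse_scenario(text: str) -> Scenario:
    """Parse a scenario token: ``spike:0.005``, ``healthy_donor`` or ``wild_type``."""
    if text == "healthy_donor":
        return HealthyDonorScenario()
    if text == "wild_type":
        return WildTypeScenario()
    if text.startswith("spike:"):
        return SpikeStandardScenario(af=float(text.split(":", 1)[1]))
    raise ValueError(f"unknown scenario {text!r}")


def scenario_config(scenario: Scenario, seed: int, **overrides) -> SimulationConfig:
    """Simulator configuration matching a scenario's study conditions."""
    if isinstance(scenario, SpikeStandardScenario):
        base = dict(
            mass_ng=SPIKE_MASS_NG, tumor_fraction=scenario.af,
            ar_copies_in_tumor=SPIKE_AR_COPIES,
        )
    elif isinstance(scenario, PlasmaPatientScenario):
        base = dict(
            tumor_fraction=scenario.tumor_fraction,
            ar_copies_in_tumor=scenario.ar_copies,
        )
    else:
        base = dict(tumor_fraction=0.0)
    base.update(overrides)
    return SimulationConfig(seed=seed, **base)


def scenario_truth(scenario: Scenario) -> tuple[tuple[VariantRecord, float], ...]:
    if isinstance(scenario, SpikeStandardScenario):
        return make_spike_standard(scenario.af).variants
    if isinstance(scenario, PlasmaPatientScenario):
        return tuple(scenario.variants)
    return ()


@dataclass
class SampleData:
    """Everything simulated for one sample."""

    name: str
    reads: pd.DataFrame
    coverage: AmpliconCoverage
    truth: tuple[tuple[VariantRecord, float], ...]
    metadata: PatientRecord
    config: SimulationConfig


def simulate_sample(
    panel: PanelDesign, scenario: Scenario, seed: int, config: SimulationConfig | None = None
) -> SampleData:
    """Simulate one full sample (reads + coverage + truth + metadata)."""
    config = config or scenario_config(scenario, seed)
    truth = scenario_truth(scenario)
    molecules = simulate_molecules(panel, truth, config)
    reads = simulate_reads(molecules, config)
    coverage = simulate_coverage_profile(panel, config, sample_id=scenario.name)
    if isinstance(scenario, PlasmaPatientScenario):
        meta = PatientRecord(
            patient_id=scenario.patient_id, hormonal_status="mCRPC",
            cfdna_ng_ml=10.0,
            tumor_variants=list(scenario.tumor_variants) if scenario.tumor_variants is not None else None,
        )
    else:
        meta = PatientRecord(patient_id=scenario.name, cfdna_ng_ml=10.0)
    return SampleData(
        name=scenario.name, reads=reads, coverage=coverage, truth=truth,
        metadata=meta, config=config,
    )


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    """Read a tagged-read table (amplicon_id, umi, strand, allele)."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"amplicon_id": "category", "umi": str, "strand": "category", "allele": "category"},
    )
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reads TSV missing columns {sorted(missing)}")
    df["allele"] = df["allele"].cat.set_categories(list(ALLELES))
    df["strand"] = df["strand"].cat.set_categories(["F", "R"])
    return df


def emit_dataset(
    out_dir: str | Path,
    scenario: Scenario,
    seed: int,
    config: SimulationConfig | None = None,
    panel: PanelDesign | None = None,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write a complete simulated dataset: reads TSV, coverage CSV, truth VCF,
    metadata TSV. Refuses to write into a non-empty directory unless told to."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)
    panel = panel if panel is not None else replica_panel()
    sample = simulate_sample(panel, scenario, seed, config=config)

    paths = {
        "reads": out / "reads.tsv",
        "coverage": out / "coverage.csv",
        "truth": out / "truth.vcf",
        "metadata": out / "metadata.tsv",
    }
    sample.reads.to_csv(paths["reads"], sep="\t", index=False)
    write_coverage_csv(sample.coverage, panel, paths["coverage"])
    truth_records = [replace(v, af=target) for v, target in sample.truth]
    write_variants_vcf(truth_records, paths["truth"])
    write_sample_metadata([sample.metadata], paths["metadata"])
    return paths


# ---------------------------------------------------------------------------
# Cohort builders
# ---------------------------------------------------------------------------

def _panel_variant(loci: dict[str, Locus], amp_id: str) -> VariantRecord:
    locus = loci[amp_id]
    alt = ALLELES[(ALLELES.index(locus.ref) + 1) % 4]
    return VariantRecord(
        chrom=locus.chrom, pos=locus.pos, ref=locus.ref, alt=alt, gene=locus.gene, af=0.05
    )


def make_matched_cohort(panel: PanelDesign | None = None) -> list[PatientRecord]:
    """Deterministic matched tumor/plasma cohort reproducing the published
    concordance structure: mCRPC 17 concordant / 0 discordant / 5 without a
    panel-target tumor mutation; mCSPC 4 / 7 / 9. Of the 14 no-target patients,
    6 have no tumor mutation at all and 8 carry one the panel does not cover.
    """
    panel = panel if panel is not None else replica_panel()
    loci = locus_map(panel)
    # non-AR amplicons, stable order, one variant locus per patient
    amp_ids = [a.id for a in panel.amplicons if a.gene != "AR"]
    off_panel = VariantRecord(chrom="chrZ", pos=100, ref="A", alt="T", gene="OFFPANEL", af=0.3)

    patients: list[PatientRecord] = []
    k = 0

    def next_variant() -> VariantRecord:
        nonlocal k
        v = _panel_variant(loci, amp_ids[k])
        k += 1
        return v

    plan = [
        # (status, n, kind)
        ("mCRPC", 17, "concordant"),
        ("mCRPC", 0, "discordant"),
        ("mCRPC", 2, "tumor_empty"),
        ("mCRPC", 3, "tumor_off_panel"),
        ("mCSPC", 4, "concordant"),
        ("mCSPC", 7, "discordant"),
        ("mCSPC", 4, "tumor_empty"),
        ("mCSPC", 5, "tumor_off_panel"),
    ]
    pid = 0
    for status, n, kind in plan:
        for _ in range(n):
            pid += 1
            if kind == "concordant":
                v = next_variant()
                tumor, plasma = [v], [v]
            elif kind == "discordant":
                v = next_variant()
                tumor, plasma = [v], []
            elif kind == "tumor_empty":
                tumor, plasma = [], []
            else:  # tumor_off_panel
                tumor, plasma = [off_panel], []
            patients.append(
                PatientRecord(
                    patient_id=f"P{pid:03d}", hormonal_status=status,
                    psa_ng_ml=50.0, cfdna_ng_ml=12.0, on_therapy=False,
                    tumor_variants=tumor, plasma_variants=plasma,
                )
            )
    return patients


def make_association_cohort(
    seed: int,
    n_low: int = 8,
    n_high: int = 50,
    p_low: float = 0.375,
    p_high: float = 0.80,
) -> list[PatientRecord]:
    """Cohort with a PSA-ctDNA-positivity association at a stated effect size:
    PSA < 4 ng/mL patients are ctDNA-positive with probability ``p_low``,
    PSA >= 4 ng/mL with probability ``p_high``."""
    rng = np.random.default_rng(seed)
    dummy = VariantRecord(chrom="chr1", pos=1_000_050, ref="A", alt="G", gene="TP53", af=0.05)
    patients = []
    for i in range(n_low + n_high):
        low = i < n_low
        positive = rng.random() < (p_low if low else p_high)
        patients.append(
            PatientRecord(
                patient_id=f"S{i:03d}", hormonal_status="mCRPC",
                psa_ng_ml=float(rng.uniform(0.5, 3.9)) if low else float(rng.uniform(10, 500)),
                cfdna_ng_ml=float(rng.uniform(3, 60)),
                plasma_variants=[dummy] if positive else [],
            )
        )
    return patients
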