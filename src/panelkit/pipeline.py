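"""End-to-end orchestration: simulate -> group families -> QC -> call -> filter
-> copy number, driven by a single config with one seed, writing per-stage
outputs and a deterministic manifest (content hashes, no timestamps).
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pysam

from . import consensus, filters
from .cnv import call_amplification, gene_ratio
from .panel import (
    PanelDesign,
    VariantRecord,
    locus_map,
    replica_panel,
    write_coverage_csv,
    write_variants_vcf,
)
from .simulate import (
    SampleData,
    Scenario,
    SimulationConfig,
    parse_scenario,
    scenario_config,
    simulate_sample,
)

__all__ = ["RunConfig", "validate_config", "load_config", "run_pipeline",
           "write_candidates_vcf", "read_candidates_vcf"]

log = logging.getLogger("panelkit")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration. Defaults are the assay's published operating
    points: 3 supporting reads on both strands, mean family size >= 8 per
    amplicon, population MAF cutoff 0.001, CHIP advisory below 1% AF, AR gain
    threshold 2.0."""

    seed: int
    scenarios: tuple[str, ...]
    out_dir: str = "panelkit_run"
    # simulator
    mass_ng: float = 22.0
    conversion_efficiency: float = 0.5
    reads_per_family_mean: float = 9.0
    per_base_error_rate: float = 1e-3
    # caller
    min_reads: int = 3
    both_strands: bool = True
    min_mean_reads: float = 8.0
    # filter
    maf_cutoff: float = 0.001
    chip_af: float = 0.01
    # cnv
    cnv_gene: str = "AR"
    cnv_threshold: float = 2.0


_DEFAULTS = RunConfig(seed=0, scenarios=())


def validate_config(raw: dict) -> RunConfig:
    """Normalize and range-check a raw (string-valued) config mapping."""
    def get(key, cast, default, check=None, bound=""):
        if key not in raw or raw[key] in (None, ""):
            return default
        try:
            value = cast(raw[key])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"config key {key!r}: cannot parse {raw[key]!r}") from exc
        if check is not None and not check(value):
            raise ValueError(f"config key {key!r} = {value!r} out of range ({bound})")
        return value

    def as_bool(v):
        if isinstance(v, bool):
            return v
        if str(v).lower() in ("true", "yes", "1"):
            return True
        if str(v).lower() in ("false", "no", "0"):
            return False
        raise ValueError(v)

    scenarios = raw.get("scenarios", ())
    if isinstance(scenarios, str):
        scenarios = tuple(s.strip() for s in scenarios.split(",") if s.strip())
    for s in scenarios:
        parse_scenario(s)  # raises on unknown scenario tokens

    return RunConfig(
        seed=get("seed", int, 0, lambda v: v >= 0, ">= 0"),
        scenarios=tuple(scenarios),
        out_dir=str(raw.get("out_dir", _DEFAULTS.out_dir)),
        mass_ng=get("mass_ng", float, _DEFAULTS.mass_ng, lambda v: v >= 0, ">= 0"),
        conversion_efficiency=get(
            "conversion_efficiency", float, _DEFAULTS.conversion_efficiency,
            lambda v: 0 < v <= 1, "(0, 1]",
        ),
        reads_per_family_mean=get(
            "reads_per_family_mean", float, _DEFAULTS.reads_per_family_mean,
            lambda v: v >= 1, ">= 1",
        ),
        per_base_error_rate=get(
            "per_base_error_rate", float, _DEFAULTS.per_base_error_rate,
            lambda v: 0 <= v < 1, "[0, 1)",
        ),
        min_reads=get("min_reads", int, _DEFAULTS.min_reads, lambda v: v >= 1, ">= 1"),
        both_strands=get("both_strands", as_bool, _DEFAULTS.both_strands),
        min_mean_reads=get(
            "min_mean_reads", float, _DEFAULTS.min_mean_reads, lambda v: v >= 0, ">= 0"
        ),
        maf_cutoff=get(
            "maf_cutoff", float, _DEFAULTS.maf_cutoff, lambda v: 0 <= v <= 1, "[0, 1]"
        ),
        chip_af=get("chip_af", float, _DEFAULTS.chip_af, lambda v: 0 <= v <= 1, "[0, 1]"),
        cnv_gene=str(raw.get("cnv_gene", _DEFAULTS.cnv_gene)),
        cnv_threshold=get(
            "cnv_threshold", float, _DEFAULTS.cnv_threshold, lambda v: v >= 1, ">= 1"
        ),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key-value config file (INI sections are allowed and ignored
    for addressing: keys must be globally unique)."""
    parser = configparser.ConfigParser()
    text = Path(path).read_text()
    if not text.strip().startswith("["):
        text = "[run]\n" + text
    parser.read_string(text)
    raw: dict[str, str] = {}
    for section in parser.sections():
        for key, value in parser.items(section):
            if key in raw:
                raise ValueError(f"{path}: duplicate config key {key!r}")
            raw[key] = value
    return validate_config(raw)


# ---------------------------------------------------------------------------
# Candidate VCF with support fields
# ---------------------------------------------------------------------------

_CAND_INFO = (
    ("AF", "1", "Float", "Family-space allele fraction"),
    ("GENE", "1", "String", "Gene symbol"),
    ("PCHANGE", "1", "String", "Protein change"),
    ("READS", "1", "Integer", "Supporting reads, both strands"),
    ("FWD", "1", "Integer", "Supporting reads, forward strand"),
    ("REV", "1", "Integer", "Supporting reads, reverse strand"),
    ("FAMS", "1", "Integer", "Supporting molecular families"),
    ("TOTFAMS", "1", "Integer", "Molecular families at the locus"),
)


def write_candidates_vcf(candidates: Sequence[consensus.VariantCandidate], path: str | Path) -> None:
    header = pysam.VariantHeader()
    for name, number, vtype, desc in _CAND_INFO:
        header.add_line(f'##INFO=<ID={name},Number={number},Type={vtype},Description="{desc}">')
    for chrom in dict.fromkeys(c.variant.chrom for c in candidates):
        header.add_line(f"##contig=<ID={chrom}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in candidates:
            v = c.variant
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["AF"] = float(v.af)
            rec.info["GENE"] = v.gene or "."
            rec.info["PCHANGE"] = v.protein_change or "."
            rec.info["READS"] = c.supporting_reads_total
            rec.info["FWD"] = c.supporting_reads_forward
            rec.info["REV"] = c.supporting_reads_reverse
            rec.info["FAMS"] = c.supporting_families
            rec.info["TOTFAMS"] = c.total_families_at_locus
            out.write(rec)


def read_candidates_vcf(path: str | Path) -> list[consensus.VariantCandidate]:
    out: list[consensus.VariantCandidate] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gene = str(rec.info["GENE"])
            pchange = str(rec.info["PCHANGE"])
            out.append(
                consensus.VariantCandidate(
                    variant=VariantRecord(
                        chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                        gene="" if gene == "." else gene,
                        protein_change="" if pchange == "." else pchange,
                        af=float(f"{float(rec.info['AF']):.6g}"),
                    ),
                    supporting_reads_total=int(rec.info["READS"]),
                    supporting_reads_forward=int(rec.info["FWD"]),
                    supporting_reads_reverse=int(rec.info["REV"]),
                    supporting_families=int(rec.info["FAMS"]),
                    total_families_at_locus=int(rec.info["TOTFAMS"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sample_seed(seed: int, index: int) -> int:
    return (seed * 1009 + index) % (2**31 - 1)


def run_pipeline(config: RunConfig, panel: PanelDesign | None = None) -> dict:
    """Execute every scenario through the full stage chain and write a manifest.

    Per sample: simulate reads and coverage, group molecular families, compute
    library QC (downstream stages are skipped on QC failure and the skip is
    recorded), call candidates on valid amplicons, run the somatic filter
    cascade with the truth-derived annotation table, flag CHIP where a matched
    tumor exists, and compute the target-gene coverage ratio and gain call.
    """
    panel = panel if panel is not None else replica_panel()
    loci = locus_map(panel)
    ref_alleles = {a: l.ref for a, l in loci.items()}
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items() if k != "scenarios"},
        "samples": {},
        "files": {},
    }

    for i, token in enumerate(config.scenarios):
        scenario = parse_scenario(token)
        sample_seed = _sample_seed(config.seed, i)
        sim_config = scenario_config(
            scenario, sample_seed,
            mass_ng=config.mass_ng,
            conversion_efficiency=config.conversion_efficiency,
            reads_per_family_mean=config.reads_per_family_mean,
            per_base_error_rate=config.per_base_error_rate,
        )
        sample = simulate_sample(panel, scenario, sample_seed, config=sim_config)
        sample_dir = out_root / sample.name
        sample_dir.mkdir(exist_ok=True)
        entry: dict = {"scenario": token, "seed": sample_seed}
        log.info("sample=%s stage=simulate reads=%d", sample.name, len(sample.reads))

        families = consensus.group_families(sample.reads, ref_alleles=ref_alleles)
        qc = consensus.sample_qc(families, panel)
        entry["qc"] = {
            "passed": qc.passed,
            "molecular_uniformity": qc.molecular_uniformity,
            "median_reads_per_functional_molecule": qc.median_reads_per_functional_molecule,
            "average_molecular_coverage": qc.average_molecular_coverage,
            "reason": qc.reason,
        }
        (sample_dir / "qc.json").write_text(json.dumps(entry["qc"], sort_keys=True, indent=1))
        write_coverage_csv(sample.coverage, panel, sample_dir / "coverage.csv")

        truth_records = [replace(v, af=t) for v, t in sample.truth]
        write_variants_vcf(truth_records, sample_dir / "truth.vcf")

        if not qc.passed:
            log.warning("sample=%s stage=qc event=failed reason=%s", sample.name, qc.reason)
            entry["skipped_after_qc"] = True
        else:
            valid, validity = consensus.valid_families(families, config.min_mean_reads)
            candidates = consensus.call_candidates(
                valid, loci, min_reads=config.min_reads,
                require_both_strands=config.both_strands,
            )
            write_candidates_vcf(candidates, sample_dir / "candidates.vcf")

            table = filters.AnnotationTable.for_truth_variants([v for v, _ in sample.truth])
            annotated = filters.annotate(candidates, table)
            somatic, audit = filters.apply_filters(
                annotated, maf_cutoff=config.maf_cutoff, min_reads=config.min_reads
            )
            (sample_dir / "filter_audit.json").write_text(
                json.dumps(
                    [
                        {k: (list(v) if isinstance(v, tuple) else v) for k, v in r.items()}
                        for r in audit.records
                    ],
                    sort_keys=True, indent=1,
                )
            )
            tumor = sample.metadata.tumor_variants
            chip = filters.flag_chip(somatic, tumor, af_threshold=config.chip_af)
            write_variants_vcf([ac.candidate.variant for ac in somatic], sample_dir / "somatic.vcf")

            truth_keys = {v.key for v, _ in sample.truth}
            somatic_keys = {ac.key for ac in somatic}
            entry["n_candidates"] = len(candidates)
            entry["n_somatic"] = len(somatic)
            entry["n_invalid_amplicons"] = sum(not ok for ok in validity.values())
            entry["truth_variants"] = len(truth_keys)
            entry["truth_recovered"] = len(truth_keys & somatic_keys)
            entry["chip_flags"] = {
                "|".join(map(str, k)): v for k, v in sorted(chip.items())
            }

        ratio = gene_ratio(sample.coverage, panel, gene=config.cnv_gene)
        cnv = call_amplification(ratio, config.cnv_threshold)
        entry["cnv"] = {
            "gene": config.cnv_gene,
            "ratio_median": cnv.ratio_median,
            "ratio_mean": cnv.ratio_mean,
            "threshold": cnv.threshold,
            "amplified": cnv.amplified,
            "amplified_by_mean": cnv.amplified_by_mean,
            "median_mean_agree": cnv.median_mean_agree,
        }
        manifest["samples"][sample.name] = entry

    for path in sorted(out_root.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out_root))] = _sha256(path)

    (out_root / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
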