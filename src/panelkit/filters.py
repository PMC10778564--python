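"""Candidate-to-somatic filter cascade and the CHIP (clonal hematopoiesis) flag.

A candidate passes only when every rule holds:

  (a) read support: at least ``min_reads`` supporting reads with at least one
      on each strand (enforced upstream by the caller; re-checked here),
  (b) absent from public databases of common germline variants,
  (c) population minor allele frequency at most 0.001,
  (d) a protein-affecting consequence (missense, nonsense, frameshift, splice);
      synonymous, intronic, UTR and unannotated consequences are removed,
  (e) not annotated benign or likely benign in ClinVar.

The verdict is a pure conjunction, so rule order only affects which rule an
audit names as the first failure (evaluated a through e).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus import VariantCandidate
from .panel import VariantRecord

__all__ = [
    "CODING_CONSEQUENCES",
    "CONSEQUENCES",
    "CLINVAR_CLASSES",
    "Annotation",
    "AnnotationTable",
    "AnnotatedCandidate",
    "FilterAudit",
    "annotate",
    "apply_filters",
    "flag_chip",
]

CONSEQUENCES = (
    "missense", "nonsense", "frameshift", "splice",
    "synonymous", "intronic", "utr3", "utr5",
)
#: Consequences accepted by rule (d): the protein-affecting complement of the
#: excluded classes.
CODING_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "splice"})
CLINVAR_CLASSES = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")
_BENIGN = frozenset({"benign", "likely_benign"})

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class Annotation:
    """External annotation for one variant key. A missing population MAF means
    the variant was never observed and is treated as 0."""

    population_maf: float | None = None
    consequence: str | None = None
    clinvar: str | None = None
    in_common_db: bool = False

    def __post_init__(self) -> None:
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.clinvar is not None and self.clinvar not in CLINVAR_CLASSES:
            raise ValueError(f"unknown ClinVar class {self.clinvar!r}")
        if self.population_maf is not None and not 0 <= self.population_maf <= 1:
            raise ValueError("population_maf outside [0, 1]")


MISSING_ANNOTATION = Annotation()


class AnnotationTable:
    """Variant-key -> Annotation lookup with TSV round-trip."""

    def __init__(self, entries: Mapping[VariantKey, Annotation] | None = None):
        self.entries: dict[VariantKey, Annotation] = dict(entries or {})

    def get(self, key: VariantKey) -> Annotation:
        return self.entries.get(key, MISSING_ANNOTATION)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        entries = {}
        for row in df.itertuples():
            key = (row.chrom, int(row.pos), row.ref, row.alt)
            if key in entries:
                raise ValueError(f"{path}: duplicate annotation for {key}")
            entries[key] = Annotation(
                population_maf=float(row.population_maf) if row.population_maf else None,
                consequence=row.consequence or None,
                clinvar=row.clinvar or None,
                in_common_db=row.in_common_db == "yes",
            )
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tpopulation_maf\tconsequence\tclinvar\tin_common_db\n")
            for (chrom, pos, ref, alt), a in self.entries.items():
                maf = "" if a.population_maf is None else f"{a.population_maf:g}"
                fh.write(
                    f"{chrom}\t{pos}\t{ref}\t{alt}\t{maf}\t{a.consequence or ''}\t"
                    f"{a.clinvar or ''}\t{'yes' if a.in_common_db else 'no'}\n"
                )

    @classmethod
    def for_truth_variants(
        cls, variants: Iterable[VariantRecord]
    ) -> "AnnotationTable":
        """Annotate known somatic truth variants as they would look after real
        annotation: rare (MAF 0), protein-affecting, pathogenic. Nonsense is
        inferred from a protein change ending in '*'."""
        entries = {}
        for v in variants:
            consequence = "nonsense" if v.protein_change.endswith("*") else "missense"
            entries[v.key] = Annotation(
                population_maf=0.0, consequence=consequence,
                clinvar="pathogenic", in_common_db=False,
            )
        return cls(entries)


@dataclass(frozen=True)
class AnnotatedCandidate:
    candidate: VariantCandidate
    annotation: Annotation

    @property
    def key(self) -> VariantKey:
        return self.candidate.variant.key


@dataclass
class FilterAudit:
    """Per-candidate audit trail: verdict and the first failed rule (a-e)."""

    records: list[dict] = field(default_factory=list)

    def add(self, key: VariantKey, failed_rule: str | None, values: dict) -> None:
        self.records.append(
            {
                "variant": key,
                "verdict": "fail" if failed_rule else "pass",
                "failed_rule": failed_rule or "none",
                "values": values,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def annotate(
    candidates: Sequence[VariantCandidate], table: AnnotationTable
) -> list[AnnotatedCandidate]:
    """Attach annotations; candidates absent from the table get the missing
    annotation (MAF treated as 0, unknown consequence, no ClinVar class)."""
    return [AnnotatedCandidate(c, table.get(c.variant.key)) for c in candidates]


def _check_rule_a(c: VariantCandidate, min_reads: int) -> bool:
    if c.supporting_reads_total is None:
        raise ValueError("candidate missing read-support fields (rule a inputs)")
    return (
        c.supporting_reads_total >= min_reads
        and c.supporting_reads_forward > 0
        and c.supporting_reads_reverse > 0
    )


def apply_filters(
    annotated: Sequence[AnnotatedCandidate],
    maf_cutoff: float = 0.001,
    min_reads: int = 3,
) -> tuple[list[AnnotatedCandidate], FilterAudit]:
    """Run the five-rule cascade; returns (passing candidates, audit trail)."""
    audit = FilterAudit()
    passed: list[AnnotatedCandidate] = []
    for ac in annotated:
        c, a = ac.candidate, ac.annotation
        maf = a.population_maf if a.population_maf is not None else 0.0
        failed: str | None = None
        if not _check_rule_a(c, min_reads):
            failed = "a"
        elif a.in_common_db:
            failed = "b"
        elif maf > maf_cutoff:
            failed = "c"
        elif a.consequence not in CODING_CONSEQUENCES:
            failed = "d"
        elif a.clinvar in _BENIGN:
            failed = "e"
        audit.add(
            ac.key, failed,
            {
                "reads": c.supporting_reads_total,
                "forward": c.supporting_reads_forward,
                "reverse": c.supporting_reads_reverse,
                "population_maf": maf,
                "consequence": a.consequence,
                "clinvar": a.clinvar,
                "in_common_db": a.in_common_db,
            },
        )
        if failed is None:
            passed.append(ac)
    return passed, audit


def flag_chip(
    somatic: Sequence[AnnotatedCandidate],
    matched_tumor_variants: Sequence[VariantRecord] | None,
    af_threshold: float = 0.01,
) -> dict[VariantKey, bool | None]:
    """Advisory clonal-hematopoiesis flag, never a filter.

    A plasma variant is flagged when its family AF is below the threshold AND
    it is absent from the matched tumor; without a tumor sample the flag is
    indeterminate (None). Flagged variants warrant buffy-coat confirmation.
    """
    flags: dict[VariantKey, bool | None] = {}
    tumor_keys = (
        None if matched_tumor_variants is None else {v.key for v in matched_tumor_variants}
    )
    for ac in somatic:
        if tumor_keys is None:
            flags[ac.key] = None
        else:
            flags[ac.key] = (
                ac.candidate.family_af < af_threshold and ac.key not in tumor_keys
            )
    return flags
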