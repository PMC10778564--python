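"""The five-rule somatic filter cascade with its audit trail and the CHIP flag.

Builds a handful of annotated candidates covering each failure mode, applies
the cascade, and prints the first failed rule per rejected candidate. The final
block shows the clonal-hematopoiesis advisory: a sub-1%-AF variant absent from
the matched tumor is flagged for buffy-coat confirmation, never removed.
"""

from panelkit.consensus import VariantCandidate
from panelkit.filters import (
    Annotation,
    AnnotationTable,
    annotate,
    apply_filters,
    flag_chip,
)
from panelkit.panel import VariantRecord


def candidate(pos, fams=25, total=500, reads=40, fwd=22):
    return VariantCandidate(
        variant=VariantRecord(chrom="chr17", pos=pos, ref="C", alt="T", gene="TP53"),
        supporting_reads_total=reads, supporting_reads_forward=fwd,
        supporting_reads_reverse=reads - fwd,
        supporting_families=fams, total_families_at_locus=total,
    )


cases = {
    "pathogenic missense":    (candidate(1001), Annotation(0.0, "missense", "pathogenic")),
    "common germline":        (candidate(1002), Annotation(0.0, "missense", in_common_db=True)),
    "population MAF 0.005":   (candidate(1003), Annotation(0.005, "missense")),
    "synonymous":             (candidate(1004), Annotation(0.0, "synonymous")),
    "likely benign (ClinVar)": (candidate(1005), Annotation(0.0, "missense", "likely_benign")),
    "low-AF, not in tumor":   (candidate(1006, fams=2), Annotation(0.0, "missense", "vus")),
}
table = AnnotationTable({c.variant.key: ann for c, ann in cases.values()})
annotated = annotate([c for c, _ in cases.values()], table)
somatic, audit = apply_filters(annotated)

print(f"{len(somatic)}/{len(annotated)} candidates pass the cascade")
for label, record in zip(cases, audit.records):
    print(f"  {label:24s} -> {record['verdict']:4s} (rule {record['failed_rule']})")

tumor = [cases["pathogenic missense"][0].variant]  # only the first is in tissue
flags = flag_chip(somatic, matched_tumor_variants=tumor)
for ac in somatic:
    print(f"CHIP flag {ac.candidate.variant.chrom}:{ac.candidate.variant.pos} "
          f"(family AF {ac.candidate.family_af:.3f}): {flags[ac.key]}")
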