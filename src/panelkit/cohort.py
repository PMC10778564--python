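"""Cohort-level analyses: tumor-plasma concordance classification, CHAARTED
disease-volume classification, 2x2 contingency construction with Fisher's exact
test, and the correlation / rank-sum / t statistics used on clinical covariates.

Missing clinical values are excluded pairwise per analysis and each result
reports its effective n; no multiple-testing correction is applied (raw
p-values are reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelDesign, PatientRecord, VariantRecord

__all__ = [
    "ConcordanceRecord",
    "ContingencyTable2x2",
    "classify_volume",
    "classify_concordance",
    "concordance_summary",
    "ctdna_positive",
    "build_contingency",
    "fisher_exact_2x2",
    "pearson_corr",
    "wilcoxon_rank_sum",
    "two_sample_t",
    "gene_frequencies",
    "PSA_CUTOFF_NG_ML",
    "LOW_CFDNA_NG",
]

#: PSA grouping cutoff (ng/mL); "normal" is strictly below, so 4.0 goes to high.
PSA_CUTOFF_NG_ML = 4.0
#: Library preparation fails below this cfDNA amount (ng); such patients are
#: excluded from concordance analysis.
LOW_CFDNA_NG = 2.0

ConcordanceCategory = Literal[
    "concordant", "discordant", "no_target_mutation", "excluded_low_cfdna"
]


@dataclass(frozen=True)
class ConcordanceRecord:
    patient_id: str
    category: ConcordanceCategory


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("positive", "negative")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def counts(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def classify_volume(
    bone_met_count: int | None,
    extra_pelvic_or_spine: bool | None,
    visceral: bool | None,
) -> str | None:
    """CHAARTED disease volume: high iff (>= 4 bone metastases with at least one
    outside the pelvis or spine) and/or visceral metastases; low otherwise.
    Missing inputs yield a missing classification."""
    if bone_met_count is None or extra_pelvic_or_spine is None or visceral is None:
        return None
    if visceral or (bone_met_count >= 4 and extra_pelvic_or_spine):
        return "high"
    return "low"


def classify_concordance(patient: PatientRecord, panel: PanelDesign) -> ConcordanceRecord:
    """Patient-level tumor/plasma concordance.

    Excluded when the cfDNA amount is below the library-preparation minimum.
    ``no_target_mutation`` when the tumor carries no variant inside a panel
    region (none found, or found only outside the panel). Otherwise concordant
    iff at least one panel-covered tumor variant also appears in plasma,
    matched on (chrom, pos, ref, alt).
    """
    if patient.tumor_variants is None:
        raise ValueError(
            f"patient {patient.patient_id} has no matched tumor sample; "
            "concordance is defined only for the matched cohort"
        )
    if patient.cfdna_ng_ml is not None and patient.cfdna_ng_ml < LOW_CFDNA_NG:
        return ConcordanceRecord(patient.patient_id, "excluded_low_cfdna")
    in_panel = [v for v in patient.tumor_variants if panel.covers(v.chrom, v.pos)]
    if not in_panel:
        return ConcordanceRecord(patient.patient_id, "no_target_mutation")
    plasma_keys = {v.key for v in patient.plasma_variants}
    if any(v.key in plasma_keys for v in in_panel):
        return ConcordanceRecord(patient.patient_id, "concordant")
    return ConcordanceRecord(patient.patient_id, "discordant")


def concordance_summary(
    records: Sequence[ConcordanceRecord],
    strata: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Tabulate concordance categories (optionally per stratum) and compute the
    corrected concordance rate concordant / (concordant + discordant).

    Returns (table, corrected_rate); the rate is None when no patient carries a
    panel-target tumor mutation. The table also reports the raw rate over the
    whole matched cohort (concordant / all classified patients)."""
    if not records:
        return pd.DataFrame(), None
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "category": [r.category for r in records],
            "stratum": [
                (strata or {}).get(r.patient_id, "all") for r in records
            ],
        }
    )
    table = (
        df.pivot_table(index="stratum", columns="category", values="patient_id",
                       aggfunc="count", fill_value=0)
        .reindex(columns=["concordant", "discordant", "no_target_mutation",
                          "excluded_low_cfdna"], fill_value=0)
    )
    n_conc = int((df["category"] == "concordant").sum())
    n_disc = int((df["category"] == "discordant").sum())
    rate = n_conc / (n_conc + n_disc) if (n_conc + n_disc) else None
    return table, rate


def ctdna_positive(patient: PatientRecord) -> bool:
    """A sample is ctDNA-positive when at least one somatic variant was
    detected in its plasma cfDNA."""
    return len(patient.plasma_variants) > 0


_GROUPERS: dict[str, Callable[[PatientRecord], str | None]] = {
    "treatment": lambda p: None if p.on_therapy is None else ("yes" if p.on_therapy else "no"),
    "hormonal_status": lambda p: p.hormonal_status,
    "volume": lambda p: p.volume,
    "psa_cutoff": lambda p: None if p.psa_ng_ml is None else (
        "normal" if p.psa_ng_ml < PSA_CUTOFF_NG_ML else "high"
    ),
}
_GROUP_LEVELS: dict[str, tuple[str, str]] = {
    "treatment": ("yes", "no"),
    "hormonal_status": ("mCRPC", "mCSPC"),
    "volume": ("high", "low"),
    "psa_cutoff": ("normal", "high"),
}


def build_contingency(
    patients: Sequence[PatientRecord],
    grouping: str,
    positivity: Callable[[PatientRecord], bool] = ctdna_positive,
) -> ContingencyTable2x2:
    """Cross-tabulate a two-level clinical grouping against ctDNA positivity.

    Patients with a missing grouping variable are excluded (the effective n is
    the table total); a group level with no patients is an error."""
    if grouping not in _GROUPERS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {sorted(_GROUPERS)}")
    group_of = _GROUPERS[grouping]
    levels = _GROUP_LEVELS[grouping]
    counts = {lvl: [0, 0] for lvl in levels}
    for p in patients:
        lvl = group_of(p)
        if lvl is None:
            continue
        counts[lvl][0 if positivity(p) else 1] += 1
    for lvl in levels:
        if sum(counts[lvl]) == 0:
            raise ValueError(f"grouping {grouping!r}: level {lvl!r} has no patients")
    (a, b), (c, d) = counts[levels[0]], counts[levels[1]]
    return ContingencyTable2x2(
        a=a, b=b, c=c, d=d, row_labels=levels, col_labels=("ctDNA_positive", "ctDNA_negative")
    )


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p: the hypergeometric mass (margins fixed) of
    all tables at most as probable as the observed one."""
    counts = table.counts if isinstance(table, ContingencyTable2x2) else [list(r) for r in table]
    if sum(counts[0]) + sum(counts[1]) == 0:
        raise ValueError("empty contingency table")
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def _paired_complete(x: Sequence[float | None], y: Sequence[float | None]):
    xa = np.array([np.nan if v is None else v for v in x], dtype=float)
    ya = np.array([np.nan if v is None else v for v in y], dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    return xa[keep], ya[keep]


def pearson_corr(x: Sequence[float | None], y: Sequence[float | None]) -> tuple[float, float, int]:
    """Pearson product-moment correlation with the two-sided t-transform p-value
    (n - 2 degrees of freedom). Pairs with missing values are dropped; returns
    (r, p, effective n)."""
    xa, ya = _paired_complete(x, y)
    n = len(xa)
    if n < 3:
        raise ValueError(f"pearson_corr needs >= 3 complete pairs, got {n}")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p), n


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value with average ranks for ties.

    Exact null enumeration when n_a * n_b <= 10,000 and the data are tie-free;
    otherwise the normal approximation with continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 10_000 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value (Welch-Satterthwaite degrees of freedom).

    When both samples are constant with equal means the p-value is 1 by
    convention (no evidence of a difference is obtainable)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        return 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def gene_frequencies(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-gene mutated-patient counts among ctDNA-positive patients.

    A patient counts once per gene regardless of how many variants they carry
    in it; patients with more than one variant in a gene are flagged multi-hit.
    Fractions are over the ctDNA-positive denominator."""
    positive = [p for p in patients if ctdna_positive(p)]
    if not positive:
        return pd.DataFrame(columns=["gene", "patients", "fraction", "multi_hit_patients"])
    rows: dict[str, dict[str, int]] = {}
    for p in positive:
        per_gene: dict[str, int] = {}
        for v in p.plasma_variants:
            per_gene[v.gene] = per_gene.get(v.gene, 0) + 1
        for gene, n in per_gene.items():
            d = rows.setdefault(gene, {"patients": 0, "multi_hit_patients": 0})
            d["patients"] += 1
            if n > 1:
                d["multi_hit_patients"] += 1
    df = pd.DataFrame(
        [
            {
                "gene": g,
                "patients": d["patients"],
                "fraction": d["patients"] / len(positive),
                "multi_hit_patients": d["multi_hit_patients"],
            }
            for g, d in rows.items()
        ]
    ).sort_values(["patients", "gene"], ascending=[False, True], ignore_index=True)
    return df
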