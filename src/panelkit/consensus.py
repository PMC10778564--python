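"""Molecular-family reconstruction from UMI-tagged reads, library QC, and raw
candidate variant calling under read/strand support rules.

Families are represented as a DataFrame with one row per (amplicon, UMI) pair:

    amplicon_id, umi, strand, size, consensus_allele, consensus_reads, agreement

``size`` is the family's read count, ``consensus_allele`` the majority allele
(ties broken toward the reference when a reference map is supplied, otherwise
toward the lexicographically smallest allele), ``consensus_reads`` the number
of reads matching the consensus and ``agreement`` their fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Locus, PanelDesign, VariantRecord

__all__ = [
    "FAMILY_COLUMNS",
    "LibraryQC",
    "VariantCandidate",
    "group_families",
    "valid_families",
    "sample_qc",
    "call_candidates",
    "theoretical_lod",
]

FAMILY_COLUMNS = (
    "amplicon_id", "umi", "strand", "size", "consensus_allele", "consensus_reads", "agreement",
)


@dataclass
class LibraryQC:
    """Sample-level quality metrics for a molecular-tag library.

    A cfDNA library passes when molecular uniformity exceeds 90% and the median
    reads per functional molecule exceeds 7. Molecular uniformity is the
    fraction of panel amplicons whose molecular coverage (family count) is at
    least 20% of the mean molecular coverage; a functional molecule is any
    family with at least one read.
    """

    molecular_uniformity: float
    median_reads_per_functional_molecule: float
    mean_reads_per_molecule_by_amplicon: dict[str, float]
    average_base_coverage: float
    average_molecular_coverage: float
    passed: bool
    reason: str = ""

    UNIFORMITY_CUTOFF = 0.90
    MEDIAN_READS_CUTOFF = 7.0


@dataclass(frozen=True)
class VariantCandidate:
    """A called non-reference allele with its read/family/strand support."""

    variant: VariantRecord
    supporting_reads_total: int
    supporting_reads_forward: int
    supporting_reads_reverse: int
    supporting_families: int
    total_families_at_locus: int

    def __post_init__(self) -> None:
        if self.supporting_reads_forward + self.supporting_reads_reverse != self.supporting_reads_total:
            raise ValueError("forward + reverse supporting reads must equal total")
        if self.supporting_families > self.total_families_at_locus:
            raise ValueError("supporting families exceed families at locus")

    @property
    def family_af(self) -> float:
        return self.supporting_families / self.total_families_at_locus


def _codes(series: pd.Series) -> tuple[np.ndarray, list]:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return series.cat.codes.to_numpy(), list(series.cat.categories)
    codes, uniques = pd.factorize(series.to_numpy())
    return codes, list(uniques)


def group_families(
    reads: pd.DataFrame, ref_alleles: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse UMI-tagged reads into molecular families.

    One family per distinct (amplicon_id, umi); reads of one family must share
    a strand (the tag marks a single input molecule). ``ref_alleles`` maps
    amplicon_id to its reference base and directs consensus tie-breaking.
    """
    if len(reads) == 0:
        return pd.DataFrame({c: [] for c in FAMILY_COLUMNS})

    amp_codes, amp_labels = _codes(reads["amplicon_id"])
    umi = reads["umi"].to_numpy()
    if not np.issubdtype(umi.dtype, np.integer):
        umi, _ = pd.factorize(umi)
    umi = umi.astype(np.int64)
    al_codes, al_labels = _codes(reads["allele"])
    st_codes, st_labels = _codes(reads["strand"])

    key = amp_codes.astype(np.int64) * (int(umi.max()) + 1) + umi
    if np.any(np.diff(key) < 0):  # generic path: sort reads by family key
        order = np.argsort(key, kind="stable")
        key = key[order]
        amp_codes, al_codes, st_codes, umi = (
            amp_codes[order], al_codes[order], st_codes[order], umi[order],
        )
        orig_index = reads.index.to_numpy()[order]
    else:
        orig_index = reads.index.to_numpy()

    new_fam = np.empty(len(key), dtype=bool)
    new_fam[0] = True
    np.not_equal(key[1:], key[:-1], out=new_fam[1:])
    fam_id = np.cumsum(new_fam) - 1
    n_fam = int(fam_id[-1]) + 1
    starts = np.flatnonzero(new_fam)

    sizes = np.bincount(fam_id, minlength=n_fam)

    n_al = len(al_labels)
    counts = np.bincount(fam_id * n_al + al_codes, minlength=n_fam * n_al).reshape(n_fam, n_al)

    n_st = max(len(st_labels), 1)
    st_counts = np.bincount(fam_id * n_st + st_codes, minlength=n_fam * n_st).reshape(n_fam, n_st)
    if n_st > 1 and np.any((st_counts > 0).sum(axis=1) > 1):
        bad = int(np.flatnonzero((st_counts > 0).sum(axis=1) > 1)[0])
        raise ValueError(
            f"reads of family (amplicon={amp_labels[amp_codes[starts[bad]]]}, "
            f"umi={umi[starts[bad]]}) carry conflicting strands"
        )

    consensus = counts.argmax(axis=1)  # ties -> lowest allele code
    max_counts = counts[np.arange(n_fam), consensus]
    if ref_alleles is not None:
        al_index = {a: i for i, a in enumerate(al_labels)}
        ref_code_of_amp = np.array(
            [al_index.get(ref_alleles.get(a, ""), -1) for a in amp_labels], dtype=np.int64
        )
        fam_ref = ref_code_of_amp[amp_codes[starts]]
        has_ref = fam_ref >= 0
        ref_count = np.where(has_ref, counts[np.arange(n_fam), np.where(has_ref, fam_ref, 0)], -1)
        tie_to_ref = has_ref & (ref_count == max_counts)
        consensus = np.where(tie_to_ref, fam_ref, consensus)
    consensus_reads = counts[np.arange(n_fam), consensus]

    amp_cat = pd.Categorical.from_codes(amp_codes[starts], categories=amp_labels)
    strand_vals = pd.Categorical.from_codes(st_codes[starts], categories=st_labels)
    allele_vals = pd.Categorical.from_codes(consensus, categories=al_labels)
    return pd.DataFrame(
        {
            "amplicon_id": amp_cat,
            "umi": umi[starts],
            "strand": strand_vals,
            "size": sizes,
            "consensus_allele": allele_vals,
            "consensus_reads": consensus_reads,
            "agreement": consensus_reads / sizes,
        },
        index=pd.RangeIndex(n_fam),
    )


def valid_families(
    families: pd.DataFrame, min_mean_reads: float = 8.0
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Keep families of amplicons whose MEAN family size reaches the cutoff.

    An amplicon is valid iff the mean reads per input molecule on that amplicon
    is at least ``min_mean_reads`` (default 8); families on invalid amplicons
    are excluded from calling. Returns (filtered families, per-amplicon map).
    """
    if len(families) == 0:
        return families, {}
    means = families.groupby("amplicon_id", observed=True)["size"].mean()
    validity = {str(a): bool(m >= min_mean_reads) for a, m in means.items()}
    keep = families["amplicon_id"].map(validity).fillna(False).astype(bool)
    return families.loc[keep], validity


def sample_qc(families: pd.DataFrame, panel: PanelDesign) -> LibraryQC:
    """Compute library QC over all families (before amplicon validity filtering)."""
    n_amp = len(panel)
    if len(families) == 0:
        return LibraryQC(
            molecular_uniformity=0.0,
            median_reads_per_functional_molecule=0.0,
            mean_reads_per_molecule_by_amplicon={},
            average_base_coverage=0.0,
            average_molecular_coverage=0.0,
            passed=False,
            reason="no molecular families",
        )
    fam_per_amp = families.groupby("amplicon_id", observed=True).size()
    mol_cov = np.zeros(n_amp)
    for i, amp in enumerate(panel.amplicon_ids):
        mol_cov[i] = fam_per_amp.get(amp, 0)
    mean_mol = mol_cov.mean()
    uniformity = float((mol_cov >= 0.2 * mean_mol).mean())
    median_reads = float(families["size"].median())
    mean_by_amp = {
        str(a): float(m)
        for a, m in families.groupby("amplicon_id", observed=True)["size"].mean().items()
    }
    passed = (
        uniformity > LibraryQC.UNIFORMITY_CUTOFF
        and median_reads > LibraryQC.MEDIAN_READS_CUTOFF
    )
    reason = "" if passed else (
        f"molecular uniformity {uniformity:.3f} (need > {LibraryQC.UNIFORMITY_CUTOFF}) / "
        f"median reads per molecule {median_reads:g} (need > {LibraryQC.MEDIAN_READS_CUTOFF})"
    )
    return LibraryQC(
        molecular_uniformity=uniformity,
        median_reads_per_functional_molecule=median_reads,
        mean_reads_per_molecule_by_amplicon=mean_by_amp,
        average_base_coverage=float(families["size"].sum() / n_amp),
        average_molecular_coverage=float(len(families) / n_amp),
        passed=passed,
        reason=reason,
    )


def call_candidates(
    families: pd.DataFrame,
    loci: Mapping[str, Locus],
    min_reads: int = 3,
    require_both_strands: bool = True,
) -> list[VariantCandidate]:
    """Call non-reference alleles supported by the consensus families.

    An allele is a candidate iff its supporting reads — reads matching the
    allele within families whose consensus IS the allele — total at least
    ``min_reads`` AND (when required) at least one supporting read sits on each
    strand. The candidate AF is family-based: supporting families over all
    families at the locus.
    """
    if len(families) == 0:
        return []
    fams_per_amp = families.groupby("amplicon_id", observed=True).size().to_dict()
    grouped = families.groupby(
        ["amplicon_id", "consensus_allele", "strand"], observed=True
    )["consensus_reads"].agg(["sum", "count"])

    support: dict[tuple[str, str], dict[str, int]] = {}
    for (amp, allele, strand), row in grouped.iterrows():
        locus = loci.get(str(amp))
        if locus is None or str(allele) == locus.ref:
            continue
        d = support.setdefault((str(amp), str(allele)), {"F": 0, "R": 0, "fams": 0})
        d[str(strand)] += int(row["sum"])
        d["fams"] += int(row["count"])

    out: list[VariantCandidate] = []
    for (amp, allele), d in sorted(support.items()):
        total = d["F"] + d["R"]
        if total < min_reads:
            continue
        if require_both_strands and (d["F"] == 0 or d["R"] == 0):
            continue
        locus = loci[amp]
        n_fams_locus = int(fams_per_amp[amp])
        out.append(
            VariantCandidate(
                variant=VariantRecord(
                    chrom=locus.chrom, pos=locus.pos, ref=locus.ref, alt=allele,
                    gene=locus.gene, af=d["fams"] / n_fams_locus,
                ),
                supporting_reads_total=total,
                supporting_reads_forward=d["F"],
                supporting_reads_reverse=d["R"],
                supporting_families=d["fams"],
                total_families_at_locus=n_fams_locus,
            )
        )
    return out


def theoretical_lod(
    mass_ng: float,
    depth: float,
    min_mutant_molecules: int = 6,
    pg_per_haploid_genome: float = 3.3,
) -> float:
    """Theoretical limit of detection in allele fraction.

    The LOD is bounded by whichever is scarcer: input molecules or reads —
    af = max(m / GE(mass), m / depth) for m detectable mutant molecules,
    rounded UP to one significant digit. m defaults to 6, the value at which
    20 ng and 50,000x depth give exactly 0.1%.
    """
    if mass_ng <= 0 or depth <= 0:
        raise ValueError("LOD undefined for zero mass or depth")
    from .simulate import mass_to_genome_equivalents

    ge = mass_to_genome_equivalents(mass_ng, pg_per_haploid_genome)
    if ge == 0:
        raise ValueError("LOD undefined: input mass below one genome equivalent")
    raw = max(min_mutant_molecules / ge, min_mutant_molecules / depth)
    exponent = math.floor(math.log10(raw))
    scale = 10.0 ** exponent
    mantissa = math.ceil(raw / scale - 1e-9)
    return mantissa * scale
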