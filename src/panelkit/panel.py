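"""Panel data model and readers/writers for the external formats the pipeline touches.

Coordinate conventions: BED intervals are 0-based half-open; VCF positions are
1-based. All conversions between the two happen in this module and nowhere else.
"""

from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "Amplicon",
    "PanelDesign",
    "Locus",
    "VariantRecord",
    "AmpliconCoverage",
    "PatientRecord",
    "PanelError",
    "ParseError",
    "PANEL_GENES",
    "replica_panel",
    "locus_map",
    "read_panel_bed",
    "write_panel_bed",
    "read_coverage_csv",
    "write_coverage_csv",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_sample_metadata",
    "write_sample_metadata",
]

#: The 46 genes whose hotspot regions the prostate-cancer cfDNA panel covers.
PANEL_GENES: tuple[str, ...] = (
    "ACVR2A", "AKT1", "APC", "AR", "ASXL1", "ATM", "BRAF", "BRCA1", "BRCA2",
    "CDK12", "CHD1", "CHEK2", "CSMD3", "CTNNB1", "CUL3", "CYP17A1", "CYP19A1",
    "FBXW7", "FOXA1", "HRAS", "HSD17B4", "HSD3B1", "IDH1", "JAK1", "KDM6A",
    "KMT2C", "KRAS", "LHCGR", "MED12", "MGA", "MYC", "NCOR1", "NCOR2",
    "PIK3CA", "PIK3R1", "PTEN", "RB1", "RNF43", "SLCO1B1", "SLCO1B3", "SPOP",
    "TP53", "ZBTB16", "ZFHX3", "ZMYM3", "ZNF780B",
)

_GENE_SYMBOL_RE = re.compile(r"^[A-Za-z0-9._-]+$")

# amplicon size range of the assay (bp)
MIN_AMPLICON_LEN = 75
MAX_AMPLICON_LEN = 140


class PanelError(ValueError):
    """Panel or coverage table violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries the offending location."""


@dataclass(frozen=True)
class Amplicon:
    """One PCR amplicon: a half-open genomic interval tagged with its gene."""

    id: str
    gene: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelError(
                f"amplicon {self.id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise PanelError(f"amplicon {self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PanelDesign:
    """An amplicon panel: the gene/region map every pipeline stage is indexed by."""

    amplicons: tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate amplicon ids: {dupes}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(a.gene for a in self.amplicons)

    @property
    def amplicon_ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def by_gene(self, gene: str) -> tuple[Amplicon, ...]:
        return tuple(a for a in self.amplicons if a.gene == gene)

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)

    def covers(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position falls inside any amplicon."""
        return self.find_amplicon(chrom, pos) is not None

    def find_amplicon(self, chrom: str, pos: int) -> Amplicon | None:
        """Return the amplicon containing a 1-based position, or None."""
        for a in self.amplicons:
            if a.chrom == chrom and a.start < pos <= a.end:
                return a
        return None


@dataclass(frozen=True)
class Locus:
    """The single interrogated position of one amplicon (1-based), with its
    reference base. The simulator and caller operate on one locus per amplicon."""

    amplicon_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with gene/protein annotation and allele fraction."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    protein_change: str = ""
    af: float = 0.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise PanelError(f"variant at {self.chrom}:{self.pos}: ref == alt")
        if not 0.0 <= self.af <= 1.0:
            raise PanelError(f"variant at {self.chrom}:{self.pos}: af {self.af} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Matching key used everywhere variants are compared."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class AmpliconCoverage:
    """Per-amplicon total read counts for one sample."""

    sample_id: str
    rows: dict[str, int]

    def __post_init__(self) -> None:
        for amp_id, n in self.rows.items():
            if n < 0:
                raise PanelError(f"coverage for {amp_id} is negative ({n})")

    def validate_against(self, panel: PanelDesign) -> None:
        panel_ids = set(panel.amplicon_ids)
        unknown = sorted(set(self.rows) - panel_ids)
        if unknown:
            raise PanelError(f"coverage rows for unknown amplicons: {unknown}")
        missing = sorted(panel_ids - set(self.rows))
        if missing:
            raise PanelError(
                f"coverage missing {len(missing)} panel amplicons: {missing}"
            )


@dataclass
class PatientRecord:
    """One patient's clinical covariates plus tumor and plasma variant sets.

    ``tumor_variants`` is None when no matched tissue sample exists (distinct
    from an empty list, which means tissue was sequenced and nothing found).
    Missing clinical values stay None and are never imputed.
    """

    patient_id: str
    hormonal_status: str | None = None  # mCRPC | mCSPC
    psa_ng_ml: float | None = None
    cfdna_ng_ml: float | None = None
    on_therapy: bool | None = None
    volume: str | None = None  # high | low
    bone_met_count: int | None = None
    extra_pelvic_or_spine: bool | None = None
    visceral: bool | None = None
    tumor_variants: list[VariantRecord] | None = None
    plasma_variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hormonal_status not in (None, "mCRPC", "mCSPC"):
            raise ParseError(
                f"patient {self.patient_id}: unknown hormonal_status "
                f"{self.hormonal_status!r}"
            )
        if self.psa_ng_ml is not None and self.psa_ng_ml < 0:
            raise PanelError(f"patient {self.patient_id}: negative PSA")
        if self.cfdna_ng_ml is not None and self.cfdna_ng_ml < 0:
            raise PanelError(f"patient {self.patient_id}: negative cfDNA amount")


# ---------------------------------------------------------------------------
# Replica panel
# ---------------------------------------------------------------------------

def _det_int(token: str, modulus: int) -> int:
    """Stable pseudo-random integer from a string (CRC32, not Python hash)."""
    return zlib.crc32(token.encode()) % modulus


def replica_panel() -> PanelDesign:
    """Deterministically build the 273-amplicon, 46-gene panel replica.

    Coordinates are invented (the assay's designs are proprietary); the gene
    list, amplicon count and the 75-140 bp size range match the assay. AR gets
    8 amplicons so the copy-number ratio has a multi-amplicon target block; the
    remaining 265 are spread round-robin over the other 45 genes.
    """
    others = sorted(g for g in PANEL_GENES if g != "AR")
    counts = {"AR": 8}
    for i, g in enumerate(others):
        counts[g] = 6 if i < 40 else 5  # 40*6 + 5*5 = 265
    amplicons: list[Amplicon] = []
    gene_order = ["AR"] + others
    for gi, gene in enumerate(gene_order):
        chrom = "chrX" if gene == "AR" else f"chr{(gi % 22) + 1}"
        base = 1_000_000 * (gi + 1)
        for j in range(counts[gene]):
            amp_id = f"{gene}_{j + 1:03d}"
            length = MIN_AMPLICON_LEN + _det_int(amp_id, MAX_AMPLICON_LEN - MIN_AMPLICON_LEN + 1)
            start = base + j * 500
            amplicons.append(
                Amplicon(id=amp_id, gene=gene, chrom=chrom, start=start, end=start + length)
            )
    panel = PanelDesign(tuple(amplicons))
    assert len(panel) == 273 and len(panel.genes) == 46
    return panel


def locus_map(panel: PanelDesign) -> dict[str, Locus]:
    """One interrogated locus per amplicon: the interval midpoint, with a
    deterministic reference base derived from the amplicon id."""
    loci = {}
    for a in panel.amplicons:
        pos = a.start + a.length // 2 + 1  # 1-based midpoint
        ref = "ACGT"[_det_int(a.id + "/ref", 4)]
        loci[a.id] = Locus(amplicon_id=a.id, gene=a.gene, chrom=a.chrom, pos=pos, ref=ref)
    return loci


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_panel_bed(path: str | Path) -> PanelDesign:
    """Read a 6-column BED (name encodes ``gene|amplicon_id``) into a panel."""
    amplicons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if "|" not in name:
                raise ParseError(f"{path}:{lineno}: name must encode 'gene|amplicon_id'")
            gene, amp_id = name.split("|", 1)
            try:
                amplicons.append(
                    Amplicon(id=amp_id, gene=gene, chrom=chrom, start=start, end=end, strand=strand)
                )
            except PanelError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PanelDesign(tuple(amplicons))


def write_panel_bed(panel: PanelDesign, path: str | Path) -> None:
    """Write a panel as 6-column BED; inverse of :func:`read_panel_bed`."""
    for a in panel.amplicons:
        for token in (a.gene, a.id):
            if not _GENE_SYMBOL_RE.match(token):
                raise PanelError(f"symbol {token!r} outside the allowed charset")
    with open(path, "w") as fh:
        for a in panel.amplicons:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene}|{a.id}\t0\t{a.strand}\n")


# ---------------------------------------------------------------------------
# Coverage CSV
# ---------------------------------------------------------------------------

def read_coverage_csv(path: str | Path, panel: PanelDesign, sample_id: str | None = None) -> AmpliconCoverage:
    """Read an amplicon read-count table (columns amplicon_id,gene,total_reads).

    Every panel amplicon must appear exactly once; unknown amplicons, duplicate
    rows, negative counts and missing amplicons are all reported as errors.
    """
    df = pd.read_csv(path)
    required = {"amplicon_id", "gene", "total_reads"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: coverage CSV needs columns {sorted(required)}")
    if df["amplicon_id"].duplicated().any():
        dupes = sorted(df.loc[df["amplicon_id"].duplicated(), "amplicon_id"])
        raise PanelError(f"duplicate coverage rows for: {dupes}")
    cov = AmpliconCoverage(
        sample_id=sample_id or Path(path).stem,
        rows={str(r.amplicon_id): int(r.total_reads) for r in df.itertuples()},
    )
    cov.validate_against(panel)
    return cov


def write_coverage_csv(cov: AmpliconCoverage, panel: PanelDesign, path: str | Path) -> None:
    gene_of = {a.id: a.gene for a in panel.amplicons}
    df = pd.DataFrame(
        {
            "amplicon_id": list(cov.rows),
            "gene": [gene_of[i] for i in cov.rows],
            "total_reads": list(cov.rows.values()),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_LINES = (
    ('AF', '1', 'Float', 'Alternate allele fraction (molecular-family space)'),
    ('GENE', '1', 'String', 'Gene symbol'),
    ('PCHANGE', '1', 'String', 'Protein change, e.g. p.T878A; a dot when unknown'),
)


def write_variants_vcf(variants: Sequence[VariantRecord], path: str | Path) -> None:
    """Write variants as VCF 4.2 with AF/GENE/PCHANGE INFO keys."""
    header = pysam.VariantHeader()
    for name, number, vtype, desc in _INFO_LINES:
        header.add_line(f'##INFO=<ID={name},Number={number},Type={vtype},Description="{desc}">')
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.add_line(f"##contig=<ID={chrom}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["AF"] = float(v.af)
            rec.info["GENE"] = v.gene or "."
            rec.info["PCHANGE"] = v.protein_change or "."
            out.write(rec)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF written by :func:`write_variants_vcf` (or equivalent)."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for key in ("AF", "GENE", "PCHANGE"):
                if key not in rec.info:
                    raise ParseError(
                        f"{path}: record {rec.contig}:{rec.pos} missing INFO/{key}"
                    )
            # htslib stores Float INFO as float32; renormalize to 6 significant
            # digits so written values round-trip exactly.
            af = float(f"{float(rec.info['AF']):.6g}")
            gene = str(rec.info["GENE"])
            pchange = str(rec.info["PCHANGE"])
            out.append(
                VariantRecord(
                    chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                    gene="" if gene == "." else gene,
                    protein_change="" if pchange == "." else pchange,
                    af=af,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Sample metadata TSV
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = (
    "patient_id", "hormonal_status", "psa_ng_ml", "cfdna_ng_ml", "on_therapy",
    "volume", "bone_met_count", "extra_pelvic_or_spine", "visceral",
)


def _parse_flag(token: str, where: str) -> bool | None:
    if token == "":
        return None
    if token in ("yes", "no"):
        return token == "yes"
    raise ParseError(f"{where}: flag must be yes/no/empty, got {token!r}")


def read_sample_metadata(path: str | Path) -> list[PatientRecord]:
    """Read a cohort metadata TSV. Empty cells become None (never imputed)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(_METADATA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise ParseError(f"{path}: duplicated patient_id: {dupes}")
    records = []
    for row in df.itertuples():
        where = f"{path} patient {row.patient_id}"
        status = row.hormonal_status or None
        if status not in (None, "mCRPC", "mCSPC"):
            raise ParseError(f"{where}: unknown hormonal_status {status!r}")
        vol = row.volume or None
        if vol not in (None, "high", "low"):
            raise ParseError(f"{where}: volume must be high/low/empty")
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                hormonal_status=status,
                psa_ng_ml=float(row.psa_ng_ml) if row.psa_ng_ml else None,
                cfdna_ng_ml=float(row.cfdna_ng_ml) if row.cfdna_ng_ml else None,
                on_therapy=_parse_flag(row.on_therapy, where),
                volume=vol,
                bone_met_count=int(row.bone_met_count) if row.bone_met_count else None,
                extra_pelvic_or_spine=_parse_flag(row.extra_pelvic_or_spine, where),
                visceral=_parse_flag(row.visceral, where),
            )
        )
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_sample_metadata(patients: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_METADATA_COLUMNS) + "\n")
        for p in patients:
            fh.write(
                "\t".join(
                    _fmt(getattr(p, col)) for col in _METADATA_COLUMNS
                )
                + "\n"
            )
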