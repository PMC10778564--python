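"""Panel-based gene copy-number statistic: the median (and mean) coverage ratio
of a target gene's amplicons versus all other amplicons, a threshold calibrated
on a spike-in reference set, and amplification calls.

The statistic deliberately uses raw per-amplicon total read counts with no
GC or length normalization — the calibrated threshold is defined on raw ratios.
Gene losses are out of scope: the panel is too small to resolve them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import AmpliconCoverage, PanelDesign

__all__ = [
    "RatioResult",
    "CnvThreshold",
    "CnvCall",
    "gene_ratio",
    "calibrate_threshold",
    "call_amplification",
]


@dataclass(frozen=True)
class RatioResult:
    """Target-vs-background coverage summary for one sample and gene."""

    sample_id: str
    gene: str
    median_target: float
    median_background: float
    mean_target: float
    mean_background: float

    @property
    def ratio_median(self) -> float:
        return self.median_target / self.median_background

    @property
    def ratio_mean(self) -> float:
        return self.mean_target / self.mean_background


@dataclass(frozen=True)
class CnvThreshold:
    """Calibrated minimum gain threshold with its derivation trail."""

    value: float
    positives: tuple[float, ...] = ()
    negatives: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.value < 1:
            raise ValueError("CNV gain threshold must be >= 1")


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    gene: str
    ratio_median: float
    ratio_mean: float
    threshold: float
    amplified: bool
    amplified_by_mean: bool

    @property
    def median_mean_agree(self) -> bool:
        return self.amplified == self.amplified_by_mean


def gene_ratio(coverage: AmpliconCoverage, panel: PanelDesign, gene: str = "AR") -> RatioResult:
    """Median and mean total reads of the gene's amplicons vs all others."""
    if gene not in panel.genes:
        raise ValueError(f"gene {gene!r} not on the panel")
    coverage.validate_against(panel)
    target = np.array([coverage.rows[a.id] for a in panel.amplicons if a.gene == gene], dtype=float)
    background = np.array(
        [coverage.rows[a.id] for a in panel.amplicons if a.gene != gene], dtype=float
    )
    if background.size == 0:
        raise ValueError("no background amplicons")
    med_bg = float(np.median(background))
    mean_bg = float(background.mean())
    if med_bg == 0 or mean_bg == 0:
        raise ZeroDivisionError("background coverage median/mean is zero; ratio undefined")
    return RatioResult(
        sample_id=coverage.sample_id,
        gene=gene,
        median_target=float(np.median(target)),
        median_background=med_bg,
        mean_target=float(target.mean()),
        mean_background=mean_bg,
    )


def _floor_one_significant(x: float) -> float:
    """Round down to one significant digit (2.15 -> 2.0, 0.37 -> 0.3)."""
    if x <= 0:
        raise ValueError("requires a positive value")
    exponent = math.floor(math.log10(x))
    scale = 10.0 ** exponent
    return math.floor(x / scale + 1e-9) * scale


def calibrate_threshold(
    positives: Sequence[float], negatives: Sequence[float]
) -> CnvThreshold:
    """Derive the minimum gain threshold from a reference set.

    The threshold is the smallest amplification-positive ratio rounded down to
    one significant digit, and must strictly exceed every negative-reference
    ratio; overlap between the sets is a calibration failure.
    """
    if not positives:
        raise ValueError("calibration needs at least one amplification-positive ratio")
    if negatives and max(negatives) >= min(positives):
        raise ValueError(
            f"calibration failure: max negative ratio {max(negatives):g} >= "
            f"min positive ratio {min(positives):g}"
        )
    value = _floor_one_significant(min(positives))
    if negatives and value <= max(negatives):
        raise ValueError(
            f"calibration failure: rounded threshold {value:g} does not strictly "
            f"exceed max negative ratio {max(negatives):g}"
        )
    return CnvThreshold(value=value, positives=tuple(positives), negatives=tuple(negatives))


def call_amplification(ratio: RatioResult, threshold: CnvThreshold | float) -> CnvCall:
    """Call amplification when the median-based ratio is at least the threshold.

    The boundary is inclusive: the defining positive standard sits exactly at
    the rounded threshold. The mean-based call is computed alongside and any
    disagreement is surfaced on the returned call, not silently resolved.
    """
    t = threshold.value if isinstance(threshold, CnvThreshold) else float(threshold)
    return CnvCall(
        sample_id=ratio.sample_id,
        gene=ratio.gene,
        ratio_median=ratio.ratio_median,
        ratio_mean=ratio.ratio_mean,
        threshold=t,
        amplified=ratio.ratio_median >= t,
        amplified_by_mean=ratio.ratio_mean >= t,
    )
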