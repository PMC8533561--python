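"""Per-call and per-sample quality metrics for liquid-biopsy variant calls.

Three quantities drive the downstream concordance analysis:

* **VAF** (variant allele fraction, percent) — mutant molecules over total
  molecules at a locus, from digital-PCR copy readouts or NGS allele counts.
* **MAPD** — the median of the absolute values of all pairwise differences
  of log2 coverage ratios between genomically adjacent amplicons; a
  per-sample estimate of coverage noise on amplicon panels. Vendor pipelines
  flag runs with MAPD above 0.5 for manual review.
* **R-score** — ``log10(MAPD / VAF)``, a single per-call quality index:
  high values mean a noisy run and/or a low-frequency variant, i.e. a call
  that deserves less trust.

All logarithms on the VAF/MAPD scale are base 10; coverage ratios are
base 2, matching the conventions of the copy-number literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "DpcrReadout",
    "NgsAlleleCount",
    "Amplicon",
    "AmpliconCoverage",
    "Log2RatioProfile",
    "QualityMetrics",
    "MAPD_REVIEW_THRESHOLD",
    "compute_vaf_dpcr",
    "compute_vaf_ngs",
    "compute_log2_ratios",
    "compute_mapd",
    "compute_rscore",
    "classify_mapd",
    "compute_quality_metrics",
]

#: Vendor default: a sample with MAPD strictly above this is flagged for review.
MAPD_REVIEW_THRESHOLD = 0.5


@dataclass(frozen=True)
class DpcrReadout:
    """Digital-PCR copy readout for one assay in one sample.

    FAM fluorescence counts mutant template copies, VIC counts wild-type
    copies; both are absolute concentrations in copies/µL.
    """

    fam_copies_per_ul: float
    vic_copies_per_ul: float

    def __post_init__(self) -> None:
        if self.fam_copies_per_ul < 0 or self.vic_copies_per_ul < 0:
            raise ValidationError(
                "dPCR copy concentrations must be non-negative, got "
                f"FAM={self.fam_copies_per_ul}, VIC={self.vic_copies_per_ul}"
            )


@dataclass(frozen=True)
class NgsAlleleCount:
    """Molecule counts at one locus from an NGS run (mutant vs total)."""

    mutant_molecules: int
    total_molecules: int

    def __post_init__(self) -> None:
        if self.mutant_molecules < 0:
            raise ValidationError("mutant_molecules must be >= 0")
        if self.mutant_molecules > self.total_molecules:
            raise ValidationError(
                f"mutant_molecules ({self.mutant_molecules}) exceeds "
                f"total_molecules ({self.total_molecules})"
            )


@dataclass(frozen=True)
class Amplicon:
    """One amplicon's coverage record. ``start`` is 0-based."""

    amplicon_id: str
    chrom: str
    start: int
    read_count: int


@dataclass
class AmpliconCoverage:
    """Ordered per-amplicon read counts for one sample run.

    Amplicons must be strictly increasing by start within each chromosome;
    adjacency (for MAPD) is defined only between consecutive amplicons on
    the same chromosome.
    """

    amplicons: list[Amplicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        for a in self.amplicons:
            if a.start < 0 or a.read_count < 0:
                raise ValidationError(
                    f"amplicon {a.amplicon_id}: start and read_count must be >= 0"
                )
            if a.chrom in prev and a.start <= prev[a.chrom]:
                raise ValidationError(
                    f"amplicons on {a.chrom} not strictly increasing by start "
                    f"(at {a.amplicon_id})"
                )
            prev[a.chrom] = a.start

    def __len__(self) -> int:
        return len(self.amplicons)

    @property
    def read_counts(self) -> np.ndarray:
        return np.array([a.read_count for a in self.amplicons], dtype=float)


@dataclass
class Log2RatioProfile:
    """Per-amplicon log2 read-count ratios against a baseline, in panel order."""

    amplicon_ids: list[str]
    chroms: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("log2 ratios must all be finite")


@dataclass(frozen=True)
class QualityMetrics:
    """Bundle of the three per-call metrics plus the MAPD review flag.

    ``r_score`` is None when undefined (VAF or MAPD non-positive, e.g. the
    variant was not detected); it is never imputed.
    """

    vaf_percent: float
    mapd: float
    r_score: float | None
    mapd_flag: str


def compute_vaf_dpcr(readout: DpcrReadout) -> float:
    """VAF in percent from a dPCR readout: 100 * FAM / (FAM + VIC)."""
    total = readout.fam_copies_per_ul + readout.vic_copies_per_ul
    if total <= 0:
        raise UndefinedMetricError(
            "VAF undefined: no template detected (FAM + VIC = 0)"
        )
    return 100.0 * readout.fam_copies_per_ul / total


def compute_vaf_ngs(count: NgsAlleleCount) -> float:
    """VAF in percent from NGS molecule counts: 100 * mutant / total."""
    if count.total_molecules <= 0:
        raise UndefinedMetricError("VAF undefined: zero total molecules")
    return 100.0 * count.mutant_molecules / count.total_molecules


def compute_log2_ratios(
    coverage: AmpliconCoverage,
    pseudocount: float = 0.5,
    baseline: Mapping[str, float] | Sequence[float] | None = None,
) -> Log2RatioProfile:
    """Log2 read-count ratios per amplicon against a reference baseline.

    By default the baseline is the per-sample median of the pseudocounted
    read counts, so the profile is centred on the sample's own typical
    coverage. A per-amplicon baseline (sequence in panel order, or a
    mapping from amplicon id) can be supplied instead, e.g. from a panel
    of normal samples. The pseudocount keeps ratios finite for
    zero-coverage amplicons.
    """
    if len(coverage) == 0:
        raise UndefinedMetricError("cannot compute log2 ratios of empty coverage")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    counts = coverage.read_counts + pseudocount
    if not np.any(counts > 0):
        raise UndefinedMetricError("all pseudocounted read counts are zero")

    if baseline is None:
        base = np.full(len(counts), np.median(counts))
    elif isinstance(baseline, Mapping):
        try:
            base = np.array(
                [baseline[a.amplicon_id] for a in coverage.amplicons], dtype=float
            )
        except KeyError as exc:
            raise ValidationError(f"baseline missing amplicon {exc}") from exc
    else:
        base = np.asarray(baseline, dtype=float)
        if base.shape != counts.shape:
            raise ValidationError(
                f"baseline length {base.size} != number of amplicons {counts.size}"
            )
    if np.any(base <= 0):
        raise ValidationError("baseline values must be positive")

    return Log2RatioProfile(
        amplicon_ids=[a.amplicon_id for a in coverage.amplicons],
        chroms=[a.chrom for a in coverage.amplicons],
        values=np.log2(counts / base),
    )


def compute_mapd(profile: Log2RatioProfile) -> float:
    """MAPD: median absolute difference between adjacent log2 ratios.

    Adjacency is between consecutive amplicons on the same chromosome in
    coordinate order; pairs spanning a chromosome boundary are excluded.
    With an even number of pairs the median is the mean of the two central
    values.
    """
    diffs: list[np.ndarray] = []
    chroms = np.asarray(profile.chroms)
    for chrom in dict.fromkeys(profile.chroms):  # preserves first-seen order
        x = profile.values[chroms == chrom]
        if x.size >= 2:
            diffs.append(np.abs(np.diff(x)))
    if not diffs:
        raise UndefinedMetricError(
            "MAPD undefined: no within-chromosome adjacent amplicon pair"
        )
    return float(np.median(np.concatenate(diffs)))


def compute_rscore(mapd: float, vaf_percent: float) -> float:
    """R-score = log10(MAPD / VAF), with VAF expressed in percent.

    Undefined (raises) when either argument is non-positive — a VAF of
    zero is a non-detection, a MAPD of zero a degenerate noise estimate.
    """
    if mapd <= 0 or vaf_percent <= 0:
        raise UndefinedMetricError(
            f"R-score undefined for MAPD={mapd}, VAF={vaf_percent}%"
        )
    return math.log10(mapd / vaf_percent)


def classify_mapd(mapd: float, threshold: float = MAPD_REVIEW_THRESHOLD) -> str:
    """Return ``"review"`` if MAPD strictly exceeds the threshold, else ``"pass"``.

    Equality passes: a run at exactly the threshold is not flagged.
    """
    if mapd < 0:
        raise ValidationError(f"MAPD must be >= 0, got {mapd}")
    return "review" if mapd > threshold else "pass"


def compute_quality_metrics(
    vaf_percent: float,
    mapd: float,
    threshold: float = MAPD_REVIEW_THRESHOLD,
) -> QualityMetrics:
    """Assemble VAF, MAPD, R-score and the review flag for one call."""
    r: float | None
    try:
        r = compute_rscore(mapd, vaf_percent)
    except UndefinedMetricError:
        r = None
    return QualityMetrics(
        vaf_percent=vaf_percent,
        mapd=mapd,
        r_score=r,
        mapd_flag=classify_mapd(mapd, threshold),
    )
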