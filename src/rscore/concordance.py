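"""Cross-platform agreement statistics for reference-positive variant calls.

The unit of analysis is one mutation in one sample, called positive by a
reference platform (digital PCR, or the MAPD-bearing NGS platform when two
NGS assays are compared) and either confirmed or missed by a comparison
platform. On that set we compute:

* **PPA** (positive percent agreement) with exact Clopper–Pearson or Wald
  confidence intervals,
* a **quadrant analysis** splitting calls by log10(VAF) and log10(MAPD)
  cutpoints,
* a **cutoff sweep** of PPA over R-score thresholds, with the Spearman
  correlation between cutoff and PPA,
* rank-sum comparisons of VAF / MAPD / R-score between concordant and
  discordant calls, and Spearman correlation of VAFs across platforms.

Negative agreement is out of scope: every record is reference-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import EmptyResultError, UndefinedMetricError, ValidationError
from .metrics import compute_rscore

__all__ = [
    "VariantCall",
    "PairedCallRecord",
    "PPAEstimate",
    "QuadrantResult",
    "SweepResult",
    "RankSumResult",
    "DEFAULT_SWEEP_CUTOFFS",
    "match_calls",
    "compute_ppa",
    "quadrant_analysis",
    "rscore_cutoff_sweep",
    "compare_groups",
    "correlate_vaf",
]

#: R-score thresholds conventionally swept when assessing call reliability.
DEFAULT_SWEEP_CUTOFFS: tuple[float, ...] = (-1.25, -1.0, -0.75, -0.5, -0.25, 0.0, 0.25)


@dataclass
class VariantCall:
    """One platform's call of one variant in one sample.

    ``variant_id`` is the specific variant (gene + HGVS where known);
    ``variant_class`` is the assay-level label (e.g. "ex19del", "L858R",
    "T790M") — class-level assays such as dPCR deletion screens report only
    the latter. ``mapd`` is the per-sample run noise of the platform, if it
    reports one; it is defined even for non-detections.
    """

    sample_id: str
    variant_id: str
    variant_class: str
    platform: str
    detected: bool
    vaf_percent: float | None = None
    mapd: float | None = None
    gene: str = "EGFR"

    def __post_init__(self) -> None:
        if not self.detected and self.vaf_percent not in (None, 0, 0.0):
            raise ValidationError(
                f"{self.sample_id}/{self.variant_id}: undetected call cannot "
                f"carry a positive VAF ({self.vaf_percent})"
            )
        if self.vaf_percent is not None and not 0 <= self.vaf_percent <= 100:
            raise ValidationError(
                f"{self.sample_id}/{self.variant_id}: VAF {self.vaf_percent} "
                "outside [0, 100]"
            )
        if self.mapd is not None and self.mapd < 0:
            raise ValidationError(
                f"{self.sample_id}/{self.variant_id}: negative MAPD {self.mapd}"
            )


@dataclass
class PairedCallRecord:
    """A reference-positive call with the comparison platform's verdict.

    ``r_score`` is log10(MAPD / reference VAF): the reference platform's
    quantification is the trusted one and is defined whether or not the
    comparison platform detected the variant, so concordant and discordant
    records are scored on the same footing. ``comparison_vaf_percent`` is
    kept alongside for cross-platform correlation.
    """

    sample_id: str
    variant_class: str
    reference_platform: str
    comparison_platform: str
    reference_vaf_percent: float
    comparison_detected: bool
    comparison_vaf_percent: float | None = None
    mapd: float | None = None
    r_score: float | None = None

    @property
    def concordant(self) -> bool:
        return self.comparison_detected


@dataclass(frozen=True)
class PPAEstimate:
    """PPA point estimate with its counts and confidence interval."""

    n_concordant: int
    n_discordant: int
    ppa_percent: float
    ci_low_percent: float
    ci_high_percent: float
    ci_method: str
    alpha: float = 0.05

    @property
    def n_total(self) -> int:
        return self.n_concordant + self.n_discordant


@dataclass
class QuadrantResult:
    """PPA in each of four quadrants of the (log10 VAF, log10 MAPD) plane.

    Quadrants are keyed ``(vaf_side, mapd_side)`` with sides "low"
    (value <= cut) and "high" (value > cut). Empty quadrants map to None.
    """

    vaf_cut_log10: float
    mapd_cut_log10: float
    quadrants: dict[tuple[str, str], PPAEstimate | None]
    n_records: int
    n_excluded: int


@dataclass
class SweepResult:
    """PPA restricted to records with R-score <= each cutoff.

    ``correlation_r``/``correlation_p`` give the Spearman correlation of the
    defined PPA point estimates against their cutoffs; both are None when
    fewer than three cutoffs yield a defined PPA or the PPAs are constant.
    """

    cutoffs: list[float]
    ppa_at_cutoff: list[PPAEstimate | None]
    correlation_r: float | None
    correlation_p: float | None
    n_excluded_undefined_rscore: int


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Mann–Whitney U test result."""

    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


def _check_duplicates(calls: Iterable[VariantCall], key) -> None:
    seen: dict[tuple, VariantCall] = {}
    dups = []
    for c in calls:
        k = key(c)
        if k in seen:
            dups.append(k)
        seen[k] = c
    if dups:
        raise ValidationError(f"duplicate calls for (sample, variant): {sorted(set(dups))}")


def _match_key(call: VariantCall, level: str) -> tuple[str, str]:
    if level == "exact_variant":
        return (call.sample_id, call.variant_id)
    if level == "variant_class":
        return (call.sample_id, call.variant_class)
    # auto: class-level for exon 19 deletions (assays target the class, not
    # one specific deletion), exact variant otherwise
    if level == "auto":
        if call.variant_class.lower().startswith("ex19del"):
            return (call.sample_id, call.variant_class)
        return (call.sample_id, call.variant_id)
    raise ValidationError(
        f"unknown match level {level!r}; use exact_variant, variant_class or auto"
    )


def match_calls(
    reference_calls: Sequence[VariantCall],
    comparison_calls: Sequence[VariantCall],
    level: str = "auto",
) -> list[PairedCallRecord]:
    """Pair each reference-positive call with the comparison platform's call.

    One record per reference call; the record is concordant iff a detected
    comparison call matches on sample and (per ``level``) variant or variant
    class. The record carries the comparison run's MAPD where available
    (falling back on the reference run's), and the R-score computed from
    that MAPD and the reference VAF.
    """
    for c in reference_calls:
        if not c.detected or not c.vaf_percent or c.vaf_percent <= 0:
            raise ValidationError(
                f"reference call {c.sample_id}/{c.variant_id} is not a "
                "detected positive with VAF > 0"
            )
    _check_duplicates(reference_calls, lambda c: _match_key(c, level))
    _check_duplicates(comparison_calls, lambda c: _match_key(c, level))

    cmp_by_key = {_match_key(c, level): c for c in comparison_calls}
    # per-sample run MAPD of the comparison platform (same for all calls in a run)
    cmp_sample_mapd: dict[str, float] = {}
    for c in comparison_calls:
        if c.mapd is not None:
            cmp_sample_mapd[c.sample_id] = c.mapd

    records = []
    for ref in reference_calls:
        cmp = cmp_by_key.get(_match_key(ref, level))
        detected = cmp is not None and cmp.detected
        mapd = None
        if cmp is not None and cmp.mapd is not None:
            mapd = cmp.mapd
        elif ref.sample_id in cmp_sample_mapd:
            mapd = cmp_sample_mapd[ref.sample_id]
        elif ref.mapd is not None:
            mapd = ref.mapd
        r = None
        if mapd is not None:
            try:
                r = compute_rscore(mapd, ref.vaf_percent)
            except UndefinedMetricError:
                r = None
        records.append(
            PairedCallRecord(
                sample_id=ref.sample_id,
                variant_class=ref.variant_class,
                reference_platform=ref.platform,
                comparison_platform=cmp.platform
                if cmp is not None
                else (comparison_calls[0].platform if comparison_calls else "comparison"),
                reference_vaf_percent=ref.vaf_percent,
                comparison_detected=detected,
                comparison_vaf_percent=cmp.vaf_percent if detected else None,
                mapd=mapd,
                r_score=r,
            )
        )
    return records


def compute_ppa(
    n_concordant: int,
    n_discordant: int,
    ci_method: str = "clopper_pearson",
    alpha: float = 0.05,
) -> PPAEstimate:
    """Positive percent agreement with a two-sided confidence interval.

    PPA = 100 * concordant / (concordant + discordant). The default CI is
    the exact Clopper–Pearson interval; ``ci_method="wald"`` gives the
    normal approximation.
    """
    if n_concordant < 0 or n_discordant < 0:
        raise ValidationError("counts must be non-negative")
    n = n_concordant + n_discordant
    if n == 0:
        raise UndefinedMetricError("PPA undefined: no reference-positive calls")
    methods = {"clopper_pearson": "beta", "wald": "normal"}
    if ci_method not in methods:
        raise ValidationError(
            f"unknown ci_method {ci_method!r}; use clopper_pearson or wald"
        )
    low, high = proportion_confint(n_concordant, n, alpha=alpha, method=methods[ci_method])
    return PPAEstimate(
        n_concordant=n_concordant,
        n_discordant=n_discordant,
        ppa_percent=100.0 * n_concordant / n,
        ci_low_percent=100.0 * float(low),
        ci_high_percent=100.0 * float(high),
        ci_method=ci_method,
        alpha=alpha,
    )


def _ppa_of(records: Sequence[PairedCallRecord], ci_method: str, alpha: float) -> PPAEstimate:
    c = sum(r.concordant for r in records)
    return compute_ppa(c, len(records) - c, ci_method=ci_method, alpha=alpha)


def quadrant_analysis(
    records: Sequence[PairedCallRecord],
    vaf_cut_log10: float | None = None,
    mapd_cut_log10: float | None = None,
    ci_method: str = "clopper_pearson",
    alpha: float = 0.05,
) -> QuadrantResult:
    """PPA within the four quadrants of the (log10 VAF, log10 MAPD) plane.

    Cutpoints default to the log10 medians of the data (reference VAF and
    MAPD over the eligible records). Records on a boundary go to the "low"
    side (value <= cut). Records missing MAPD or with VAF <= 0 are excluded
    and counted.
    """
    eligible = [
        r for r in records if r.mapd is not None and r.mapd > 0 and r.reference_vaf_percent > 0
    ]
    if not eligible:
        raise EmptyResultError("quadrant analysis: no record has both VAF and MAPD")
    log_vaf = np.log10([r.reference_vaf_percent for r in eligible])
    log_mapd = np.log10([r.mapd for r in eligible])
    if vaf_cut_log10 is None:
        vaf_cut_log10 = float(np.median(log_vaf))
    if mapd_cut_log10 is None:
        mapd_cut_log10 = float(np.median(log_mapd))

    quadrants: dict[tuple[str, str], list[PairedCallRecord]] = {
        (v, m): [] for v in ("low", "high") for m in ("low", "high")
    }
    for r, lv, lm in zip(eligible, log_vaf, log_mapd):
        v_side = "low" if lv <= vaf_cut_log10 else "high"
        m_side = "low" if lm <= mapd_cut_log10 else "high"
        quadrants[(v_side, m_side)].append(r)

    return QuadrantResult(
        vaf_cut_log10=vaf_cut_log10,
        mapd_cut_log10=mapd_cut_log10,
        quadrants={
            k: (_ppa_of(v, ci_method, alpha) if v else None) for k, v in quadrants.items()
        },
        n_records=len(eligible),
        n_excluded=len(records) - len(eligible),
    )


def rscore_cutoff_sweep(
    records: Sequence[PairedCallRecord],
    cutoffs: Sequence[float] = DEFAULT_SWEEP_CUTOFFS,
    ci_method: str = "clopper_pearson",
    alpha: float = 0.05,
) -> SweepResult:
    """PPA over records with R-score <= cutoff, for each cutoff in turn.

    Comparisons are inclusive on the low side (<=). Records with an
    undefined R-score are excluded from every subset and counted. Cutoffs
    whose subset is empty get a None PPA and are dropped from the Spearman
    correlation between cutoff value and PPA point estimate.
    """
    if not cutoffs:
        raise ValidationError("cutoffs must be non-empty")
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValidationError("cutoffs must be strictly increasing")
    scored = [r for r in records if r.r_score is not None]
    ppa_list: list[PPAEstimate | None] = []
    for t in cutoffs:
        subset = [r for r in scored if r.r_score <= t]
        ppa_list.append(_ppa_of(subset, ci_method, alpha) if subset else None)

    defined = [(t, p.ppa_percent) for t, p in zip(cutoffs, ppa_list) if p is not None]
    corr_r = corr_p = None
    if len(defined) >= 3:
        ts, ps = zip(*defined)
        if len(set(ps)) > 1:  # constant PPA -> correlation undefined
            res = stats.spearmanr(ts, ps)
            corr_r, corr_p = float(res.statistic), float(res.pvalue)
    return SweepResult(
        cutoffs=cutoffs,
        ppa_at_cutoff=ppa_list,
        correlation_r=corr_r,
        correlation_p=corr_p,
        n_excluded_undefined_rscore=len(records) - len(scored),
    )


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> RankSumResult:
    """Two-sided Mann–Whitney U test between two groups of values.

    Used to compare VAF, MAPD or R-score between concordant and discordant
    calls. Small untied samples (both n <= 20) are tested exactly by
    enumeration; otherwise the tie-corrected normal approximation is used
    (no continuity correction, so identical groups give p = 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    if np.all(combined == combined[0]):
        # every value tied: no ordering information at all
        return RankSumResult(a.size * b.size / 2.0, 1.0, a.size, b.size, "degenerate")
    if not has_ties and a.size <= 20 and b.size <= 20:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "asymptotic"
    return RankSumResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), a.size, b.size, method
    )


def correlate_vaf(
    pairs: Iterable[tuple[float | None, float | None]],
) -> tuple[float, float, int, int]:
    """Spearman correlation of VAFs measured by two platforms.

    Pairs with a missing member (one platform did not detect the variant)
    are excluded. Returns (r, p, n_used, n_excluded); at least three
    complete pairs are required.
    """
    complete, excluded = [], 0
    for va, vb in pairs:
        if va is None or vb is None or not (math.isfinite(va) and math.isfinite(vb)):
            excluded += 1
        else:
            complete.append((va, vb))
    if len(complete) < 3:
        raise ValidationError(
            f"need >= 3 complete VAF pairs, got {len(complete)}"
        )
    xa, xb = zip(*complete)
    res = stats.spearmanr(xa, xb)
    return float(res.statistic), float(res.pvalue), len(complete), excluded
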