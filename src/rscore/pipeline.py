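"""End-to-end analysis: match calls, score them, compute every agreement statistic.

`run_full_analysis` ties the stages together the way the study design
dictates: read call tables → derive per-sample MAPD from the coverage
table → pair reference-positive calls with the comparison platform →
overall and per-variant-class PPA → quadrant analysis → R-score cutoff
sweep → concordant-vs-discordant rank-sum tests → cross-platform VAF
correlation. Every exclusion is counted, never silent; the report
reconciles (concordant + discordant = matched records).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .errors import EmptyResultError, ValidationError
from .metrics import compute_log2_ratios, compute_mapd
from .concordance import (
    DEFAULT_SWEEP_CUTOFFS,
    PPAEstimate,
    QuadrantResult,
    RankSumResult,
    SweepResult,
    VariantCall,
    compare_groups,
    compute_ppa,
    correlate_vaf,
    match_calls,
    quadrant_analysis,
    rscore_cutoff_sweep,
)
from . import io as _io

__all__ = ["AnalysisConfig", "RunReport", "run_full_analysis", "TECHNICAL_CUT_LOG10"]

log = logging.getLogger("rscore")

#: log10(0.5): the technical-specification cut applied to both axes of the
#: quadrant plot (VAF 0.5% and MAPD 0.5).
TECHNICAL_CUT_LOG10 = -0.301


@dataclass
class AnalysisConfig:
    """Configuration of one concordance run; round-trips through YAML."""

    call_tables: list[str]
    reference_platform: str
    comparison_platform: str
    coverage_table: str | None = None
    mapd_platform: str | None = None  # platform the coverage table belongs to
    match_level: str = "auto"
    ci_method: str = "clopper_pearson"
    alpha: float = 0.05
    quadrant_mode: str = "data_median"  # or "technical"
    sweep_cutoffs: list[float] = field(default_factory=lambda: list(DEFAULT_SWEEP_CUTOFFS))
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = []
        if not self.call_tables:
            bad.append("call_tables is empty")
        for p in self.call_tables:
            if not Path(p).exists():
                bad.append(f"call table not found: {p}")
        if self.coverage_table and not Path(self.coverage_table).exists():
            bad.append(f"coverage table not found: {self.coverage_table}")
        if not 0 < self.alpha < 0.5:
            bad.append(f"alpha={self.alpha} outside (0, 0.5)")
        if self.quadrant_mode not in ("data_median", "technical"):
            bad.append(f"unknown quadrant_mode {self.quadrant_mode!r}")
        if any(b <= a for a, b in zip(self.sweep_cutoffs, self.sweep_cutoffs[1:])):
            bad.append("sweep_cutoffs must be strictly increasing")
        if bad:
            raise ValidationError("invalid analysis config: " + "; ".join(bad))
        if self.mapd_platform is None:
            self.mapd_platform = self.comparison_platform

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _ppa_dict(p: PPAEstimate | None) -> dict | None:
    if p is None:
        return None
    return {
        "n_concordant": p.n_concordant,
        "n_discordant": p.n_discordant,
        "n_total": p.n_total,
        "ppa_percent": round(p.ppa_percent, 2),
        "ci_low_percent": round(p.ci_low_percent, 2),
        "ci_high_percent": round(p.ci_high_percent, 2),
        "ci_method": p.ci_method,
    }


def _test_dict(t: RankSumResult | None) -> dict | str:
    if t is None:
        return "test skipped: a group is empty"
    return {
        "u_statistic": t.u_statistic,
        "p_value": t.p_value,
        "n_a": t.n_a,
        "n_b": t.n_b,
        "method": t.method,
    }


@dataclass
class RunReport:
    """Everything one analysis run computed, serializable to JSON."""

    overall: PPAEstimate
    per_class: dict[str, PPAEstimate]
    quadrants: QuadrantResult
    sweep: SweepResult
    group_tests: dict[str, RankSumResult | None]
    vaf_correlation: dict | str
    counts: dict[str, int]
    provenance: dict

    def to_dict(self) -> dict:
        quad = {
            "vaf_cut_log10": round(self.quadrants.vaf_cut_log10, 4),
            "mapd_cut_log10": round(self.quadrants.mapd_cut_log10, 4),
            "n_records": self.quadrants.n_records,
            "n_excluded": self.quadrants.n_excluded,
            "quadrants": {
                f"vaf_{v}_mapd_{m}": _ppa_dict(p)
                for (v, m), p in self.quadrants.quadrants.items()
            },
        }
        sweep = {
            "cutoffs": self.sweep.cutoffs,
            "ppa_at_cutoff": [_ppa_dict(p) for p in self.sweep.ppa_at_cutoff],
            "correlation_r": self.sweep.correlation_r,
            "correlation_p": self.sweep.correlation_p,
            "n_excluded_undefined_rscore": self.sweep.n_excluded_undefined_rscore,
        }
        return {
            "overall_ppa": _ppa_dict(self.overall),
            "per_class_ppa": {k: _ppa_dict(v) for k, v in sorted(self.per_class.items())},
            "quadrant_analysis": quad,
            "rscore_sweep": sweep,
            "group_tests": {k: _test_dict(v) for k, v in self.group_tests.items()},
            "vaf_correlation": self.vaf_correlation,
            "counts": self.counts,
            "provenance": self.provenance,
        }

    def summary_lines(self) -> list[str]:
        o = self.overall
        lines = [
            f"matched records: {o.n_total} "
            f"(concordant {o.n_concordant}, discordant {o.n_discordant})",
            f"overall PPA: {o.ppa_percent:.2f}% "
            f"(95% CI {o.ci_low_percent:.2f}-{o.ci_high_percent:.2f}, {o.ci_method})",
        ]
        for cls, p in sorted(self.per_class.items()):
            lines.append(
                f"  {cls}: PPA {p.ppa_percent:.2f}% ({p.n_concordant}/{p.n_total})"
            )
        if self.sweep.correlation_r is not None:
            lines.append(
                f"sweep Spearman r(cutoff, PPA) = {self.sweep.correlation_r:.3f} "
                f"(p = {self.sweep.correlation_p:.3g})"
            )
        return lines


def run_full_analysis(config: AnalysisConfig) -> RunReport:
    """Execute the full concordance analysis described by ``config``.

    Deterministic given the input files. Raises EmptyResultError when no
    record can be matched. If ``config.out_dir`` is set, writes
    ``records.tsv``, ``report.json`` and ``summary.txt`` there.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    calls: list[VariantCall] = []
    for path in config.call_tables:
        calls.extend(_io.read_call_table(path))
    by_platform: dict[str, list[VariantCall]] = {}
    for c in calls:
        by_platform.setdefault(c.platform, []).append(c)
    for name in (config.reference_platform, config.comparison_platform):
        if name not in by_platform:
            raise ValidationError(
                f"platform {name!r} absent from call tables "
                f"(found: {sorted(by_platform)})"
            )

    sample_mapd: dict[str, float] = {}
    if config.coverage_table:
        coverage = _io.read_coverage_table(config.coverage_table)
        sample_mapd = {
            sid: compute_mapd(compute_log2_ratios(cov)) for sid, cov in coverage.items()
        }
        log.info("computed MAPD for %d samples from coverage", len(sample_mapd))
        for c in by_platform.get(config.mapd_platform, []):
            if c.mapd is None and c.sample_id in sample_mapd:
                c.mapd = sample_mapd[c.sample_id]

    reference = [
        c
        for c in by_platform[config.reference_platform]
        if c.detected and c.vaf_percent and c.vaf_percent > 0
    ]
    n_ref_dropped = len(by_platform[config.reference_platform]) - len(reference)
    if n_ref_dropped:
        log.info("excluded %d non-positive reference calls", n_ref_dropped)
    comparison = by_platform[config.comparison_platform]
    records = match_calls(reference, comparison, level=config.match_level)
    if not records:
        raise EmptyResultError("no records matched between the two platforms")

    overall = compute_ppa(
        sum(r.concordant for r in records),
        sum(not r.concordant for r in records),
        ci_method=config.ci_method,
        alpha=config.alpha,
    )
    per_class: dict[str, PPAEstimate] = {}
    for cls in sorted({r.variant_class for r in records}):
        sub = [r for r in records if r.variant_class == cls]
        per_class[cls] = compute_ppa(
            sum(r.concordant for r in sub),
            sum(not r.concordant for r in sub),
            ci_method=config.ci_method,
            alpha=config.alpha,
        )

    if config.quadrant_mode == "technical":
        quad = quadrant_analysis(
            records, TECHNICAL_CUT_LOG10, TECHNICAL_CUT_LOG10,
            ci_method=config.ci_method, alpha=config.alpha,
        )
    else:
        quad = quadrant_analysis(records, ci_method=config.ci_method, alpha=config.alpha)

    sweep = rscore_cutoff_sweep(
        records, config.sweep_cutoffs, ci_method=config.ci_method, alpha=config.alpha
    )

    conc = [r for r in records if r.concordant]
    disc = [r for r in records if not r.concordant]
    group_tests: dict[str, RankSumResult | None] = {}
    for name, getter in (
        ("vaf", lambda r: r.reference_vaf_percent),
        ("mapd", lambda r: r.mapd),
        ("r_score", lambda r: r.r_score),
    ):
        va = [getter(r) for r in conc if getter(r) is not None]
        vb = [getter(r) for r in disc if getter(r) is not None]
        group_tests[name] = compare_groups(va, vb) if va and vb else None

    both = [(r.reference_vaf_percent, r.comparison_vaf_percent) for r in records]
    try:
        r, p, n_used, n_excl = correlate_vaf(both)
        vaf_corr: dict | str = {
            "spearman_r": round(r, 4),
            "p_value": p,
            "n_pairs": n_used,
            "n_excluded": n_excl,
        }
    except ValidationError as exc:
        vaf_corr = f"correlation skipped: {exc}"

    counts = {
        "n_reference_positive": len(reference),
        "n_reference_dropped_nonpositive": n_ref_dropped,
        "n_matched_records": len(records),
        "n_concordant": overall.n_concordant,
        "n_discordant": overall.n_discordant,
        "n_quadrant_excluded": quad.n_excluded,
        "n_sweep_excluded_undefined_rscore": sweep.n_excluded_undefined_rscore,
    }
    report = RunReport(
        overall=overall,
        per_class=per_class,
        quadrants=quad,
        sweep=sweep,
        group_tests=group_tests,
        vaf_correlation=vaf_corr,
        counts=counts,
        provenance={
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_paired_records(records, out / "records.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        (out / "summary.txt").write_text("\n".join(report.summary_lines()) + "\n")
    return report
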