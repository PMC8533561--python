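"""Synthetic paired-platform liquid-biopsy cohorts.

Real concordance studies of ctDNA genotyping rest on per-patient call
tables that are rarely machine-readable. This module generates cohorts
with the same statistical structure, so every stage of the analysis is
testable end to end:

* each sample carries one EGFR driver mutation (exon 19 deletion, L858R,
  or a rarer activating variant, in the frequencies typical of
  EGFR-positive NSCLC) and a T790M resistance mutation with probability
  ~0.61;
* true VAFs are log10-normal around a median of ~1.87%;
* each comparison-platform run has a coverage-noise level sigma drawn from
  a Gamma distribution; amplicon log2 ratios are iid Normal(0, sigma^2),
  which makes the realized MAPD concentrate at ~0.9539*sigma (the median
  of |N(0, 2*sigma^2)|), calibrated so the cohort median MAPD is ~0.28;
* the reference platform (dPCR-like) always detects the truth; the first
  comparison platform (amplicon-NGS-like, reporting MAPD) detects with
  probability 1 / (1 + exp(a + b*R)) where R = log10(MAPD / true VAF%) —
  a single-index logistic, the simplest model under which call reliability
  degrades jointly with low VAF and high coverage noise. This is a
  simulation assumption, not a mechanistic claim.
* observed VAFs are the truth times a log10-normal noise factor, floored
  at the platform limit of detection (0.1%); a second comparison platform
  (UMI-NGS-like) has its own VAF noise and detection curve but reports no
  MAPD.

Defaults are calibrated so that at large n the cohort reproduces the
headline behaviour of published dPCR-vs-NGS EGFR comparisons: overall PPA
~0.66, cross-platform VAF Spearman correlation ~0.89, and detection
probability strictly decreasing in R-score.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .metrics import Amplicon, AmpliconCoverage, compute_log2_ratios, compute_mapd
from .concordance import VariantCall

__all__ = [
    "DRIVER_CLASS_FREQS",
    "EX19DEL_VARIANTS",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_amplicon_coverage",
    "generate_paired_vaf",
]

#: Driver-mutation class frequencies among EGFR-positive NSCLC patients.
DRIVER_CLASS_FREQS: dict[str, float] = {
    "ex19del": 0.553,
    "L858R": 0.365,
    "L861Q": 0.035,
    "G719A": 0.023,
    "S768I": 0.012,
    "ex20ins": 0.012,
}

#: Common exon 19 deletion alleles; NGS reports one of these specific HGVS
#: variants while a class-level dPCR assay reports only "ex19del".
EX19DEL_VARIANTS: tuple[str, ...] = (
    "c.2235_2249del",
    "c.2236_2250del",
    "c.2240_2254del",
    "c.2239_2256del",
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    The defaults encode the study conditions the generator emulates; see
    the module docstring. ``detect_intercept``/``detect_slope`` are (a, b)
    of the logistic miss model P(detect) = 1/(1 + exp(a + b*R)) for the
    MAPD-bearing comparison platform; ``detect_intercept_b``/
    ``detect_slope_b`` are (c0, c1) of P(detect) = expit(c0 + c1*log10 VAF)
    for the second comparison platform.
    """

    n_samples: int = 85
    p_t790m: float = 0.61
    vaf_log10_mean: float = math.log10(1.87)
    vaf_log10_sd: float = 0.55
    mapd_shape: float = 4.0
    mapd_scale: float = 0.0799388
    n_amplicons: int = 500
    baseline_count: int = 1000
    detect_intercept: float = 0.85
    detect_slope: float = 2.0
    detect_intercept_b: float = 2.2
    detect_slope_b: float = 2.0
    vaf_obs_noise_sd: float = 0.27
    lod_vaf_percent: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        bad = []
        if self.n_samples < 1:
            bad.append(f"n_samples={self.n_samples} (need >= 1)")
        if not 0 <= self.p_t790m <= 1:
            bad.append(f"p_t790m={self.p_t790m} (need in [0, 1])")
        for name in ("vaf_log10_sd", "mapd_shape", "mapd_scale",
                     "vaf_obs_noise_sd", "lod_vaf_percent"):
            if getattr(self, name) <= 0:
                bad.append(f"{name}={getattr(self, name)} (need > 0)")
        if self.detect_slope < 0:
            bad.append(f"detect_slope={self.detect_slope} (need >= 0)")
        if self.n_amplicons < 2:
            bad.append(f"n_amplicons={self.n_amplicons} (need >= 2)")
        if self.baseline_count < 1:
            bad.append(f"baseline_count={self.baseline_count} (need >= 1)")
        if bad:
            raise ValidationError("invalid cohort config: " + "; ".join(bad))


@dataclass
class SyntheticCohort:
    """A realized cohort: truth, coverage, and per-platform call tables."""

    truth: pd.DataFrame
    coverage: dict[str, AmpliconCoverage]
    calls_reference: list[VariantCall]
    calls_ngs_a: list[VariantCall]
    calls_ngs_b: list[VariantCall]
    config: CohortConfig

    def write(self, out_dir: str | Path) -> None:
        """Write truth, call tables, coverage and provenance under a directory."""
        from . import io as _io  # local import: io depends on this module's types

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        _io.write_call_table(self.calls_reference, out / "calls_dpcr.tsv")
        _io.write_call_table(self.calls_ngs_a, out / "calls_ngs_a.tsv")
        _io.write_call_table(self.calls_ngs_b, out / "calls_ngs_b.tsv")
        _io.write_coverage_table(self.coverage, out / "coverage.tsv")
        with open(out / "provenance.json", "w") as fh:
            json.dump({"config": dataclasses.asdict(self.config)}, fh, indent=2)


def _rng_of(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_amplicon_coverage(
    n_amplicons: int,
    sigma: float,
    baseline_count: int = 1000,
    seed: int | np.random.Generator = 0,
    chrom: str = "chrS",
) -> AmpliconCoverage:
    """Coverage for one run: counts = round(baseline * 2^x), x ~ N(0, sigma^2).

    Amplicons sit on one synthetic chromosome at strictly increasing
    coordinates. With sigma = 0 every amplicon has the baseline count and
    the MAPD of the run is exactly 0.
    """
    if n_amplicons < 2:
        raise ValidationError(f"n_amplicons must be >= 2, got {n_amplicons}")
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    rng = _rng_of(seed)
    x = rng.normal(0.0, sigma, n_amplicons) if sigma > 0 else np.zeros(n_amplicons)
    counts = np.rint(baseline_count * np.exp2(x)).astype(int)
    return AmpliconCoverage(
        [
            Amplicon(f"AMP_{i:05d}", chrom, 200 * i, int(c))
            for i, c in enumerate(counts)
        ]
    )


def _realized_mapd(coverage: AmpliconCoverage) -> float:
    return compute_mapd(compute_log2_ratios(coverage))


def generate_paired_vaf(
    n: int,
    rank_corr: float,
    seed: int | np.random.Generator = 0,
    log10_mean: float = math.log10(1.87),
    log10_sd: float = 0.55,
) -> list[tuple[float, float]]:
    """Paired VAFs from a Gaussian copula with log10-normal margins.

    The Pearson parameter of the underlying bivariate normal is
    2*sin(pi*rank_corr/6), the standard inversion that makes the sample
    Spearman correlation converge to ``rank_corr``.
    """
    if n < 3:
        raise ValidationError(f"n must be >= 3, got {n}")
    if not -1 < rank_corr < 1:
        raise ValidationError(f"rank_corr must be in (-1, 1), got {rank_corr}")
    rng = _rng_of(seed)
    rho = 2.0 * math.sin(math.pi * rank_corr / 6.0)
    cov = [[1.0, rho], [rho, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    vaf = 10.0 ** (log10_mean + log10_sd * z)
    return [(float(a), float(b)) for a, b in vaf]


def _observed_vaf(true_vaf: float, noise_sd: float, lod: float, rng) -> float:
    obs = true_vaf * 10.0 ** rng.normal(0.0, noise_sd)
    return float(min(max(obs, lod), 100.0))


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Generate a full paired-platform cohort from the given configuration.

    Deterministic given ``config.seed``. Returns the truth table, one
    amplicon-coverage profile per sample (the MAPD-bearing platform's run),
    and three call tables: the reference platform (detects every truth row
    at the true VAF), comparison platform A (MAPD-bearing, logistic
    detection in R), and comparison platform B (no MAPD, logistic detection
    in log10 VAF).
    """
    rng = np.random.default_rng(config.seed)
    classes = list(DRIVER_CLASS_FREQS)
    probs = np.array([DRIVER_CLASS_FREQS[c] for c in classes])
    probs = probs / probs.sum()

    truth_rows = []
    coverage: dict[str, AmpliconCoverage] = {}
    calls_ref: list[VariantCall] = []
    calls_a: list[VariantCall] = []
    calls_b: list[VariantCall] = []

    for i in range(config.n_samples):
        sid = f"S{i + 1:04d}"
        sigma = rng.gamma(config.mapd_shape, config.mapd_scale)
        cov = generate_amplicon_coverage(
            config.n_amplicons, sigma, config.baseline_count, seed=rng
        )
        coverage[sid] = cov
        mapd = _realized_mapd(cov)

        muts: list[tuple[str, str]] = []  # (variant_class, ngs_variant_id)
        driver = classes[rng.choice(len(classes), p=probs)]
        if driver == "ex19del":
            ngs_id = "EGFR " + EX19DEL_VARIANTS[rng.choice(len(EX19DEL_VARIANTS))]
        else:
            ngs_id = f"EGFR {driver}"
        muts.append((driver, ngs_id))
        if rng.random() < config.p_t790m:
            muts.append(("T790M", "EGFR T790M"))

        for variant_class, ngs_variant_id in muts:
            true_vaf = float(
                min(10.0 ** rng.normal(config.vaf_log10_mean, config.vaf_log10_sd), 100.0)
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "variant_class": variant_class,
                    "true_vaf_percent": true_vaf,
                }
            )
            # a class-level dPCR assay reports "ex19del"; point-mutation
            # assays name the substitution itself, same label as NGS
            ref_id = variant_class if variant_class == "ex19del" else f"EGFR {variant_class}"
            calls_ref.append(
                VariantCall(
                    sample_id=sid,
                    variant_id=ref_id,
                    variant_class=variant_class,
                    platform="dpcr",
                    detected=True,
                    vaf_percent=true_vaf,
                )
            )
            # platform A: miss probability rises with R = log10(MAPD / VAF)
            r_true = math.log10(mapd / true_vaf) if mapd > 0 else -math.inf
            p_detect_a = float(
                expit(-(config.detect_intercept + config.detect_slope * r_true))
            )
            det_a = rng.random() < p_detect_a
            calls_a.append(
                VariantCall(
                    sample_id=sid,
                    variant_id=ngs_variant_id,
                    variant_class=variant_class,
                    platform="ngs_a",
                    detected=det_a,
                    vaf_percent=_observed_vaf(
                        true_vaf, config.vaf_obs_noise_sd, config.lod_vaf_percent, rng
                    )
                    if det_a
                    else None,
                    mapd=mapd,
                )
            )
            # platform B: no MAPD; detection driven by VAF alone
            p_detect_b = float(
                expit(config.detect_intercept_b + config.detect_slope_b * math.log10(true_vaf))
            )
            det_b = rng.random() < p_detect_b
            calls_b.append(
                VariantCall(
                    sample_id=sid,
                    variant_id=ngs_variant_id,
                    variant_class=variant_class,
                    platform="ngs_b",
                    detected=det_b,
                    vaf_percent=_observed_vaf(
                        true_vaf, config.vaf_obs_noise_sd, config.lod_vaf_percent, rng
                    )
                    if det_b
                    else None,
                )
            )

    return SyntheticCohort(
        truth=pd.DataFrame(truth_rows),
        coverage=coverage,
        calls_reference=calls_ref,
        calls_ngs_a=calls_a,
        calls_ngs_b=calls_b,
        config=config,
    )
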