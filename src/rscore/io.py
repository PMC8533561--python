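"""Readers and writers for call tables, coverage tables and VCF input.

Call tables are TSV with header::

    sample_id  platform  gene  variant_id  variant_class  detected  vaf_percent  mutant_molecules  total_molecules

``detected`` is 0/1. ``vaf_percent`` may be empty for undetected calls; if
empty for a detected call but molecule counts are present, the VAF is
computed from the counts. Coverage tables are TSV with header::

    sample_id  amplicon_id  chrom  start  read_count

with ``start`` 0-based. VCF input (4.2) maps CHROM/POS/REF/ALT plus the
AF or AO/DP tags into the call-table schema; AF is a fraction and is
converted to percent.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .metrics import Amplicon, AmpliconCoverage, NgsAlleleCount, compute_vaf_ngs
from .concordance import VariantCall

__all__ = [
    "CALL_TABLE_COLUMNS",
    "read_call_table",
    "write_call_table",
    "read_coverage_table",
    "write_coverage_table",
    "read_vcf_calls",
    "write_paired_records",
]

CALL_TABLE_COLUMNS = [
    "sample_id",
    "platform",
    "gene",
    "variant_id",
    "variant_class",
    "detected",
    "vaf_percent",
    "mutant_molecules",
    "total_molecules",
]

COVERAGE_COLUMNS = ["sample_id", "amplicon_id", "chrom", "start", "read_count"]


def _parse_optional_float(raw: str, row: int, col: str) -> float | None:
    raw = raw.strip()
    if raw == "" or raw.upper() in ("NA", "NAN"):
        return None
    try:
        v = float(raw)
    except ValueError:
        raise ValidationError(f"row {row}: non-numeric {col} {raw!r}") from None
    if not math.isfinite(v):
        raise ValidationError(f"row {row}: non-finite {col} {raw!r}")
    return v


def read_call_table(path: str | Path, dialect: str = "\t") -> list[VariantCall]:
    """Read and validate a call table; errors name the offending row/field."""
    path = Path(path)
    calls: list[VariantCall] = []
    seen: dict[tuple[str, str, str], int] = {}
    dups: list[tuple] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect)
        missing = [c for c in CALL_TABLE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValidationError(f"{path.name}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):  # 1-based, header is row 1
            detected_raw = row["detected"].strip()
            if detected_raw not in ("0", "1"):
                raise ValidationError(
                    f"{path.name} row {i}: detected must be 0 or 1, got {detected_raw!r}"
                )
            detected = detected_raw == "1"
            vaf = _parse_optional_float(row["vaf_percent"], i, "vaf_percent")
            mutant = _parse_optional_float(row["mutant_molecules"], i, "mutant_molecules")
            total = _parse_optional_float(row["total_molecules"], i, "total_molecules")
            if vaf is None and detected:
                if mutant is not None and total is not None:
                    vaf = compute_vaf_ngs(NgsAlleleCount(int(mutant), int(total)))
                else:
                    raise ValidationError(
                        f"{path.name} row {i}: detected call has no vaf_percent "
                        "and no molecule counts"
                    )
            key = (row["sample_id"], row["platform"], row["variant_id"])
            if key in seen:
                dups.append(key)
            seen[key] = i
            try:
                calls.append(
                    VariantCall(
                        sample_id=row["sample_id"],
                        variant_id=row["variant_id"],
                        variant_class=row["variant_class"],
                        platform=row["platform"],
                        detected=detected,
                        vaf_percent=vaf,
                        gene=row["gene"],
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path.name} row {i}: {exc}") from exc
    if dups:
        raise ValidationError(
            f"{path.name}: duplicated (sample, platform, variant): {sorted(set(dups))}"
        )
    return calls


def write_call_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "platform": c.platform,
                "gene": c.gene,
                "variant_id": c.variant_id,
                "variant_class": c.variant_class,
                "detected": int(c.detected),
                "vaf_percent": "" if c.vaf_percent is None else repr(c.vaf_percent),
                "mutant_molecules": "",
                "total_molecules": "",
            }
        )
    pd.DataFrame(rows, columns=CALL_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> dict[str, AmpliconCoverage]:
    """Read a per-sample amplicon coverage table into one profile per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "amplicon_id": str, "chrom": str})
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{Path(path).name}: missing columns {missing}")
    out: dict[str, AmpliconCoverage] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        out[str(sid)] = AmpliconCoverage(
            [
                Amplicon(r.amplicon_id, r.chrom, int(r.start), int(r.read_count))
                for r in grp.itertuples()
            ]
        )
    return out


def write_coverage_table(coverage: Mapping[str, AmpliconCoverage], path: str | Path) -> None:
    rows = [
        {
            "sample_id": sid,
            "amplicon_id": a.amplicon_id,
            "chrom": a.chrom,
            "start": a.start,
            "read_count": a.read_count,
        }
        for sid, cov in coverage.items()
        for a in cov.amplicons
    ]
    pd.DataFrame(rows, columns=COVERAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_vcf_calls(
    path: str | Path,
    sample_id: str,
    platform: str,
    variant_class_of: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """Read detected calls for one sample from a VCF (4.2).

    The VAF is taken from the AF INFO tag (a fraction, converted to
    percent), falling back on AO/DP when AF is absent. ``variant_class_of``
    optionally maps variant ids ("GENE chrom:pos ref>alt" keys are also
    tried) to class labels; unmapped variants use the id itself.
    """
    from cyvcf2 import VCF  # deferred: keeps import cheap for non-VCF users

    calls = []
    for rec in VCF(str(path)):
        gene = "EGFR"
        for kv in (rec.INFO.get("GENE"), rec.INFO.get("Gene")):
            if kv:
                gene = str(kv)
                break
        alt = rec.ALT[0] if rec.ALT else "."
        variant_id = f"{gene} {rec.CHROM}:{rec.POS} {rec.REF}>{alt}"
        af = rec.INFO.get("AF")
        if af is not None:
            frac = float(af[0] if isinstance(af, tuple) else af)
        else:
            ao, dp = rec.INFO.get("AO"), rec.INFO.get("DP")
            if ao is None or dp is None or float(dp) <= 0:
                raise ValidationError(
                    f"{Path(path).name} {rec.CHROM}:{rec.POS}: no AF and no AO/DP"
                )
            frac = float(ao[0] if isinstance(ao, tuple) else ao) / float(dp)
        vclass = variant_id
        if variant_class_of:
            vclass = variant_class_of.get(variant_id, variant_class_of.get(alt, variant_id))
        calls.append(
            VariantCall(
                sample_id=sample_id,
                variant_id=variant_id,
                variant_class=vclass,
                platform=platform,
                detected=True,
                vaf_percent=100.0 * frac,
                gene=gene,
            )
        )
    return calls


def write_paired_records(records: Iterable, path: str | Path) -> None:
    """Write PairedCallRecords one per row; missing values as empty fields."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "variant_class": r.variant_class,
                "reference_platform": r.reference_platform,
                "comparison_platform": r.comparison_platform,
                "reference_vaf_percent": repr(r.reference_vaf_percent),
                "comparison_detected": int(r.comparison_detected),
                "comparison_vaf_percent": ""
                if r.comparison_vaf_percent is None
                else repr(r.comparison_vaf_percent),
                "mapd": "" if r.mapd is None else repr(r.mapd),
                "r_score": "" if r.r_score is None else repr(r.r_score),
                "concordant": int(r.concordant),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
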