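"""Full pipeline: simulate a cohort to disk, run the analysis, read the report.

The same flow is available from the shell:

    rscore simulate --out cohort/ --seed 5
    rscore concord --calls cohort/calls_dpcr.tsv --calls cohort/calls_ngs_a.tsv \
        --coverage cohort/coverage.tsv --ref-platform dpcr --cmp-platform ngs_a
"""

import tempfile
from pathlib import Path

from rscore import AnalysisConfig, CohortConfig, generate_cohort, run_full_analysis

with tempfile.TemporaryDirectory() as tmp:
    cohort_dir = Path(tmp) / "cohort"
    generate_cohort(CohortConfig(n_samples=85, seed=5)).write(cohort_dir)

    report = run_full_analysis(
        AnalysisConfig(
            call_tables=[
                str(cohort_dir / "calls_dpcr.tsv"),
                str(cohort_dir / "calls_ngs_a.tsv"),
            ],
            reference_platform="dpcr",
            comparison_platform="ngs_a",
            coverage_table=str(cohort_dir / "coverage.tsv"),
            out_dir=str(Path(tmp) / "out"),
        )
    )

print("\n".join(report.summary_lines()))
tests = report.group_tests
print(
    "rank-sum p (concordant vs discordant): "
    f"VAF {tests['vaf'].p_value:.2g}, MAPD {tests['mapd'].p_value:.2g}, "
    f"R-score {tests['r_score'].p_value:.2g}"
)
print(f"cross-platform VAF Spearman r = {report.vaf_correlation['spearman_r']}")
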