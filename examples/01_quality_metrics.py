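"""Score a single variant call: VAF from raw counts, MAPD from coverage, R-score.

A dPCR readout gives the mutant (FAM) and wild-type (VIC) copy
concentrations; an amplicon coverage profile from the NGS run gives the
per-sample noise level. Combining the two yields the R-score, the
per-call reliability index log10(MAPD / VAF).
"""

from rscore import (
    DpcrReadout,
    compute_log2_ratios,
    compute_mapd,
    compute_quality_metrics,
    compute_vaf_dpcr,
    generate_amplicon_coverage,
)

# dPCR saw 13.7 mutant and 719.3 wild-type copies/uL at this locus
vaf = compute_vaf_dpcr(DpcrReadout(fam_copies_per_ul=13.7, vic_copies_per_ul=719.3))

# the NGS run's coverage profile (here simulated with noise sigma = 0.29,
# a typical cell-free DNA run) determines the sample's MAPD
coverage = generate_amplicon_coverage(n_amplicons=500, sigma=0.29, seed=7)
mapd = compute_mapd(compute_log2_ratios(coverage))

qm = compute_quality_metrics(vaf_percent=vaf, mapd=mapd)
print(f"VAF     = {qm.vaf_percent:.3f} %   (mutant fraction of template molecules)")
print(f"MAPD    = {qm.mapd:.3f}     (coverage noise; flag: {qm.mapd_flag})")
print(f"R-score = {qm.r_score:.3f}    (log10(MAPD/VAF); lower = more reliable call)")
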