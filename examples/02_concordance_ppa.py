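"""Positive percent agreement between two platforms, from call lists or counts.

PPA is computed over reference-positive calls: the fraction the comparison
platform confirms, with an exact Clopper-Pearson confidence interval.
Exon 19 deletions are matched at the class level (a dPCR deletion assay
cannot name the exact allele), point mutations exactly.
"""

from rscore import VariantCall, compute_ppa, match_calls

reference = [
    VariantCall("P01", "ex19del", "ex19del", "dpcr", True, 2.4),
    VariantCall("P01", "EGFR T790M", "T790M", "dpcr", True, 0.9),
    VariantCall("P02", "EGFR L858R", "L858R", "dpcr", True, 4.1),
]
comparison = [
    # a different exon 19 deletion allele: still the same variant class
    VariantCall("P01", "ex19del c.2236_2250del", "ex19del", "ngs", True, 2.1, mapd=0.22),
    # T790M missed by NGS in sample P01
    VariantCall("P01", "EGFR T790M", "T790M", "ngs", False, None, mapd=0.22),
    VariantCall("P02", "EGFR L858R", "L858R", "ngs", True, 3.8, mapd=0.35),
]

records = match_calls(reference, comparison)
for r in records:
    status = "concordant" if r.concordant else "DISCORDANT"
    print(f"{r.sample_id} {r.variant_class:8s} {status}  R-score = {r.r_score:+.3f}")

est = compute_ppa(
    sum(r.concordant for r in records), sum(not r.concordant for r in records)
)
print(
    f"\nPPA = {est.ppa_percent:.2f}% ({est.n_concordant}/{est.n_total}; "
    f"95% CI {est.ci_low_percent:.2f}-{est.ci_high_percent:.2f})"
)

# PPA can also be computed directly from published agreement counts:
print(f"91 concordant / 46 discordant -> PPA {compute_ppa(91, 46).ppa_percent:.2f}%")
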