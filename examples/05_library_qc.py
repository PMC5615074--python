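"""Score a genotyped clone set: AR efficiency, coverage, clone budget.

Synthetic Sanger-style reads (with wild-type contamination and synthesis
indels) are classified exactly against the 18 designed members; the QC
report gives the allelic-replacement efficiency, library coverage and
per-member discrepancy from the uniform pool share.  The coupon-collector
calculation answers how many clones to pick for full coverage.
"""

from smartrbs import (
    FixtureSpec,
    LibraryComposition,
    clones_for_coverage,
    expand_degenerate,
    gen_clones,
    qc_report,
)

members = sorted(expand_degenerate("BDGGGW"))  # an 18-member smart library
wild = "ACGTAC"
spec = FixtureSpec(seed=42, wild_fraction=0.10, indel_rate=0.02, n_clones=96)

reads = gen_clones({m: 1 / 18 for m in members}, wild, spec)["read_core"]
comp = LibraryComposition.from_reads(reads, members, wild)
rep = qc_report(comp)

print(f"clones sequenced   : {rep['total_clones']}")
print(f"AR efficiency      : {rep['ar_efficiency']:.2f}")
print(f"coverage           : {rep['coverage_percent']}% of 18 members")
print(f"wild-type fraction : {rep['wild_fraction']:.2f}")
print(f"indel fraction     : {rep['indel_fraction']:.2f}")

budget = clones_for_coverage([1 / 18] * 18, p_target=0.95)
print(f"clones for 95% chance of full coverage (uniform library): {budget}")
# With realistic sub-100% AR, scale the budget by 1/AR — hence the
# practical guidance of picking a couple of hundred clones.
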