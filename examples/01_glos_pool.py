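"""Build the MMR-invisible candidate pool for a wild-type RBS core.

Excluding the wild-type base at every window position gives a degenerate
sequence whose every member mismatches the wild type across the whole
window — a >= 6 bp contiguous mismatch that mismatch repair cannot see.
"""

from smartrbs import GlosSpec, expand_degenerate, glos_candidates, glos_degenerate

wild = "ACGTAC"  # the 6-nt core upstream of the start codon
deg = glos_degenerate(wild)
pool = glos_candidates(GlosSpec(wild))

print(f"wild-type core      : {wild}")
print(f"exclusion degenerate: {deg}  (A->B, C->D, G->H, T->V)")
print(f"candidate pool size : {len(pool)}  (3^6; full randomization would give "
      f"{len(expand_degenerate('N' * len(wild)))})")
print(f"wild type in pool?  : {wild in pool}")

# Every candidate differs from wild type at all six positions, so each
# recombineering heteroduplex is one 6-nt bubble — below nothing for the
# MutS sensor to act on.
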