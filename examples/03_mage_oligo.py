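"""Assemble a MAGE-ready oligo, including a concomitant deletion.

The degenerate core is flanked by homology arms copied from the
post-edit genome, so removing a 220 bp regulatory element upstream of
the window simply makes the left arm span the deletion junction.  The
emitted strand follows the replichore of the target (lagging-strand
annealing), and the four 5'-terminal bases are phosphorothioated.
"""

from smartrbs import FixtureSpec, RbsTarget, build_oligo, format_oligo, gen_locus
from smartrbs.glos import glos_degenerate

genome, target = gen_locus(FixtureSpec(seed=3))
seq = genome["synthetic_locus"]
rbs = RbsTarget(
    seq,
    orf_start=target["orf_start"],
    gene_strand=target["gene_strand"],
    window_offsets=tuple(target["window_offsets"]),
    oriC=0,
    dif=len(seq) // 2,
)
core = glos_degenerate(target["wild_core"])

plain = build_oligo(rbs, core)
upstream_deletion = (target["orf_start"] - 250, target["orf_start"] - 30)
with_del = build_oligo(rbs, core, deletion=upstream_deletion)

print(f"wild core     : {target['wild_core']}  at offsets {target['window_offsets']}")
print(f"replichore    : {plain.replichore}  ->  orientation {plain.orientation}")
print(f"90-mer oligo  : {format_oligo(plain)}")
print(f"+220bp deletion {upstream_deletion}:")
print(f"junction oligo: {format_oligo(with_del)}")
print(f"lengths       : {len(plain.sequence)} and {len(with_del.sequence)} nt "
      "(deletion size never changes oligo length)")
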