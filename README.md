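# smartrbs

Design chromosomal ribosome-binding-site (RBS) libraries that an active
mismatch-repair system cannot bias.

## The problem

Recombineering (MAGE/CRMAGE) installs an RBS library by annealing
degenerate single-stranded oligos at the replication fork. In
MMR-proficient strains, MutS surveys the resulting heteroduplex and
reverts short mismatches — so library members closest to the wild-type
sequence are selectively erased, collapsing diversity and flooding the
clone set with wild type. MutS, however, does not recognize contiguous
mismatches longer than ~5 bp, nor C:C mismatches.

`smartrbs` implements the design rule that exploits this (**GLOS** —
genome library optimized sequences): exclude the wild-type base at every
position of the target window, so *every* library member differs from
wild type across the whole window and each recombineering intermediate
is a single ≥ 6 bp bubble that MMR cannot see. For a 6-nt window this
keeps 3⁶ = 729 of the 4⁶ = 4096 fully randomized candidates. The
package then reduces that pool to a single synthesizable, partially
degenerate oligonucleotide of requested size n whose predicted
translation-initiation rates (TIRs) tile the accessible range as
uniformly as possible:

minimize  Σᵢ ( t₍ᵢ₎ − uᵢ )²,  uᵢ = t_min + (i−1)(t_max − t_min)/(n−1),

over all per-position base-subset products with degeneracy exactly n,
where t₍₁₎ ≤ … ≤ t₍ₙ₎ are the member TIRs and [t_min, t_max] the full
pool's TIR range. Around the core it assembles MAGE-ready 90-mers
(homology arms from the post-edit genome, concomitant deletions,
replichore-aware strand choice, 5′ phosphorothioates), simulates
MMR-dependent library attrition, and computes library QC statistics
(allelic-replacement efficiency, coverage, discrepancy from uniform,
clone budgets) from clone or pool sequencing.

TIR predictions come from any external RBS calculator as a
`sequence,tir` CSV; a clearly-labeled offline proxy exists so everything
runs without external tools.

## Worked example

```python
from smartrbs import (FixtureSpec, GlosSpec, TirModel, gen_tir_table,
                      glos_candidates, reduce_library)

pool = sorted(glos_candidates(GlosSpec("ACGTAC")))       # 729 candidates
tirs = gen_tir_table(pool, FixtureSpec(seed=11))          # or your calculator's CSV
model = TirModel(table=dict(zip(tirs["sequence"], tirs["tir"])))
lib = reduce_library(pool, model, n=18)
print(lib.degenerate, lib.score)
```

Running `python examples/02_reduce_library.py` prints:

```
pool                : 729 candidates, TIR range [10.1, 9914.2]
reduced degenerate  : YDTGTD  (degeneracy 18)
uniformity score    : 4.934e+07  (sum of squared grid deviations)
members (TIR-sorted):
   1  TTTGTG        10.8
   2  TGTGTG        40.7
   ...
  18  TATGTT      9651.7
```

`YDTGTD` is the single oligo to synthesize: its 18 encoded variants span
the pool's TIR range (10.8–9651.7 arbitrary units) in near-equal steps,
and every variant is a full 6-bp mismatch to the wild core `ACGTAC`, so
integration is unbiased by MMR. The other examples show the candidate
pool construction (`01`), MAGE oligo assembly with a concomitant 220-bp
deletion (`03`), attrition of a fully randomized library versus the
exclusion-rule library under active repair — 36% vs 100% of members
surviving under a stringent table (`04`) — and clone-set QC with the
coupon-collector clone budget: 103 clones for a 95% chance of seeing
all 18 members of a uniform library (`05`).

The same pipeline is scriptable from the shell:

```bash
smartrbs glos --wild-core ACGTAC --out pool.csv
smartrbs reduce --pool pool.csv --tir tir.csv --n 18 --out members.csv
smartrbs oligos --genome locus.fasta --target target.json --core YDTGTD
smartrbs simulate --library members.csv --wild ACGTAC --beta 1.0 --kappa 1.0
smartrbs qc --reads clones.csv --members members.csv --wild ACGTAC
smartrbs fixtures --seed 1 --outdir demo/   # synthetic inputs for all of the above
```

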