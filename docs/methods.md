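# Methods

## Problem and model

`smartrbs` designs chromosomal ribosome-binding-site (RBS) libraries for
recombineering (MAGE/CRMAGE) in mismatch-repair-proficient bacteria. The
obstacle it addresses is MutS-dependent mismatch repair (MMR): after a
single-stranded oligo anneals at the replication fork, the resulting
heteroduplex is surveyed by MutS, and short mismatches are reverted
before they can fix in the genome. Repair efficiency falls with mismatch
length and is effectively abolished for contiguous mismatches longer
than about 5 bp; C:C mismatches escape recognition at any length. MMR
therefore biases which library members integrate — it prunes exactly the
members closest in sequence to the wild type.

The design rule implemented here (GLOS, *genome library optimized
sequences*) sidesteps repair instead of disabling it: at every position
of the target window, the wild-type base is excluded (A→B, C→D, G→H,
T→V in IUPAC code). Every encoded member then mismatches the wild type
across the entire window, so a 6-nt window yields one ≥ 6 bp heteroduplex
bubble per member — invisible to MutS — at the cost of shrinking the
candidate space from 4^L to 3^L (4096 → 729 for L = 6).

## Library reduction

A synthesizable library must be a *single* partially degenerate
oligonucleotide, i.e. a Cartesian product of per-position base subsets.
Given a TIR (translation-initiation-rate) prediction for every candidate,
the reduction picks the product library of requested size n whose member
TIRs tile the accessible range most uniformly:

* sort the n member TIRs ascending, t_(1) ≤ … ≤ t_(n);
* lay the ideal grid u_i = t_min + (i−1)(t_max − t_min)/(n−1), anchored
  by default at the **full pool's** extremes (configurable to the
  candidate library's own extremes);
* score Σᵢ (t_(i) − u_i)²; smaller is more uniform, 0 is a perfect grid.

The search is exhaustive over all per-position subset choices whose
sizes multiply to exactly n, enumerated by first factorizing n into a
per-position size vector and then expanding subset combinations. For a
3-base/position 6-mer pool and n = 18 (= 2·3·3) this leaves 60 size
vectors × 81 subset combinations = 4,860 candidates; for a 4-base
N6 pool it is ~3.7 × 10⁵. Exhaustive search is exact at these scales, so
no heuristic is used. Ties are broken by the lexicographically smallest
IUPAC string, making the reduction deterministic and byte-reproducible.
Scoring can optionally be done on log10(TIR) (`log_tir=True`); the
default is the raw scale.

## Mismatch analysis and the repair model

Mismatch pairs are reported as (oligo base, template base), where the
template is the complement of the wild-type top strand — the strand the
oligo anneals to. An oligo C opposite a genomic G therefore reads as the
(C,C) pair. The default recognized-pair set is every mismatch pair
except (C,C); it is fully configurable because quantitative recognition
differences among other pairs are not modeled.

The attrition simulator assigns each member a repair probability by
decomposing its heteroduplex against the wild core into maximal
contiguous mismatch runs — the physical bubbles MutS encounters. A run
is recognizable at its full length iff it contains at least one
recognized pair (a run of only C:C pairs is invisible at any length);
each recognizable run is then repaired independently with a
length-dependent probability p(L), and the member survives only if no
run is repaired. We deliberately key p on the full bubble length rather
than on the longest flag-contiguous recognized stretch: a C:C pair
inside a 6 bp mismatch does not split the bubble into two short,
repairable ones, and the whole-bubble convention is what makes the
package's central guarantee — GLOS libraries behave identically with
and without MMR — an exact identity rather than an approximation.

The default table p = {1: 0.9, 2: 0.8, 3: 0.6, 4: 0.4, 5: 0.2, ≥6: 0}
is an *illustrative* monotone decay: the length dependence and the zero
beyond 5 bp are the established MutS behavior, but the intermediate
rates are placeholders, not fitted values. Lookups clamp to the largest
tabulated key; L = 0 returns 0 (nothing to repair). User tables replace
the default wherever rates matter; non-monotone tables are accepted but
flagged.

Per clone, the model draws a member i from the pool frequencies f, lets
it integrate with probability β, reverts it with probability p_i, and
kills clones that remain wild type at the protospacer with the
counterselection probability κ. Expectation mode evaluates the closed
form (member mass β·f_i·(1 − p_i); wild mass (1 − Σ masses)(1 − κ));
sampled mode draws surviving clones with a seeded generator, redrawing
killed clones. AR efficiency is Σ member mass / total mass. The outcome
exposes both overall frequencies (summing with the wild fraction to 1)
and member frequencies conditional on carrying a library allele; the
two coincide under full counterselection. β, κ and the repair rates are
mechanism dials for exploring regimes, not estimators of any measured
efficiency.

## Oligo assembly

Window offsets use the biologist's convention (−1 is the base
immediately 5′ of the start codon on the coding strand); all internal
arithmetic is 0-based half-open on the plus strand. Homology arms are
copied from the *post-edit* genome, so a concomitant deletion (e.g.
removing a 220 bp riboswitch upstream of the window) automatically
yields junction-spanning arms, and the oligo length — default 90 nt,
left arm taking the extra base on an odd split — never depends on the
deletion size. A deletion overlapping the window is rejected.

Replichore assignment places a position on replichore 1 iff it lies on
the oriC→dif arc in increasing-coordinate direction (oriC itself → 1,
dif itself → 2, wrap-around handled modulo genome length). The emitted
strand follows the lagging-strand-annealing convention — plus
orientation on replichore 1, minus on replichore 2 — pinned here as a
package convention and invertible with one flag, since either convention
is defensible depending on how the replichores are labeled. The first
four 5′ linkages are rendered phosphorothioated (`T*T*T*T*…`), the
standard exonuclease protection for MAGE oligos.

## QC statistics

Clone classification is exact: a read equal to a designed member counts
for that member, a read equal to the wild core is wild type, a read of
any other length is an indel (synthesis artifacts dominate this class),
and a correct-length read matching nothing is "other". AR efficiency is
mutant clones over all sequenced clones by default; a flag removes
indels from the denominator, since published displays often exclude
them. Coverage is the fraction of designed members seen at least once;
replicate coverages are averaged and reported as integer percent
(e.g. recovering 16 and 18 of 18 members → 94%, 5 and 9 of 18 → 39%).

Discrepancy from uniform is (observed/expected − 1)·100 with expected =
1/n, signed so that negative means underrepresented. A `one_decimal`
convention truncates the expected percent share to one decimal (5.5%
for n = 18, under which a 2.75% abundance is exactly −50%); it exists
because truncated shares are what sequencing reports typically print,
and is not the default.

The clone budget for full coverage is the generalized coupon-collector
question: the smallest m with P(all n members seen in m iid draws) ≥
p_target. P is computed exactly by inclusion–exclusion over member
subsets (subset sums built by doubling; practical to n = 25) and by
seeded Monte Carlo beyond; the search over m brackets exponentially and
bisects, exploiting monotonicity. For an 18-member uniform library at
95% confidence the exact answer is 103 clones; with realistic sub-100%
AR efficiency and skewed abundances the practical budget scales up
accordingly — into the low hundreds.

The hairpin score is a proxy, not a thermodynamic prediction: an
exhaustive scan for the longest perfect Watson–Crick stem (≥ 3 bp) with
a ≥ 3 nt loop, scored at −2 kcal/mol per stem pair, 0 when no stem
qualifies. It only ranks oligos by gross secondary structure; wherever
real folding energies are available they override it, and the Spearman
correlation between ΔG and member abundance is reported descriptively,
never asserted.

## Synthetic data

The fixture generator emulates the shape of the real experiments: a
random locus with a planted ORF and a 6-nt RBS window at offsets
−15..−10; TIR tables drawn log-uniformly over [10, 10⁴] arbitrary
calculator units (three orders of magnitude, the typical dynamic range
of predicted RBS strength); 96-clone Sanger-style read sets with 10%
wild-type contamination and a 2% single-base indel rate; and
Dirichlet-skewed synthesis-pool abundances (concentration 20, matching
the few-fold member-to-member spread seen in pool sequencing). All
draws go through `numpy.random.Generator` seeded from the spec, so
outputs are byte-identical under a fixed seed.

What the generator does *not* emulate: sequencing error profiles,
chromatograms or quality scores; synthesis errors other than single-base
indels; any correlation between TIR and sequence content (TIRs are
random, not thermodynamic); growth competition between clones. Passing
tests therefore demonstrate the combinatorics, the optimizer, the
attrition identity and the estimators — not predictive accuracy of TIRs
or folding energies on real sequences.

## Numerical choices and edge cases

* Degeneracy and expansion are exact integer/set operations; expansion
  is lazy where pools get large.
* The reduction rejects pools that are not full product spaces (the
  feasible set is undefined otherwise) and reports when n admits no
  factorization into per-position subset sizes.
* A pool whose TIRs are all equal has no uniformity objective and is
  rejected; with library-extreme anchoring, candidate libraries with
  all-equal TIRs are skipped rather than scored.
* Frequencies must sum to 1 within 1e−9; sampled-mode counts are exact
  fractions of the clone total.
* β = 0 with κ = 1 leaves no surviving clones and is an explicit error.
* Test and example problem sizes (729-member pools, 10⁴-clone recovery
  checks, 2 × 10⁴-replicate Monte Carlo) were chosen to keep the full
  suite in seconds while leaving all statistical assertions at ≥ 3
  standard errors.

## Known limitations

* Table-mode TIRs are authoritative; the built-in SD-similarity proxy
  (exp(α · longest common substring with AGGAGG)) is monotone in
  SD-likeness but ignores spacing, standby sites and structure, and is
  insensitive to bases outside the matched substring.
* The repair table's intermediate rates are illustrative; only the ≥ 6 bp
  invisibility and the C:C exemption carry mechanistic weight.
* Replichore-dependent *efficiency* is not modeled — only the strand
  choice; multi-cycle MAGE accumulation and multi-locus joint design are
  out of scope.
* Window wrap-around across the circular origin is not supported for
  window/deletion intervals (arms may wrap).
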