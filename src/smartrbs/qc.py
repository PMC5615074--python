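"""Library quality statistics from clone genotyping and pool sequencing.

Covers the statistics used to judge a chromosomal RBS library:

* **AR efficiency** — allelic-replacement efficiency, the ratio of mutant
  clones to total sequenced clones;
* **coverage** — fraction of the designed members recovered at least
  once, averaged over replicate integrations and reported in percent;
* **discrepancy from uniform** — per-member relative deviation of the
  observed pool abundance from the ideal 1/n share, in signed percent
  (negative = underrepresented);
* **clones needed for coverage** — the coupon-collector question: how
  many clones must be genotyped before every member has been seen with a
  target probability, exact by inclusion–exclusion at library scale;
* **a hairpin folding-energy proxy** — a crude stem-loop scan standing in
  for a real secondary-structure calculator, used only to rank oligos by
  structure; user-supplied free energies override it everywhere.

Reads arrive pre-extracted to the core window; classification is exact
(a read of wrong length is an indel, a right-length read matching
neither a member nor wild type is "other").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .seq_core import reverse_complement_degenerate

__all__ = [
    "LibraryComposition",
    "FoldProxy",
    "classify_clone",
    "ar_efficiency",
    "coverage",
    "mean_coverage",
    "abundance_discrepancy",
    "coverage_probability",
    "clones_for_coverage",
    "hairpin_dg_proxy",
    "qc_report",
]


def classify_clone(read_core: str, members: Iterable[str], wild: str) -> str:
    """Classify one genotyped clone read against the designed library.

    Returns the member sequence on an exact member match, ``"wild"`` on
    an exact wild-type match, ``"indel"`` when the read length differs
    from the core length, and ``"other"`` for a correct-length read
    matching nothing (e.g. a point-mutated or partially repaired allele).
    """
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    read_core = read_core.upper()
    if read_core in members:
        return read_core
    if read_core == wild:
        return "wild"
    core_len = len(wild)
    if len(read_core) != core_len:
        return "indel"
    return "other"


@dataclass
class LibraryComposition:
    """Observed clone counts per category for one sequencing experiment."""

    counts: dict[str, int]
    wild_count: int = 0
    indel_count: int = 0
    other_count: int = 0
    n: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            self.n = len(self.counts)
        if any(c < 0 for c in self.counts.values()) or min(
            self.wild_count, self.indel_count, self.other_count
        ) < 0:
            raise ValueError("negative counts")

    @property
    def mutant_count(self) -> int:
        return sum(self.counts.values())

    @property
    def total(self) -> int:
        return self.mutant_count + self.wild_count + self.indel_count + self.other_count

    @classmethod
    def from_reads(
        cls, reads: Iterable[str], members: Iterable[str], wild: str
    ) -> "LibraryComposition":
        members = sorted(set(members))
        counts = {m: 0 for m in members}
        wild_c = indel_c = other_c = 0
        for read in reads:
            cat = classify_clone(read, members, wild)
            if cat == "wild":
                wild_c += 1
            elif cat == "indel":
                indel_c += 1
            elif cat == "other":
                other_c += 1
            else:
                counts[cat] += 1
        return cls(counts, wild_c, indel_c, other_c, n=len(members))


def ar_efficiency(
    c: LibraryComposition, *, exclude_indels: bool = False
) -> float:
    """Allelic-replacement efficiency: mutant clones / total clones.

    With ``exclude_indels`` the denominator drops indel reads (matching
    displays that exclude them); the default counts every sequenced
    clone.
    """
    denom = c.total - (c.indel_count if exclude_indels else 0)
    if denom <= 0:
        raise ValueError("no clones to evaluate")
    return c.mutant_count / denom


def coverage(c: LibraryComposition) -> float:
    """Fraction of designed members recovered at least once."""
    if c.n < 1:
        raise ValueError("library size must be >= 1")
    return sum(1 for v in c.counts.values() if v >= 1) / c.n


def mean_coverage(replicates: Sequence) -> int:
    """Mean replicate coverage in percent, rounded to the nearest integer.

    Each replicate may be a LibraryComposition, a coverage fraction, or a
    ``(recovered, n)`` pair — e.g. recovering (16, 18) and (18, 18) of an
    18-member library averages to 94%.
    """
    fracs = []
    for r in replicates:
        if isinstance(r, LibraryComposition):
            fracs.append(coverage(r))
        elif isinstance(r, tuple):
            k, n = r
            fracs.append(k / n)
        else:
            fracs.append(float(r))
    if not fracs:
        raise ValueError("no replicates")
    return int(round(100.0 * sum(fracs) / len(fracs)))


def abundance_discrepancy(
    obs_freq: float, n: int, convention: str = "exact"
) -> float:
    """Signed percent deviation of an observed pool abundance from uniform.

    The uniform expectation is 1/n (``exact``) or the percent share
    truncated to one decimal, e.g. 5.5% for n = 18 (``one_decimal``, the
    convention under which a 2.75% abundance reads as exactly -50%).
    Negative values mean underrepresented.
    """
    if not (0.0 <= obs_freq <= 1.0):
        raise ValueError(f"obs_freq {obs_freq} outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if convention == "exact":
        expected = 1.0 / n
    elif convention == "one_decimal":
        expected = (int(1000.0 / n) / 10.0) / 100.0  # truncated percent share
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return (obs_freq / expected - 1.0) * 100.0


# ---------------------------------------------------------------------------
# coupon-collector coverage sampling
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 25


def coverage_probability(
    freqs: Sequence[float],
    m: int,
    *,
    method: str = "auto",
    seed: Optional[int] = None,
    n_rep: int = 100_000,
) -> float:
    """P(every member is seen at least once in m iid clone draws).

    Exact by inclusion-exclusion over member subsets for libraries of up
    to 25 members; seeded Monte Carlo otherwise (or on request).
    """
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    if m < 0:
        raise ValueError("m must be >= 0")
    if method == "auto":
        method = "exact" if n <= _EXACT_MAX_N else "mc"
    if method == "exact":
        # subset sums by doubling; sign = (-1)^|S|
        sums = np.zeros(1)
        signs = np.ones(1)
        for f in freqs:
            sums = np.concatenate([sums, sums + f])
            signs = np.concatenate([signs, -signs])
        return float(np.sum(signs * np.clip(1.0 - sums, 0.0, 1.0) ** m))
    if method == "mc":
        rng = np.random.default_rng(seed)
        hits = 0
        batch = 1000
        done = 0
        while done < n_rep:
            b = min(batch, n_rep - done)
            draws = rng.choice(n, size=(b, m), p=freqs)
            for row in draws:
                if len(np.unique(row)) == n:
                    hits += 1
            done += b
        return hits / n_rep
    raise ValueError(f"unknown method {method!r}")


def clones_for_coverage(
    freqs: Sequence[float],
    p_target: float,
    *,
    seed: Optional[int] = None,
    n_rep: int = 100_000,
) -> int:
    """Smallest clone count m with P(all members seen in m draws) >= p_target.

    Exact (inclusion-exclusion) for libraries of <= 25 members, seeded
    Monte Carlo above.  A member with zero frequency can never be seen
    and is an error.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        bad = int(np.argmin(freqs))
        raise ValueError(
            f"member {bad} has non-positive frequency {freqs[bad]}; "
            "full coverage is unreachable"
        )
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {freqs.sum()}, not 1")
    if not (0.0 < p_target < 1.0):
        raise ValueError("p_target must lie strictly between 0 and 1")
    n = len(freqs)
    method = "exact" if n <= _EXACT_MAX_N else "mc"

    def prob(m: int) -> float:
        return coverage_probability(freqs, m, method=method, seed=seed, n_rep=n_rep)

    # exponential bracket then binary search; P(m) is monotone in m
    lo, hi = n - 1, max(n, 2)
    while prob(hi) < p_target:
        lo = hi
        hi *= 2
        if hi > 10_000_000:
            raise RuntimeError("coverage target unreachable in practice")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if prob(mid) >= p_target:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# folding-energy proxy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldProxy:
    """Crudest-possible hairpin call: longest perfect stem with loop >= 3.

    ``dg`` is a stand-in scale (-2 kcal/mol per stem base pair), NOT a
    thermodynamic prediction; it exists to rank oligos by gross
    structure.  dg == 0 iff no stem of >= 3 bp with a >= 3 nt loop exists.
    """

    sequence: str
    stem_length: int
    loop_length: int
    dg: float


def hairpin_dg_proxy(seq: str, *, min_stem: int = 3, min_loop: int = 3) -> FoldProxy:
    """Exhaustive scan for the longest perfect Watson-Crick hairpin stem.

    Considers every stem placement ``seq[i:i+s] ... seq[j:j+s]`` with loop
    ``j - (i+s) >= min_loop`` and requires the downstream arm to be the
    reverse complement of the upstream arm.  Proxy dg = -2.0 * stem
    length, 0 if no qualifying stem.  Degenerate bases are rejected —
    fold concrete realizations individually.
    """
    seq = seq.upper()
    for i, b in enumerate(seq):
        if b not in "ACGT":
            raise ValueError(
                f"degenerate base {b!r} at position {i}: fold concrete "
                "realizations individually"
            )
    L = len(seq)
    best_s, best_loop = 0, 0
    for s in range(min_stem, L // 2 + 1):
        for i in range(0, L - 2 * s - min_loop + 1):
            arm = seq[i : i + s]
            arm_rc = reverse_complement_degenerate(arm)
            for j in range(i + s + min_loop, L - s + 1):
                if seq[j : j + s] == arm_rc:
                    loop = j - (i + s)
                    if s > best_s or (s == best_s and loop < best_loop):
                        best_s, best_loop = s, loop
    dg = -2.0 * best_s if best_s >= min_stem else 0.0
    return FoldProxy(seq, best_s, best_loop if best_s else 0, dg)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def qc_report(
    composition: LibraryComposition,
    *,
    pool_abundance: Optional[Mapping[str, float]] = None,
    dg_by_member: Optional[Mapping[str, float]] = None,
    discrepancy_convention: str = "exact",
    exclude_indels: bool = False,
) -> dict:
    """Assemble the QC summary for one library experiment.

    Reports AR efficiency, coverage, indel fraction and per-member
    abundance discrepancy (from ``pool_abundance`` if given, else from
    clone counts).  If folding energies are available — user-supplied via
    ``dg_by_member`` or the built-in hairpin proxy otherwise — a Spearman
    rank correlation between dG and abundance is reported, purely
    descriptively.
    """
    total = composition.total
    members = sorted(composition.counts)
    if pool_abundance is not None:
        ab_total = sum(pool_abundance.values())
        abundance = {m: pool_abundance.get(m, 0.0) / ab_total for m in members}
    else:
        mutants = max(composition.mutant_count, 1)
        abundance = {m: composition.counts[m] / mutants for m in members}
    discrepancy = {
        m: abundance_discrepancy(abundance[m], composition.n, discrepancy_convention)
        for m in members
    }
    if dg_by_member is None:
        dg_by_member = {m: hairpin_dg_proxy(m).dg for m in members}
    dg_vals = [dg_by_member[m] for m in members]
    ab_vals = [abundance[m] for m in members]
    if len(members) >= 3 and len(set(dg_vals)) > 1 and len(set(ab_vals)) > 1:
        rho, pval = stats.spearmanr(dg_vals, ab_vals)
        dg_corr = {"spearman_rho": float(rho), "p_value": float(pval)}
    else:
        dg_corr = None
    return {
        "total_clones": total,
        "ar_efficiency": ar_efficiency(composition, exclude_indels=exclude_indels),
        "coverage": coverage(composition),
        "coverage_percent": int(round(100 * coverage(composition))),
        "wild_fraction": composition.wild_count / total,
        "indel_fraction": composition.indel_count / total,
        "other_fraction": composition.other_count / total,
        "member_counts": dict(composition.counts),
        "member_discrepancy_percent": discrepancy,
        "dg_abundance_correlation": dg_corr,
    }
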