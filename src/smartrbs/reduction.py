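"""Reduction of a candidate pool to one partially degenerate oligonucleotide.

Given a full product-space candidate pool (a GLOS pool or a fully
randomized window) and a TIR prediction for every member, find the single
degenerate IUPAC string of requested degeneracy ``n`` whose encoded
members' TIRs tile the pool's TIR range as uniformly as possible.

The objective is pinned exactly: sort the n member TIRs ascending as
t_(1..n), lay the ideal uniform grid u_i = t_min + (i-1)(t_max-t_min)/(n-1)
anchored at the FULL pool's extremes, and score sum((t_(i) - u_i)^2).  The
feasible set is every per-position subset product whose degeneracy is
exactly n — a constraint that makes the answer orderable as one synthetic
oligonucleotide.  The search is exhaustive with factorization pruning
(per-position subset sizes must multiply to n), which is exact and fast at
RBS-window scale: a 3-base/position 6-mer pool admits only 4,860 feasible
degenerate sequences for n = 18.

Ties are broken by the lexicographically smallest IUPAC string, so the
reduction is deterministic.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Sequence

from .seq_core import (
    DegenerateSequence,
    SET_TO_IUPAC,
    expand_degenerate,
)
from .tir import TirModel

__all__ = [
    "SmartLibrary",
    "uniformity_score",
    "enumerate_feasible",
    "reduce_library",
    "pool_allowed_sets",
]


@dataclass(frozen=True)
class SmartLibrary:
    """A reduced library: one degenerate oligo core plus its members and TIRs.

    ``members`` and ``tirs`` are aligned and sorted by ascending TIR;
    ``score`` is the squared-deviation uniformity objective (0 iff the
    sorted TIRs hit the ideal grid exactly); ``pool_min``/``pool_max``
    are the anchoring extremes (on the scoring scale, i.e. log10 if the
    reduction was run on log TIRs).
    """

    degenerate: DegenerateSequence
    members: tuple[str, ...]
    tirs: tuple[float, ...]
    n: int
    score: float
    pool_min: float
    pool_max: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degenerate"] = self.degenerate.symbols
        d["members"] = list(self.members)
        d["tirs"] = list(self.tirs)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def uniformity_score(
    tirs: Sequence[float], pool_min: float, pool_max: float
) -> float:
    """Squared deviation of sorted TIRs from the ideal uniform grid.

    The grid has ``n = len(tirs)`` rungs spanning [pool_min, pool_max]:
    u_i = pool_min + (i-1)(pool_max - pool_min)/(n-1).  Returns
    sum((t_(i) - u_i)^2) over the ascending-sorted TIRs; 0 iff they hit
    the grid exactly.
    """
    n = len(tirs)
    if n < 2:
        raise ValueError(f"need at least 2 TIRs, got {n}")
    if pool_max <= pool_min:
        raise ValueError(
            f"pool_max ({pool_max}) must exceed pool_min ({pool_min})"
        )
    step = (pool_max - pool_min) / (n - 1)
    return sum(
        (t - (pool_min + i * step)) ** 2 for i, t in enumerate(sorted(tirs))
    )


def _size_vectors(max_sizes: Sequence[int], n: int) -> Iterator[tuple[int, ...]]:
    """All per-position subset-size vectors with product exactly n."""

    def rec(pos: int, remaining: int, prefix: tuple[int, ...]):
        if pos == len(max_sizes):
            if remaining == 1:
                yield prefix
            return
        for s in range(1, max_sizes[pos] + 1):
            if remaining % s == 0:
                yield from rec(pos + 1, remaining // s, prefix + (s,))

    yield from rec(0, n, ())


def enumerate_feasible(
    allowed_sets: Sequence[Iterable[str]], n: int
) -> Iterator[DegenerateSequence]:
    """Every product-of-subsets degenerate sequence with degeneracy exactly n.

    Per position the subset must be nonempty and contained in the allowed
    set; enumeration is restricted to subset-size vectors whose product
    equals n.  If n admits no such factorization the stream is empty
    (not an error).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sets = [sorted(set(s)) for s in allowed_sets]
    if any(not s for s in sets):
        raise ValueError("allowed sets must be nonempty at every position")
    for sizes in _size_vectors([len(s) for s in sets], n):
        per_pos_subsets = [
            list(itertools.combinations(s, k)) for s, k in zip(sets, sizes)
        ]
        for combo in itertools.product(*per_pos_subsets):
            yield DegenerateSequence(
                "".join(SET_TO_IUPAC[frozenset(sub)] for sub in combo)
            )


def pool_allowed_sets(pool: Iterable[str]) -> list[frozenset[str]]:
    """Reconstruct per-position allowed base sets from a product-space pool.

    Fails if the pool is not a full Cartesian product of its per-position
    base sets (the reduction's feasible set is only well-defined then).
    """
    pool = sorted(set(pool))
    if not pool:
        raise ValueError("empty pool")
    length = len(pool[0])
    if any(len(s) != length for s in pool):
        raise ValueError("pool sequences must have uniform length")
    sets = [frozenset(seq[i] for seq in pool) for i in range(length)]
    expected = math.prod(len(s) for s in sets)
    if expected != len(pool):
        raise ValueError(
            f"pool of {len(pool)} sequences is not a full product space "
            f"(per-position sets imply {expected} members)"
        )
    return sets


def reduce_library(
    pool: Iterable[str],
    model: TirModel,
    n: int,
    *,
    log_tir: bool = False,
    anchor: str = "pool",
) -> SmartLibrary:
    """Find the degeneracy-n IUPAC string minimizing the uniformity score.

    Parameters
    ----------
    pool : iterable of str
        Full product-space candidate pool (e.g. the 729-member GLOS pool).
    model : TirModel
        Covers every pool member.
    n : int
        Requested library size; must factor into per-position subset
        sizes bounded by the allowed-set sizes, else no feasible
        degenerate oligo exists.
    log_tir : bool
        Score on log10(TIR) instead of the raw scale.
    anchor : "pool" | "library"
        Anchor the ideal grid at the full pool's TIR extremes (default,
        spanning the accessible range) or at each candidate library's own
        extremes.

    Deterministic: ties are broken by the lexicographically smallest
    IUPAC string, so repeated runs return byte-identical results.
    """
    if anchor not in ("pool", "library"):
        raise ValueError(f"anchor must be 'pool' or 'library', got {anchor!r}")
    pool = sorted(set(pool))
    if n > len(pool):
        raise ValueError(f"n={n} exceeds pool size {len(pool)}")
    sets = pool_allowed_sets(pool)

    def transform(t: float) -> float:
        return math.log10(t) if log_tir else t

    tir_by_seq = {seq: transform(model.predict(seq)) for seq in pool}
    pool_min = min(tir_by_seq.values())
    pool_max = max(tir_by_seq.values())
    if pool_max <= pool_min:
        raise ValueError("pool TIRs are all equal; uniformity is undefined")

    best: tuple[float, str] | None = None
    best_lib: SmartLibrary | None = None
    for cand in enumerate_feasible(sets, n):
        members = sorted(expand_degenerate(cand))
        tirs = [tir_by_seq[m] for m in members]
        if anchor == "pool":
            lo, hi = pool_min, pool_max
        else:
            lo, hi = min(tirs), max(tirs)
            if hi <= lo:
                continue  # degenerate anchor: all-equal TIRs cannot be scored
        score = uniformity_score(tirs, lo, hi)
        key = (score, cand.symbols)
        if best is None or key < best:
            best = key
            order = sorted(range(n), key=lambda i: (tirs[i], members[i]))
            best_lib = SmartLibrary(
                degenerate=cand,
                members=tuple(members[i] for i in order),
                tirs=tuple(tirs[i] for i in order),
                n=n,
                score=score,
                pool_min=lo,
                pool_max=hi,
            )
    if best_lib is None:
        raise ValueError(
            f"no feasible degenerate sequence: n={n} has no factorization "
            f"into per-position subset sizes <= {[len(s) for s in sets]}"
        )
    return best_lib
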