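"""MAGE oligonucleotide assembly around a degenerate RBS core.

A recombineering oligo carries the degenerate core flanked by concrete
homology arms copied from the (edited) genome.  Design concerns handled
here:

* window arithmetic — the RBS window is given in the biologist's
  convention (offsets like -15..-10 relative to the ORF start, where -1
  is the base immediately 5' of the start codon, counted on the coding
  strand) and converted to plus-strand genomic coordinates;
* concomitant deletions — when a regulatory element (e.g. a 220 bp FMN
  riboswitch) is removed in the same editing step, the homology arms are
  drawn from the post-deletion genome so the oligo spans the junction;
* replichore-aware strand choice — lambda-Red ssDNA incorporation is
  efficient only for the oligo annealing to the lagging-strand template,
  which flips between the two replichores (oriC -> dif arcs) of the
  circular chromosome.  Default rule: plus orientation on replichore 1,
  minus on replichore 2 (invertible via ``invert_strand_rule``);
* synthesis annotation — the first four 5' linkages are phosphorothioated
  to resist exonucleases, rendered as ``T*T*T*T*...``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .seq_core import (
    DegenerateSequence,
    reverse_complement_degenerate,
)

__all__ = [
    "RbsTarget",
    "MageOligo",
    "assign_replichore",
    "build_oligo",
    "format_oligo",
    "window_interval",
]

DEFAULT_TOTAL_LENGTH = 90
DEFAULT_PS_COUNT = 4


@dataclass(frozen=True)
class RbsTarget:
    """A chromosomal RBS engineering target.

    ``orf_start`` is the 0-based plus-strand coordinate of the first base
    of the start codon on the coding strand.  ``window_offsets`` use the
    display convention (e.g. ``(-15, -10)``): position -1 is the base
    immediately 5' of the start codon on the coding strand.  ``oriC`` and
    ``dif`` locate the replication origin and terminus for replichore
    assignment; either may be None if strand choice is made explicitly.
    """

    genome: str
    orf_start: int
    gene_strand: str = "+"
    window_offsets: tuple[int, int] = (-15, -10)
    oriC: Optional[int] = None
    dif: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gene_strand not in ("+", "-"):
            raise ValueError(f"gene_strand must be '+' or '-', got {self.gene_strand!r}")
        if not (0 <= self.orf_start < len(self.genome)):
            raise ValueError("orf_start outside genome")
        lo, hi = self.window_offsets
        if lo >= 0 or hi >= 0:
            raise ValueError(
                f"window offsets must be negative (upstream), got {self.window_offsets}"
            )

    @property
    def window_length(self) -> int:
        lo, hi = sorted(self.window_offsets)
        return hi - lo + 1


def window_interval(target: RbsTarget) -> tuple[int, int]:
    """Plus-strand 0-based half-open genomic interval of the RBS window."""
    a = max(abs(o) for o in target.window_offsets)  # farthest from start
    b = min(abs(o) for o in target.window_offsets)  # closest to start
    if target.gene_strand == "+":
        start, end = target.orf_start - a, target.orf_start - b + 1
    else:
        start, end = target.orf_start + b, target.orf_start + a + 1
    if start < 0 or end > len(target.genome):
        raise ValueError(
            f"window {start}..{end} falls outside the genome (len "
            f"{len(target.genome)}); wrap-around windows are not supported"
        )
    return start, end


def wild_core(target: RbsTarget) -> str:
    """The wild-type core on the coding strand."""
    s, e = window_interval(target)
    core = target.genome[s:e]
    if target.gene_strand == "-":
        core = reverse_complement_degenerate(core)
    return core


@dataclass(frozen=True)
class MageOligo:
    """A MAGE-ready oligo: concrete arms flanking a degenerate core.

    ``sequence`` is written 5'->3' in the emitted orientation;
    ``orientation`` says whether that equals the genomic plus strand or
    its reverse complement.  ``deletion`` records the genomic interval
    (0-based half-open, plus strand) removed concomitantly, if any.
    """

    sequence: str
    core: DegenerateSequence
    orientation: str
    replichore: Optional[int] = None
    phosphorothioate_count: int = DEFAULT_PS_COUNT
    deletion: Optional[tuple[int, int]] = None
    name: str = "oligo"

    def __post_init__(self) -> None:
        if self.orientation not in ("plus", "minus"):
            raise ValueError(f"orientation must be plus/minus, got {self.orientation!r}")
        if self.phosphorothioate_count < 0:
            raise ValueError("phosphorothioate count must be >= 0")

    @property
    def degeneracy(self) -> int:
        return self.core.degeneracy


def assign_replichore(pos: int, oriC: int, dif: int, genome_len: int) -> int:
    """Replichore of a genomic position on a circular chromosome.

    Replichore 1 is the arc traversed from oriC toward dif in increasing
    coordinate direction (modulo wrap); replichore 2 is the other arc.
    Boundary convention: pos == oriC -> 1, pos == dif -> 2.
    """
    for name, c in (("pos", pos), ("oriC", oriC), ("dif", dif)):
        if not (0 <= c < genome_len):
            raise ValueError(f"{name}={c} outside [0, {genome_len})")
    if oriC == dif:
        raise ValueError("oriC and dif coincide; replichores are undefined")
    d_pos = (pos - oriC) % genome_len
    d_dif = (dif - oriC) % genome_len
    return 1 if d_pos < d_dif else 2


def _circular_take(seq: str, start: int, length: int) -> str:
    """length characters of seq starting at start, wrapping circularly."""
    if length > len(seq):
        raise ValueError("arm longer than available sequence")
    out = []
    for k in range(length):
        out.append(seq[(start + k) % len(seq)])
    return "".join(out)


def build_oligo(
    target: RbsTarget,
    core: DegenerateSequence | str,
    *,
    arm_len: Optional[int] = None,
    total_length: int = DEFAULT_TOTAL_LENGTH,
    deletion: Optional[tuple[int, int]] = None,
    phosphorothioate_count: int = DEFAULT_PS_COUNT,
    invert_strand_rule: bool = False,
    orientation: Optional[str] = None,
    name: str = "oligo",
) -> MageOligo:
    """Assemble a MAGE oligo: homology arms around the degenerate core.

    The core is given in coding-strand sense (same sense as the wild
    core).  Arms are copied from the post-edit genome — with ``deletion``
    applied — so a concomitant deletion yields junction-spanning arms and
    the oligo length is 2*arm_len + len(core) regardless of deletion
    size.  If ``arm_len`` is omitted it is derived from ``total_length``
    (left arm takes the extra base when the split is odd).

    Orientation: if ``orientation`` is not forced, the replichore of the
    window start decides it — plus for replichore 1, minus for
    replichore 2 (the lagging-strand-annealing convention; flip with
    ``invert_strand_rule``).  Without oriC/dif coordinates the oligo is
    emitted in plus orientation.

    A deletion overlapping the window is an error; arms running into the
    ORF are permitted.
    """
    if isinstance(core, str):
        core = DegenerateSequence(core)
    ws, we = window_interval(target)
    if len(core) != we - ws:
        raise ValueError(
            f"core length {len(core)} != window length {we - ws}"
        )
    if deletion is not None:
        ds, de = deletion
        if not (0 <= ds < de <= len(target.genome)):
            raise ValueError(f"invalid deletion interval {deletion}")
        if ds < we and de > ws:
            raise ValueError(
                f"deletion {deletion} overlaps the RBS window ({ws}, {we})"
            )

    if arm_len is None:
        if total_length < len(core) + 2:
            raise ValueError(
                f"total_length {total_length} too short for core of "
                f"{len(core)} nt plus arms"
            )
        left_len = (total_length - len(core) + 1) // 2
        right_len = total_length - len(core) - left_len
    else:
        left_len = right_len = arm_len

    # Plus-strand sense of the core.
    core_plus = (
        core.symbols
        if target.gene_strand == "+"
        else reverse_complement_degenerate(core.symbols)
    )

    # Post-edit genome on the plus strand, tracking where the core sits.
    g = target.genome
    keep = [i for i in range(len(g)) if not (ws <= i < we)]
    if deletion is not None:
        ds, de = deletion
        keep = [i for i in keep if not (ds <= i < de)]
    # position in the edited string where the core is inserted
    n_before = sum(1 for i in keep if i < ws)
    edited = (
        "".join(g[i] for i in keep[:n_before])
        + core_plus
        + "".join(g[i] for i in keep[n_before:])
    )
    core_start = n_before
    core_end = n_before + len(core_plus)

    left = _circular_take(edited, core_start - left_len, left_len)
    right = _circular_take(edited, core_end, right_len)
    oligo_plus = left + core_plus + right

    repl: Optional[int] = None
    if target.oriC is not None and target.dif is not None:
        repl = assign_replichore(ws, target.oriC, target.dif, len(g))
    if orientation is None:
        if repl is None:
            orientation = "plus"
        else:
            orientation = "plus" if repl == 1 else "minus"
            if invert_strand_rule:
                orientation = "minus" if orientation == "plus" else "plus"

    seq = (
        oligo_plus
        if orientation == "plus"
        else reverse_complement_degenerate(oligo_plus)
    )
    emitted_core = (
        core_plus if orientation == "plus" else reverse_complement_degenerate(core_plus)
    )
    return MageOligo(
        sequence=seq,
        core=DegenerateSequence(emitted_core),
        orientation=orientation,
        replichore=repl,
        phosphorothioate_count=phosphorothioate_count,
        deletion=deletion,
        name=name,
    )


def format_oligo(o: MageOligo) -> str:
    """5'->3' synthesis string with '*' marking phosphorothioated bases.

    The first ``phosphorothioate_count`` 5' bases each carry a trailing
    '*' (a protected backbone linkage), e.g. ``T*T*T*T*ACGT...``.
    """
    n = o.phosphorothioate_count
    if n > len(o.sequence):
        raise ValueError(
            f"cannot phosphorothioate {n} bases of a {len(o.sequence)}-nt oligo"
        )
    return "".join(b + "*" for b in o.sequence[:n]) + o.sequence[n:]
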