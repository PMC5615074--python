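"""The GLOS rule: MMR-invisible degenerate library design.

MutS, the mismatch sensor of methyl-directed mismatch repair, does not
recognize heteroduplex mismatches longer than about 5 contiguous base
pairs.  The GLOS rule (genome library optimized sequences) exploits this:
if every library member differs from the wild type at >= 6 contiguous
positions, recombineering intermediates are invisible to MMR and the
library integrates without repair-driven sequence bias.

The candidate space is built by excluding, at every window position, the
wild-type base: an A becomes B (C/G/T), a C becomes D (A/G/T), a G
becomes H (A/C/T), a T becomes V (A/C/G).  A window of length L therefore
yields 3^L candidates, each mismatching the wild type across the full
window — e.g. 729 for a 6-nt window versus 4096 for full randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_core import (
    DegenerateSequence,
    expand_degenerate,
    longest_mismatch_run,
)

__all__ = ["GlosSpec", "glos_degenerate", "is_glos_compliant", "glos_candidates"]

_EXCLUSION = {"A": "B", "C": "D", "G": "H", "T": "V"}


@dataclass(frozen=True)
class GlosSpec:
    """A GLOS design problem: wild-type core window and minimum mismatch run.

    ``window_offsets`` records the display coordinates of the window
    relative to the ORF start (e.g. ``(-15, -10)``; position -1 is the
    base immediately 5' of the start codon).  They are carried for
    reporting; the rule itself operates on ``wild_core`` alone.
    """

    wild_core: str
    min_run: int = 6
    window_offsets: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if len(self.wild_core) < self.min_run:
            raise ValueError(
                f"window length {len(self.wild_core)} is shorter than "
                f"min_run {self.min_run}: the mismatch-run guarantee is "
                "unattainable"
            )
        if self.window_offsets is not None:
            lo, hi = self.window_offsets
            if abs(hi - lo) + 1 != len(self.wild_core):
                raise ValueError(
                    f"window offsets {self.window_offsets} span "
                    f"{abs(hi - lo) + 1} nt but wild_core has "
                    f"{len(self.wild_core)} nt"
                )


def glos_degenerate(wild_core: str) -> DegenerateSequence:
    """Per-position base-exclusion degenerate sequence for a wild-type core.

    At each position all bases except the original one are allowed
    (A->B, C->D, G->H, T->V), so the degeneracy is 3^len and every
    encoded member mismatches the wild type across the whole window.

    The wild type must be concrete; an ambiguous base has no well-defined
    exclusion set.
    """
    symbols = []
    for i, base in enumerate(wild_core):
        if base not in _EXCLUSION:
            raise ValueError(
                f"wild_core must be concrete A/C/G/T; found {base!r} at "
                f"position {i}"
            )
        symbols.append(_EXCLUSION[base])
    return DegenerateSequence("".join(symbols))


def exclusion_code(base: str) -> str:
    """IUPAC code of the 3-base complement set of a concrete base."""
    try:
        return _EXCLUSION[base]
    except KeyError:
        raise ValueError(f"not a concrete base: {base!r}") from None


def is_glos_compliant(member: str, spec: GlosSpec) -> bool:
    """True iff the member's mismatch run against the wild core reaches min_run."""
    if len(member) != len(spec.wild_core):
        raise ValueError(
            f"member length {len(member)} != wild_core length "
            f"{len(spec.wild_core)}"
        )
    return longest_mismatch_run(member, spec.wild_core) >= spec.min_run


def glos_candidates(spec: GlosSpec) -> set[str]:
    """The full GLOS candidate pool: 3^L concrete sequences, all compliant."""
    pool = expand_degenerate(glos_degenerate(spec.wild_core))
    # by construction every member mismatches at all L >= min_run positions
    return pool


def allowed_sets(spec: GlosSpec) -> list[frozenset[str]]:
    """Per-position allowed base sets of the GLOS candidate space."""
    from .seq_core import IUPAC_SETS

    return [IUPAC_SETS[exclusion_code(b)] for b in spec.wild_core]
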