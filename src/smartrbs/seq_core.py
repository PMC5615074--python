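"""IUPAC degenerate-sequence algebra, mismatch analysis, and sequence I/O.

A degenerate oligonucleotide is written as a string over the IUPAC
nucleotide alphabet; each symbol denotes a set of concrete bases
(e.g. ``B`` = {C,G,T}, ``D`` = {A,G,T}, ``N`` = {A,C,G,T}).  The library a
degenerate string encodes is the Cartesian product of its per-position
base sets.  Everything downstream — the GLOS rule, library reduction,
oligo assembly and the mismatch-repair model — builds on the primitives
here.

Sequences are uppercase DNA throughout; ``U`` is rejected.  Internal
coordinates are 0-based half-open on the plus strand; conversion to the
biologist's "-1 is the base immediately 5' of the start codon" display
convention happens only at interface layers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "IUPAC_SETS",
    "SET_TO_IUPAC",
    "DegenerateSequence",
    "MismatchProfile",
    "expand_degenerate",
    "degeneracy",
    "iupac_for_bases",
    "complement_degenerate",
    "reverse_complement_degenerate",
    "longest_mismatch_run",
    "mismatch_pairs",
    "read_fasta",
    "write_fasta",
    "read_sequence_table",
]

#: IUPAC code -> frozenset of concrete bases (DNA only, no gaps).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}

#: frozenset of concrete bases -> IUPAC code (inverse of IUPAC_SETS).
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_CONCRETE = frozenset("ACGT")


def _validate(symbols: str) -> None:
    for i, sym in enumerate(symbols):
        if sym not in IUPAC_SETS:
            raise ValueError(
                f"invalid IUPAC nucleotide symbol {sym!r} at position {i} "
                f"in {symbols!r}"
            )
    if not symbols:
        raise ValueError("empty sequence")


@dataclass(frozen=True)
class DegenerateSequence:
    """An IUPAC string with per-position base-set semantics.

    Parameters
    ----------
    symbols : str
        Uppercase IUPAC nucleotide string, e.g. ``"BDGGGW"``.

    Notes
    -----
    ``degeneracy`` (the product of per-position set sizes) equals the
    number of distinct concrete sequences the string encodes, and
    :func:`expand_degenerate` yields exactly that many.
    """

    symbols: str

    def __post_init__(self) -> None:
        _validate(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    @property
    def position_sets(self) -> list[frozenset[str]]:
        return [IUPAC_SETS[s] for s in self.symbols]

    @property
    def degeneracy(self) -> int:
        n = 1
        for s in self.position_sets:
            n *= len(s)
        return n

    def expand(self) -> set[str]:
        return expand_degenerate(self)

    def is_concrete(self) -> bool:
        return all(s in _CONCRETE for s in self.symbols)


def _as_symbols(d: DegenerateSequence | str) -> str:
    if isinstance(d, DegenerateSequence):
        return d.symbols
    _validate(d)
    return d


def degeneracy(d: DegenerateSequence | str) -> int:
    """Number of concrete sequences encoded: product of per-position set sizes."""
    symbols = _as_symbols(d)
    n = 1
    for sym in symbols:
        n *= len(IUPAC_SETS[sym])
    return n


def expand_degenerate(d: DegenerateSequence | str) -> set[str]:
    """All distinct concrete sequences encoded by a degenerate string.

    The cardinality of the result equals :func:`degeneracy`.
    """
    symbols = _as_symbols(d)
    sets = [sorted(IUPAC_SETS[sym]) for sym in symbols]
    return {"".join(combo) for combo in itertools.product(*sets)}


def iter_expand(d: DegenerateSequence | str) -> Iterator[str]:
    """Lazily iterate the concrete sequences (lexicographic order)."""
    symbols = _as_symbols(d)
    sets = [sorted(IUPAC_SETS[sym]) for sym in symbols]
    for combo in itertools.product(*sets):
        yield "".join(combo)


def iupac_for_bases(bases: Iterable[str]) -> str:
    """The single IUPAC code denoting exactly this base set."""
    key = frozenset(bases)
    if not key <= _CONCRETE or not key:
        raise ValueError(f"not a set of concrete DNA bases: {set(bases)!r}")
    return SET_TO_IUPAC[key]


def complement_degenerate(symbols: str) -> str:
    """IUPAC-aware complement (B<->V, D<->H, R<->Y, ...)."""
    _validate(symbols)
    return str(Seq(symbols).complement())


def reverse_complement_degenerate(symbols: str) -> str:
    """IUPAC-aware reverse complement."""
    _validate(symbols)
    return str(Seq(symbols).reverse_complement())


def _require_concrete(seq: str, name: str) -> None:
    for i, base in enumerate(seq):
        if base not in _CONCRETE:
            raise ValueError(
                f"{name} must be concrete A/C/G/T; found {base!r} at position {i}"
            )


def longest_mismatch_run(a: str, b: str) -> int:
    """Length of the longest run of consecutive positions where ``a[i] != b[i]``.

    Symmetric in its arguments and bounded above by the Hamming distance.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences must have equal length: {len(a)} vs {len(b)}"
        )
    best = run = 0
    for x, y in zip(a, b):
        if x != y:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


#: Default MutS-recognized mismatch set: every mismatch pair except C:C,
#: which escapes MutS surveillance.  Pairs are (oligo base, template base)
#: with template = complement of the wild-type top strand.
DEFAULT_RECOGNIZED_PAIRS: frozenset[tuple[str, str]] = frozenset(
    (o, t)
    for o in "ACGT"
    for t in "ACGT"
    if o != str(Seq(t).complement()) and (o, t) != ("C", "C")
)

#: Every mismatch pair, C:C included — the "all recognized" reference model.
ALL_MISMATCH_PAIRS: frozenset[tuple[str, str]] = frozenset(
    (o, t) for o in "ACGT" for t in "ACGT" if o != str(Seq(t).complement())
)


@dataclass(frozen=True)
class MismatchProfile:
    """Position-wise heteroduplex analysis of an oligo against the wild type.

    ``pairs[i]`` is ``(oligo_base, template_base)`` where the template is
    the complement of the wild-type top strand — the strand the MAGE oligo
    actually anneals to, so a C opposite a genomic G reads as the (C,C)
    pair that mismatch repair does not recognize.  ``recognized_mask``
    flags positions that are both mismatched and in the recognized-pair
    set; ``longest_recognized_run`` is the longest contiguous stretch of
    flagged positions, the quantity the MutS length cutoff acts on.
    """

    pairs: tuple[tuple[str, str], ...]
    recognized_mask: tuple[bool, ...]
    longest_recognized_run: int


def mismatch_pairs(
    oligo_core: str,
    wild_core: str,
    recognized: frozenset[tuple[str, str]] = DEFAULT_RECOGNIZED_PAIRS,
) -> MismatchProfile:
    """Heteroduplex mismatch profile of an oligo core against the wild core.

    Both inputs are concrete, top-strand sense, equal length.  A position
    is a match iff the oligo base equals the wild-type top-strand base;
    matches are never recognized.  A mismatch is recognized iff its
    (oligo, template) pair is in ``recognized`` (default: all mismatch
    pairs except (C,C)).
    """
    if len(oligo_core) != len(wild_core):
        raise ValueError(
            f"sequences must have equal length: {len(oligo_core)} vs "
            f"{len(wild_core)}"
        )
    _require_concrete(oligo_core, "oligo_core")
    _require_concrete(wild_core, "wild_core")

    pairs = []
    mask = []
    for o, w in zip(oligo_core, wild_core):
        template = str(Seq(w).complement())
        pairs.append((o, template))
        mask.append(o != w and (o, template) in recognized)

    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)

    return MismatchProfile(tuple(pairs), tuple(mask), best)


# ---------------------------------------------------------------------------
# I/O primitives
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ValueError(f"RNA (U) not supported in record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_sequence_table(
    path: str | Path, value_column: str | None = None
) -> pd.DataFrame:
    """Read a CSV of sequences with an optional numeric column.

    Requires a ``sequence`` column; if ``value_column`` is given (e.g.
    ``"tir"`` or ``"count"``) it must be present and parse as numeric.
    Sequences are upper-cased and validated as IUPAC.
    """
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sequence'")
    df["sequence"] = df["sequence"].astype(str).str.upper()
    for seq in df["sequence"]:
        _validate(seq)
    if value_column is not None:
        if value_column not in df.columns:
            raise ValueError(f"{path}: missing required column {value_column!r}")
        df[value_column] = pd.to_numeric(df[value_column])
    return df
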