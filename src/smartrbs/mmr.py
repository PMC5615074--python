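"""Mismatch-repair-dependent library attrition and CRISPR counterselection.

After a recombineering oligo anneals, the cell sees a heteroduplex whose
mismatched stretch MutS may recognize and revert.  Recognition falls off
with mismatch length and is abolished beyond ~5 contiguous mismatches, so
a library whose every member carries a >= 6 bp contiguous mismatch passes
through an MMR-proficient strain unscathed — the property this simulator
demonstrates as an exact identity of its expectation mode.

Model per clone: an oligo member i is drawn from the pool frequencies
f_i; it integrates with probability beta; if integrated, MMR reverts it
with a probability set by the lengths of its contiguous mismatch runs
against the wild core (a run of only C:C pairs escapes recognition
entirely, by default); clones still wild type at the protospacer are
killed by Cas9 counterselection with probability kappa.  Expectation mode evaluates the
resulting composition in closed form; sampled mode draws clones with a
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .seq_core import DEFAULT_RECOGNIZED_PAIRS, mismatch_pairs

__all__ = [
    "RepairModel",
    "EditingOutcome",
    "repair_probability",
    "member_repair_probability",
    "simulate_editing",
    "DEFAULT_REPAIR_TABLE",
]

#: Illustrative default repair probabilities per recognized-mismatch run
#: length.  The length dependence (monotone decay, zero at >= 6 bp) is the
#: established MutS behavior; the specific rates are placeholders for
#: demonstration and should be replaced by user tables when rates matter.
DEFAULT_REPAIR_TABLE: dict[int, float] = {1: 0.9, 2: 0.8, 3: 0.6, 4: 0.4, 5: 0.2, 6: 0.0}


@dataclass(frozen=True)
class RepairModel:
    """Repair probability as a function of recognized-mismatch run length.

    Lookup clamps to the largest tabulated key (so any L >= 6 maps to the
    value at 6, which is 0 under the default — the MutS length cutoff).
    L = 0 means no recognized mismatch and returns 0: there is nothing to
    revert.  A non-monotone user table is accepted but flagged.
    """

    table: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_REPAIR_TABLE))
    recognized_pairs: frozenset[tuple[str, str]] = DEFAULT_RECOGNIZED_PAIRS

    def __post_init__(self) -> None:
        if not self.table:
            raise ValueError("empty repair table")
        for L, p in self.table.items():
            if L < 1:
                raise ValueError(f"run length keys must be >= 1, got {L}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"repair probability {p} for L={L} outside [0,1]")
        keys = sorted(self.table)
        vals = [self.table[k] for k in keys]
        object.__setattr__(
            self, "_monotone", all(a >= b for a, b in zip(vals, vals[1:]))
        )

    @property
    def is_monotone(self) -> bool:
        return self._monotone  # type: ignore[attr-defined]

    def probability(self, run_length: int) -> float:
        return repair_probability(run_length, self)


def repair_probability(run_length: int, model: RepairModel) -> float:
    """P(MMR reverts the edit) for a recognized-mismatch run of given length."""
    if run_length < 0:
        raise ValueError("run length must be >= 0")
    if run_length == 0:
        return 0.0
    keys = sorted(model.table)
    if run_length in model.table:
        return model.table[run_length]
    if run_length > keys[-1]:
        return model.table[keys[-1]]
    # below the smallest tabulated key or in a gap: use nearest lower key,
    # falling back to the smallest key's value
    lower = [k for k in keys if k < run_length]
    return model.table[lower[-1]] if lower else model.table[keys[0]]


@dataclass(frozen=True)
class EditingOutcome:
    """Library composition after editing, repair and counterselection.

    ``frequencies`` are overall normalized masses per member and sum with
    ``wild_fraction`` to 1.  ``member_frequencies`` are conditional on
    carrying a library allele (sum to 1 whenever any mutant survives);
    at full counterselection the two coincide.  ``ar_efficiency`` is the
    allelic-replacement efficiency: the fraction of surviving clones that
    carry a library allele rather than wild type.
    """

    members: tuple[str, ...]
    frequencies: tuple[float, ...]
    wild_fraction: float
    ar_efficiency: float
    mode: str
    n_clones: Optional[int] = None
    seed: Optional[int] = None

    @property
    def member_frequencies(self) -> tuple[float, ...]:
        total = sum(self.frequencies)
        if total == 0:
            return tuple(0.0 for _ in self.frequencies)
        return tuple(f / total for f in self.frequencies)

    @property
    def diversity(self) -> int:
        """Number of members with nonzero (expected or observed) mass."""
        return sum(1 for f in self.frequencies if f > 0)


def member_repair_probability(member: str, wild: str, model: RepairModel) -> float:
    """P(MMR reverts a heteroduplex carrying this member) against the wild core.

    The heteroduplex decomposes into maximal contiguous mismatch runs —
    the bubbles MutS actually encounters.  A run is recognizable at its
    full length iff it contains at least one recognized pair (a bubble
    of only C:C pairs is invisible), and each recognizable run is
    repaired independently with the length-dependent probability, so a
    >= 6 bp run contributes nothing under the default table.  The member
    survives only if no run is repaired.
    """
    profile = mismatch_pairs(member, wild, model.recognized_pairs)
    is_mismatch = [o != w for o, w in zip(member, wild)]
    p_keep = 1.0
    i = 0
    n = len(member)
    while i < n:
        if not is_mismatch[i]:
            i += 1
            continue
        j = i
        while j < n and is_mismatch[j]:
            j += 1
        run_recognized = any(profile.recognized_mask[k] for k in range(i, j))
        length = (j - i) if run_recognized else 0
        p_keep *= 1.0 - repair_probability(length, model)
        i = j
    return 1.0 - p_keep


def simulate_editing(
    pool_freqs: Mapping[str, float],
    wild: str,
    model: RepairModel | None = None,
    *,
    beta: float = 1.0,
    kappa: float = 1.0,
    mode: str = "expectation",
    seed: Optional[int] = None,
    n_clones: Optional[int] = None,
) -> EditingOutcome:
    """Predict post-editing composition and AR efficiency.

    Parameters
    ----------
    pool_freqs : mapping member -> frequency (sums to 1)
        Oligo pool composition before editing.
    wild : str
        Wild-type core (top-strand sense, same length as members).
    model : RepairModel
        Length-dependent repair probabilities; default table with the
        C:C-exempt recognized-pair set.
    beta : float
        Integration probability per clone.
    kappa : float
        Counterselection kill probability for clones wild type at the
        protospacer.
    mode : "expectation" | "sampled"
        Closed-form expected composition, or seeded per-clone sampling
        (``n_clones`` surviving clones are collected; killed clones are
        redrawn).

    In expectation mode the unnormalized member mass is
    ``m_i = beta * f_i * (1 - p_i)`` with p_i the member's repair
    probability (:func:`member_repair_probability`), the wild mass is
    ``(1 - sum_i m_i) * (1 - kappa)``, and
    AR = sum(m_i) / (sum(m_i) + wild).
    """
    if model is None:
        model = RepairModel()
    if not (0.0 <= beta <= 1.0) or not (0.0 <= kappa <= 1.0):
        raise ValueError("beta and kappa must lie in [0, 1]")
    members = sorted(pool_freqs)
    freqs = np.array([pool_freqs[m] for m in members], dtype=float)
    if freqs.min() < 0:
        raise ValueError("negative pool frequency")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"pool frequencies sum to {freqs.sum()}, not 1")

    p_rep = np.array(
        [member_repair_probability(m, wild, model) for m in members]
    )

    if mode == "expectation":
        masses = beta * freqs * (1.0 - p_rep)
        wild_mass = (1.0 - masses.sum()) * (1.0 - kappa)
        total = masses.sum() + wild_mass
        if total <= 0:
            raise ValueError(
                "no surviving clones: integration impossible (beta=0) and "
                "counterselection total (kappa=1)"
            )
        return EditingOutcome(
            members=tuple(members),
            frequencies=tuple(masses / total),
            wild_fraction=float(wild_mass / total),
            ar_efficiency=float(masses.sum() / total),
            mode="expectation",
        )

    if mode != "sampled":
        raise ValueError(f"mode must be 'expectation' or 'sampled', got {mode!r}")
    if n_clones is None or n_clones < 1:
        raise ValueError("sampled mode requires n_clones >= 1")
    p_survive_mutant = beta * float((freqs * (1.0 - p_rep)).sum())
    p_survive_wild = (1.0 - p_survive_mutant) * (1.0 - kappa)
    if p_survive_mutant + p_survive_wild <= 0:
        raise ValueError(
            "no surviving clones: integration impossible (beta=0) and "
            "counterselection total (kappa=1)"
        )
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(members), dtype=int)
    wild_count = 0
    collected = 0
    while collected < n_clones:
        i = rng.choice(len(members), p=freqs)
        allele_is_member = rng.random() < beta and rng.random() >= p_rep[i]
        if allele_is_member:
            counts[i] += 1
            collected += 1
        else:
            if rng.random() < kappa:
                continue  # killed; redraw
            wild_count += 1
            collected += 1
    total = counts.sum() + wild_count
    return EditingOutcome(
        members=tuple(members),
        frequencies=tuple(counts / total),
        wild_fraction=float(wild_count / total),
        ar_efficiency=float(counts.sum() / total),
        mode="sampled",
        n_clones=n_clones,
        seed=seed,
    )
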