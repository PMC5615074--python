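"""Translation-initiation-rate models for candidate RBS cores.

Real designs use TIR predictions from an external thermodynamic
calculator (e.g. the Salis RBS Calculator in library mode); this module
ingests such predictions as a CSV table and answers lookups from it.
Table mode is authoritative for real use.

A built-in proxy mode exists so the whole pipeline runs and is testable
with no external tool: it scores a core by the length of its longest
common substring with an anti-Shine-Dalgarno consensus (default AGGAGG),
``TIR = exp(alpha * m)``.  The proxy is monotone in SD-likeness but is
NOT a free-energy model — no 16S hybridization energetics, standby sites
or spacing penalties — and is clearly a stand-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .seq_core import read_sequence_table

__all__ = ["TirModel", "load_tir_table", "sd_proxy_tir", "longest_common_substring"]

DEFAULT_ANTI_SD = "AGGAGG"


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous substring common to a and b."""
    if not a or not b:
        return 0
    # classic DP, fine at oligo scale
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def sd_proxy_tir(core: str, consensus: str = DEFAULT_ANTI_SD, alpha: float = 1.0) -> float:
    """Proxy TIR: exp(alpha * longest common substring with the SD consensus).

    Strictly positive and monotone in the match length m; insensitive to
    bases outside the matched substring (a documented limitation of the
    proxy).  m = 0 gives exp(0) = 1.
    """
    m = longest_common_substring(core, consensus)
    return math.exp(alpha * m)


@dataclass
class TirModel:
    """Mapping from concrete core sequences to predicted TIRs.

    mode ``"table"``: answers exactly the sequences in ``table``;
    anything else fails loudly.  mode ``"proxy"``: answers any concrete
    core via :func:`sd_proxy_tir`.
    """

    mode: str = "table"
    table: dict[str, float] = field(default_factory=dict)
    consensus: str = DEFAULT_ANTI_SD
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("table", "proxy"):
            raise ValueError(f"unknown TirModel mode {self.mode!r}")
        for seq, tir in self.table.items():
            if tir <= 0:
                raise ValueError(f"non-positive TIR {tir} for sequence {seq!r}")

    def predict(self, core: str) -> float:
        """Deterministic positive TIR for a concrete core."""
        if self.mode == "proxy":
            return sd_proxy_tir(core, self.consensus, self.alpha)
        try:
            return self.table[core]
        except KeyError:
            raise KeyError(
                f"sequence {core!r} not covered by the TIR table "
                f"({len(self.table)} entries)"
            ) from None

    def predict_many(self, cores: list[str]) -> list[float]:
        return [self.predict(c) for c in cores]

    @classmethod
    def proxy(cls, consensus: str = DEFAULT_ANTI_SD, alpha: float = 1.0) -> "TirModel":
        return cls(mode="proxy", consensus=consensus, alpha=alpha)


def predict(model: TirModel, core: str) -> float:
    """Functional alias for :meth:`TirModel.predict`."""
    return model.predict(core)


def load_tir_table(path: str | Path) -> TirModel:
    """Build a table-mode model from a CSV with columns ``sequence,tir``.

    Sequences must be of uniform length; TIRs must be positive; a
    sequence listed twice with conflicting TIRs is an error (exact
    duplicates are tolerated and collapsed).
    """
    df = read_sequence_table(path, value_column="tir")
    if df.empty:
        raise ValueError(f"{path}: empty TIR table")
    lengths = df["sequence"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError(
            f"{path}: sequences of non-uniform length {sorted(lengths)}"
        )
    table: dict[str, float] = {}
    for seq, tir in zip(df["sequence"], df["tir"]):
        tir = float(tir)
        if tir <= 0:
            raise ValueError(f"{path}: non-positive TIR {tir} for {seq!r}")
        if seq in table and table[seq] != tir:
            raise ValueError(
                f"{path}: duplicate sequence {seq!r} with conflicting TIRs "
                f"{table[seq]} and {tir}"
            )
        table[seq] = tir
    return TirModel(mode="table", table=table)
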