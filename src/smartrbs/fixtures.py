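"""Seeded synthetic data: loci, TIR tables, clone read sets, pool abundances.

Everything the pipeline consumes can be generated here so the whole
workflow — design, reduction, oligo assembly, attrition simulation, QC —
runs end to end with no external downloads or tools.  All generators are
deterministic under a fixed seed (byte-identical outputs).

The generators emulate the shape of real experiments: a locus with an
ORF and an upstream RBS window; a TIR table as an external calculator
would produce (log-uniform rates over a span of orders of magnitude, the
typical dynamic range of RBS strength); Sanger-style clone read sets
with wild-type contamination and synthesis indels; and skewed oligo-pool
abundances (Dirichlet-distributed, emulating synthesis bias).  They do
not emulate sequencing error profiles, chromatograms or quality scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .seq_core import reverse_complement_degenerate

__all__ = ["FixtureSpec", "gen_locus", "gen_tir_table", "gen_clones", "gen_pool_abundance"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study, mirroring the real experiments.

    Defaults follow the experimental setup being emulated: a 6-nt RBS
    window at offsets -15..-10, 18-member libraries, 96 Sanger clones per
    replicate, TIRs spanning three orders of magnitude (log-uniform on
    [10, 10000] arbitrary calculator units).  ``wild_fraction`` and
    ``indel_rate`` describe clone-set contamination; ``dirichlet_alpha``
    sets pool-abundance skew (large = near-uniform, small = skewed).
    """

    seed: int = 0
    genome_length: int = 4000
    orf_start: int = 2000
    gene_strand: str = "+"
    window_offsets: tuple[int, int] = (-15, -10)
    library_size: int = 18
    tir_lo: float = 10.0
    tir_hi: float = 10_000.0
    n_clones: int = 96
    wild_fraction: float = 0.1
    indel_rate: float = 0.02
    dirichlet_alpha: float = 20.0

    def __post_init__(self) -> None:
        for name in ("wild_fraction", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.wild_fraction + self.indel_rate > 1.0:
            raise ValueError("wild_fraction + indel_rate exceed 1")
        if self.tir_lo >= self.tir_hi:
            raise ValueError("tir_lo must be < tir_hi")


def _rng(spec: FixtureSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def gen_locus(spec: FixtureSpec) -> tuple[dict[str, str], dict]:
    """Random genome with an annotated ORF and RBS window.

    Returns ``({record_id: sequence}, target_config)`` where the config
    carries orf_start, strand, window offsets and the wild-type core on
    the coding strand.  Deterministic under the spec's seed.
    """
    rng = _rng(spec, 1)
    bases = np.array(list("ACGT"))
    genome = "".join(rng.choice(bases, size=spec.genome_length))
    # plant a start codon at the ORF position on the coding strand
    if spec.gene_strand == "+":
        if spec.orf_start + 3 > spec.genome_length:
            raise ValueError("ORF start too close to the genome end")
        genome = genome[: spec.orf_start] + "ATG" + genome[spec.orf_start + 3 :]
    else:
        if spec.orf_start - 2 < 0:
            raise ValueError("ORF start too close to the genome start")
        genome = genome[: spec.orf_start - 2] + "CAT" + genome[spec.orf_start + 1 :]

    a = max(abs(o) for o in spec.window_offsets)
    b = min(abs(o) for o in spec.window_offsets)
    if spec.gene_strand == "+":
        ws, we = spec.orf_start - a, spec.orf_start - b + 1
        core = genome[ws:we]
    else:
        ws, we = spec.orf_start + b, spec.orf_start + a + 1
        core = reverse_complement_degenerate(genome[ws:we])
    if ws < 0 or we > spec.genome_length:
        raise ValueError("RBS window outside genome")

    target = {
        "orf_start": spec.orf_start,
        "gene_strand": spec.gene_strand,
        "window_offsets": list(spec.window_offsets),
        "wild_core": core,
    }
    return {"synthetic_locus": genome}, target


def gen_tir_table(pool: Iterable[str], spec: FixtureSpec) -> pd.DataFrame:
    """One log-uniform TIR per pool member (columns ``sequence,tir``)."""
    pool = sorted(set(pool))
    if not pool:
        raise ValueError("empty pool")
    rng = _rng(spec, 2)
    logs = rng.uniform(np.log10(spec.tir_lo), np.log10(spec.tir_hi), size=len(pool))
    return pd.DataFrame({"sequence": pool, "tir": 10.0 ** logs})


def gen_pool_abundance(members: Iterable[str], spec: FixtureSpec) -> pd.DataFrame:
    """Dirichlet-skewed synthesis-pool abundances (columns ``sequence,count``)."""
    members = sorted(set(members))
    rng = _rng(spec, 3)
    props = rng.dirichlet([spec.dirichlet_alpha] * len(members))
    counts = rng.multinomial(100_000, props)
    return pd.DataFrame({"sequence": members, "count": counts})


def _make_indel(core: str, rng: np.random.Generator) -> str:
    """Single-base insertion or deletion within the core."""
    if rng.random() < 0.5 and len(core) > 1:
        i = int(rng.integers(len(core)))
        return core[:i] + core[i + 1 :]
    i = int(rng.integers(len(core) + 1))
    base = "ACGT"[int(rng.integers(4))]
    return core[:i] + base + core[i:]


def gen_clones(
    member_freqs: dict[str, float],
    wild: str,
    spec: FixtureSpec,
    n_clones: Optional[int] = None,
) -> pd.DataFrame:
    """Synthetic clone genotyping reads (column ``read_core``).

    Each clone is wild type with probability ``wild_fraction``, an indel
    read (single-base insertion or deletion of a drawn member) with
    probability ``indel_rate``, and otherwise a library member drawn
    from ``member_freqs``.  Deterministic under the spec's seed.
    """
    freqs = np.array(list(member_freqs.values()), dtype=float)
    members = list(member_freqs)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"member frequencies sum to {freqs.sum()}, not 1")
    n = n_clones if n_clones is not None else spec.n_clones
    rng = _rng(spec, 4)
    reads = []
    for _ in range(n):
        u = rng.random()
        if u < spec.wild_fraction:
            reads.append(wild)
        elif u < spec.wild_fraction + spec.indel_rate:
            base = members[int(rng.choice(len(members), p=freqs))]
            reads.append(_make_indel(base, rng))
        else:
            reads.append(members[int(rng.choice(len(members), p=freqs))])
    return pd.DataFrame({"read_core": reads})
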