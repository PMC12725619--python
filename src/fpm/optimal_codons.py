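"""Optimal-codon usage deviation: the D statistic and positional trends.

For a list of codons and a table of synonymous blocks with one nominated
optimal codon each, count per degeneracy class d the qualifying codons T_d
and optimal codons O_d. Under proportional use the optimal codon would
appear T_d/d times, so the deviation is

    D_d = (O_d - T_d/d) / (T_d/d)

and the block-degeneracy-weighted mean D = sum(D_d * T_d) / sum(T_d) over
classes with T_d > 0. D is insensitive to sample size and to codons outside
the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import stats

from ._codons import CODON_TO_AA, codons_of


@dataclass(frozen=True)
class CodonBlock:
    block_id: str
    codons: tuple[str, ...]
    optimal: str
    degeneracy: int
    optimal_ending: str  # "AT" or "GC"

    def __post_init__(self):
        if self.optimal not in self.codons:
            raise ValueError(f"{self.block_id}: optimal codon not in block")
        if len(self.codons) != self.degeneracy:
            raise ValueError(f"{self.block_id}: degeneracy != block size")
        aas = {CODON_TO_AA.get(c) for c in self.codons}
        if len(aas) != 1 or None in aas:
            raise ValueError(f"{self.block_id}: block codons are not synonymous")


@dataclass(frozen=True)
class OptimalCodonTable:
    blocks: tuple[CodonBlock, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for b in self.blocks:
            if seen & set(b.codons):
                raise ValueError("blocks overlap")
            seen.update(b.codons)

    @property
    def codon_to_block(self) -> dict[str, CodonBlock]:
        return {c: b for b in self.blocks for c in b.codons}

    @classmethod
    def from_yaml(cls, path) -> "OptimalCodonTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        blocks = tuple(
            CodonBlock(
                block_id=b["block_id"],
                codons=tuple(b["codons"]),
                optimal=b["optimal"],
                degeneracy=int(b["degeneracy"]),
                optimal_ending="AT" if b["optimal"][-1] in "AT" else "GC",
            )
            for b in raw["blocks"]
        )
        return cls(blocks)

    @classmethod
    def example(cls, species: str) -> "OptimalCodonTable":
        """Load a shipped synthetic example table ('ecoli' or 'bsubtilis')."""
        name = f"{species}_optimal_codons_synthetic.yaml"
        with resources.as_file(resources.files("fpm.data").joinpath(name)) as p:
            return cls.from_yaml(p)


@dataclass(frozen=True)
class DeviationResult:
    per_degeneracy: dict[int, tuple[int, int, float]]  # d -> (O_d, T_d, D_d)
    weighted_mean_D: float


def usage_deviation(codons, table: OptimalCodonTable) -> DeviationResult:
    """D_d per degeneracy class and the T_d-weighted mean D.

    Codons not in any block are ignored. Raises if no qualifying codons at
    all (the weighted mean is undefined).
    """
    lookup = table.codon_to_block
    counts: dict[int, list[int]] = {}
    for codon in codons:
        block = lookup.get(codon)
        if block is None:
            continue
        o_t = counts.setdefault(block.degeneracy, [0, 0])
        o_t[1] += 1
        if codon == block.optimal:
            o_t[0] += 1
    per = {}
    num = den = 0.0
    for d, (o, t) in sorted(counts.items()):
        if t == 0:
            continue
        expected = t / d
        dd = (o - expected) / expected
        per[d] = (o, t, dd)
        num += dd * t
        den += t
    if den == 0:
        raise ValueError("no qualifying codons: weighted mean D undefined")
    return DeviationResult(per, num / den)


def deviation_by_position(cds_set, table: OptimalCodonTable, max_codon=150):
    """Weighted-mean D at each codon position 2..max_codon+1.

    Codons are pooled across genes at each position; genes shorter than
    3*(max_codon+1) bases are excluded so every position has the same gene
    denominator.
    """
    min_len = 3 * (max_codon + 1)
    records = [
        r for r in cds_set if getattr(r, "valid", True) and len(r.sequence) >= min_len
    ]
    if not records:
        raise ValueError("no genes long enough for requested max_codon")
    positions = list(range(2, max_codon + 2))
    values = []
    for pos in positions:
        pooled = [r.sequence[3 * (pos - 1) : 3 * pos] for r in records]
        values.append(usage_deviation(pooled, table).weighted_mean_D)
    from .positional_profiles import PositionalProfile

    n = len(records)
    return PositionalProfile(
        np.asarray(positions),
        np.asarray(values),
        np.full(len(positions), np.nan),
        np.full(len(positions), n, dtype=int),
    )


@dataclass(frozen=True)
class BlockTrend:
    block_id: str
    optimal_ending: str
    slope_5prime: float
    p_5prime: float
    slope_downstream: float
    p_downstream: float
    success_5prime: bool  # AT-ending & negative slope, or GC-ending & positive


def _slope_p(positions, usage):
    if len(positions) < 3 or np.allclose(usage, usage[0]):
        return 0.0, 1.0
    slope = stats.linregress(positions, usage).slope
    r, p = stats.pearsonr(positions, usage)
    return float(slope), float(p)


def block_slope_classification(cds_set, table: OptimalCodonTable, boundary_codon=11, max_codon=150):
    """Per-block relative-usage slope in the 5' window and downstream.

    Relative usage at a position is (optimal count)/(qualifying count) for
    the block. The 5' window is codon positions 2..boundary_codon ("the
    first 10 codons" with the default boundary of 11); downstream is
    everything after, up to max_codon. A block's 5' trend counts as a
    success for the nucleotide-content model when an A/T-ending optimal
    codon has a negative slope or a G/C-ending one a positive slope.
    """
    min_len = 3 * (max_codon + 1)
    records = [
        r for r in cds_set if getattr(r, "valid", True) and len(r.sequence) >= min_len
    ]
    if not records:
        raise ValueError("no genes long enough for requested max_codon")
    positions = np.arange(2, max_codon + 1)
    per_block_usage: dict[str, dict[int, tuple[int, int]]] = {b.block_id: {} for b in table.blocks}
    lookup = table.codon_to_block
    pooled: dict[int, list[str]] = {
        int(p): [r.sequence[3 * (p - 1) : 3 * p] for r in records] for p in positions
    }
    for p, codons in pooled.items():
        for codon in codons:
            block = lookup.get(codon)
            if block is None:
                continue
            o, t = per_block_usage[block.block_id].get(p, (0, 0))
            per_block_usage[block.block_id][p] = (o + (codon == block.optimal), t + 1)

    trends, excluded = [], []
    for block in table.blocks:
        usage = per_block_usage[block.block_id]
        pts = [(p, o / t) for p, (o, t) in sorted(usage.items()) if t > 0]
        five = [(p, u) for p, u in pts if p <= boundary_codon]
        down = [(p, u) for p, u in pts if p > boundary_codon]
        if len(five) < 3 or len(down) < 3:
            excluded.append(block.block_id)
            continue
        s5, p5 = _slope_p(*map(np.asarray, zip(*five)))
        sd, pd = _slope_p(*map(np.asarray, zip(*down)))
        success = (block.optimal_ending == "AT" and s5 < 0) or (
            block.optimal_ending == "GC" and s5 > 0
        )
        trends.append(BlockTrend(block.block_id, block.optimal_ending, s5, p5, sd, pd, success))
    return trends, excluded
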