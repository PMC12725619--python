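"""Per-codon-position synonymous/non-synonymous rate estimation.

Pipeline: three-way codon-aligned orthologs (focal, sister, outgroup) ->
2-of-3 parsimony ancestor per codon column -> pooled (focal, ancestor) codon
pairs per position -> Nei-Gojobori (1986) counting with equal-weight
averaging over minimal mutational pathways (paths through stop codons
excluded) and Jukes-Cantor distance correction,

    K = -3/4 * ln(1 - 4p/3),

which saturates at p >= 3/4. Columns where all three species carry distinct
codons are excluded (ancestor ambiguous), as are columns with gaps or
non-canonical bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from ._codons import BASES, CODON_TO_AA, FOURFOLD_CODONS, SENSE_CODONS, STOP_CODONS

EXCLUDE = "EXCLUDE"
EXCLUDE_INVALID = "EXCLUDE_INVALID"


@dataclass(frozen=True)
class OrthologTriple:
    ortholog_id: str
    focal: str
    sister: str
    outgroup: str

    def __post_init__(self):
        if not (len(self.focal) == len(self.sister) == len(self.outgroup)):
            raise ValueError(f"{self.ortholog_id}: aligned lengths differ")
        if len(self.focal) % 3 != 0:
            raise ValueError(f"{self.ortholog_id}: alignment length not a multiple of 3")


@dataclass(frozen=True)
class CodonColumnSet:
    position: int
    pairs: tuple[tuple[str, str], ...]  # (focal, ancestor)
    n_excluded_all_different: int
    n_excluded_invalid: int = 0


@dataclass(frozen=True)
class RateEstimate:
    position: int
    ks: float
    ka: float
    ka_over_ks: float | None
    n_codons: int
    saturated: bool = False


# ---------------------------------------------------------------------------
# NG86 lookup tables, built once at import


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of a codon (changes to stops count non-synonymous)."""
    s = 0.0
    aa = CODON_TO_AA[codon]
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA.get(alt) == aa:
                s += 1 / 3
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in SENSE_CODONS}


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, non-synonymous) differences over minimal pathways.

    Each ordering of the differing sites is one pathway; pathways passing
    through a stop codon are dropped (all retained ones weighted equally).
    If every pathway is blocked, all are used as a fallback.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        sd = sum(CODON_TO_AA.get(a) == CODON_TO_AA.get(b) for a, b in steps)
        paths.append((blocked, sd, len(steps) - sd))
    open_paths = [(s, n) for b, s, n in paths if not b] or [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


_PATHS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_counts(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    if key not in _PATHS:
        _PATHS[key] = _path_counts(c1, c2)
    return _PATHS[key]


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion of differences at or beyond JC saturation (p >= 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# ancestor inference and column extraction


def infer_ancestor(column) -> str:
    """2-of-3 parsimony ancestor for a (focal, sister, outgroup) codon column."""
    focal, sister, outgroup = (c.upper() for c in column)
    for c in (focal, sister, outgroup):
        if len(c) != 3 or any(b not in "ACGT" for b in c):
            return EXCLUDE_INVALID
    if sister == focal or sister == outgroup:
        return sister
    if focal == outgroup:
        return focal
    return EXCLUDE


def _drop_focal_indels(triple: OrthologTriple) -> OrthologTriple:
    keep = []
    for i in range(0, len(triple.focal), 3):
        if "-" not in triple.focal[i : i + 3]:
            keep.append(i)
    join = lambda s: "".join(s[i : i + 3] for i in keep)
    return OrthologTriple(triple.ortholog_id, join(triple.focal), join(triple.sister), join(triple.outgroup))


def extract_codon_columns(
    triples, position: int, min_len_codons: int = 180, fourfold_only: bool = False,
    drop_focal_indels: bool = False,
) -> CodonColumnSet:
    """Pooled (focal, ancestor) codon pairs at one alignment codon position.

    Orthologs whose ungapped focal CDS is shorter than ``min_len_codons``
    contribute nothing. With ``fourfold_only`` a pair is kept only when both
    codons are 4-fold degenerate and encode the same amino acid.
    """
    pairs = []
    n_all_diff = n_invalid = 0
    for t in triples:
        if drop_focal_indels:
            t = _drop_focal_indels(t)
        if (len(t.focal) - t.focal.count("-")) // 3 < min_len_codons:
            continue
        i = 3 * (position - 1)
        if i + 3 > len(t.focal):
            continue
        col = (t.focal[i : i + 3], t.sister[i : i + 3], t.outgroup[i : i + 3])
        anc = infer_ancestor(col)
        if anc == EXCLUDE:
            n_all_diff += 1
            continue
        if anc == EXCLUDE_INVALID:
            n_invalid += 1
            continue
        focal = col[0]
        if focal in STOP_CODONS or anc in STOP_CODONS:
            n_invalid += 1
            continue
        if fourfold_only:
            if focal not in FOURFOLD_CODONS or anc not in FOURFOLD_CODONS:
                continue
            if CODON_TO_AA[focal] != CODON_TO_AA[anc]:
                continue
        pairs.append((focal, anc))
    return CodonColumnSet(position, tuple(pairs), n_all_diff, n_invalid)


# ---------------------------------------------------------------------------
# counting estimator


def counting_rates(pairs, position: int = 0) -> RateEstimate:
    """NG86 Ks/Ka over a pooled list of (focal, ancestor) codon pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no codon pairs")
    S = N = Sd = Nd = 0.0
    for c1, c2 in pairs:
        S += (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2
        N += 3 - (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2
        sd, nd = _pair_counts(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return RateEstimate(position, math.nan, math.nan, None, len(pairs), saturated=True)
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return RateEstimate(position, ks, ka, (ka / ks if ks > 0 else None), len(pairs))


def positional_rate_profile(
    triples, max_position: int = 150, fourfold_only: bool = False,
    min_len_codons: int = 180, non_overlapping_ids=None, drop_focal_indels: bool = False,
) -> list[RateEstimate]:
    """One RateEstimate per codon position 2..max_position+1.

    ``non_overlapping_ids``, when given, restricts the analysis to orthologs
    whose id is in the set (the 5'-overlap filter).
    """
    triples = list(triples)
    if non_overlapping_ids is not None:
        triples = [t for t in triples if t.ortholog_id in non_overlapping_ids]
    out = []
    for pos in range(2, max_position + 2):
        cols = extract_codon_columns(
            triples, pos, min_len_codons, fourfold_only, drop_focal_indels
        )
        if not cols.pairs:
            out.append(RateEstimate(pos, math.nan, math.nan, None, 0))
            continue
        out.append(counting_rates(cols.pairs, pos))
    return out
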