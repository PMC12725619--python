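"""Mutation-catalog statistics along and around coding sequences.

Conventions: mutation positions are 0-based internally (1-based in TSV
files) and the ancestral base must match the reference. Windows tile codons
from codon 2 onward (the start codon is outside every window), so "the
first 10 codons" is the window spanning codons 2-11; all window totals are
taken over codons >= 2 for consistency. Trinucleotide contexts are counted
on the reference strand as given, overlaps allowed, with no
reverse-complement collapsing.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import BASE_INDEX, BASES, FOURFOLD_CODONS, codons_of

TRINUCS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


@dataclass(frozen=True)
class MutationRecord:
    contig: str
    position: int  # 0-based
    ancestral: str
    derived: str
    line_id: str | None = None

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived base identical")
        if self.ancestral not in BASES or self.derived not in BASES:
            raise ValueError("non-canonical base in mutation record")


@dataclass(frozen=True)
class WindowStat:
    window: int
    start_codon: int
    end_codon: int
    mutations: int
    bp: int
    density_per_kb: float
    o_minus_e_over_e: float | None = None


@dataclass(frozen=True)
class TrinucProfile:
    """64 trinucleotide entries: central-base mutation count, ancestral
    occurrences and their ratio (the mutability)."""

    entries: dict[str, tuple[int, int, float]]

    def frequency(self, trinuc: str) -> float:
        return self.entries[trinuc][2]

    def as_series(self) -> pd.Series:
        return pd.Series({t: v[2] for t, v in self.entries.items()})

    def rank_order(self) -> list[str]:
        return sorted(self.entries, key=lambda t: -self.entries[t][2])


def read_catalog(path, genome: dict[str, str] | None = None) -> list[MutationRecord]:
    """Read a mutation TSV (contig, position 1-based, ancestral, derived[, line_id]).

    With a genome given, records whose ancestral base mismatches the
    reference raise (catalog/reference disagreement is a hard error).
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    records = []
    for row in df.itertuples(index=False):
        rec = MutationRecord(
            contig=row.contig,
            position=int(row.position) - 1,
            ancestral=row.ancestral.upper(),
            derived=row.derived.upper(),
            line_id=str(getattr(row, "line_id", "")) or None,
        )
        if genome is not None and genome[rec.contig][rec.position] != rec.ancestral:
            raise ValueError(
                f"ancestral base mismatch at {rec.contig}:{rec.position + 1}"
            )
        records.append(rec)
    return records


def write_catalog(records, path) -> None:
    pd.DataFrame(
        {
            "contig": [r.contig for r in records],
            "position": [r.position + 1 for r in records],
            "ancestral": [r.ancestral for r in records],
            "derived": [r.derived for r in records],
            "line_id": [r.line_id or "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mapping mutations into gene coordinates


class _GeneIndex:
    """Maps genomic positions to (gene, codon index) for all containing genes."""

    def __init__(self, cds_set):
        self.by_contig: dict[str, list] = {}
        self.max_len = 0
        for rec in cds_set:
            if not getattr(rec, "valid", True) or rec.interval is None:
                continue
            iv = rec.interval
            self.by_contig.setdefault(iv.contig, []).append((iv.start, iv.end, iv.strand, rec))
            self.max_len = max(self.max_len, iv.end - iv.start)
        for lst in self.by_contig.values():
            lst.sort(key=lambda x: x[0])

    def codon_hits(self, contig: str, pos: int):
        """Yield (CdsRecord, codon_position) for every gene containing pos."""
        lst = self.by_contig.get(contig, [])
        starts = [x[0] for x in lst]
        i = bisect_right(starts, pos)
        j = i - 1
        while j >= 0 and lst[j][0] > pos - self.max_len - 1:
            start, end, strand, rec = lst[j]
            if start <= pos < end:
                offset = pos - start if strand == "+" else end - 1 - pos
                yield rec, offset // 3 + 1
            j -= 1


def _window_of(codon: int, window_codons: int) -> int | None:
    """1-based window index for a codon position; codon 1 is in no window."""
    if codon < 2:
        return None
    return (codon - 2) // window_codons + 1


def window_density(catalog, cds_set, window_codons: int = 10) -> list[WindowStat]:
    """Pooled mutation count and bp per fixed-size codon window across genes.

    Genes contribute bp only to the windows they reach; mutations landing in
    overlapping genes count once per containing gene's frame.
    """
    records = [r for r in cds_set if getattr(r, "valid", True)]
    if not records:
        raise ValueError("empty CDS set")
    bp: dict[int, int] = {}
    for rec in records:
        n_codons = len(rec.sequence) // 3
        for c in range(2, n_codons + 1):
            w = _window_of(c, window_codons)
            bp[w] = bp.get(w, 0) + 3
    muts: dict[int, int] = {w: 0 for w in bp}
    index = _GeneIndex(records)
    for m in catalog:
        for _, codon in index.codon_hits(m.contig, m.position):
            w = _window_of(codon, window_codons)
            if w in muts:
                muts[w] += 1
    out = []
    for w in sorted(bp):
        start_c, end_c = 2 + (w - 1) * window_codons, 1 + w * window_codons
        out.append(
            WindowStat(w, start_c, end_c, muts[w], bp[w], 1000.0 * muts[w] / bp[w])
        )
    return out


def window_deviation(catalog, cds_set, window_codons: int = 10) -> list[WindowStat]:
    """(Observed - Expected)/Expected per window, expectation proportional to bp."""
    ws = window_density(catalog, cds_set, window_codons)
    total_m = sum(w.mutations for w in ws)
    total_bp = sum(w.bp for w in ws)
    out = []
    for w in ws:
        e = total_m * w.bp / total_bp
        dev = (w.mutations - e) / e if e > 0 else None
        out.append(
            WindowStat(w.window, w.start_codon, w.end_codon, w.mutations, w.bp,
                       w.density_per_kb, dev)
        )
    return out


def five_prime_deficit_inputs(catalog, cds_set, up_to_codon: int = 10):
    """(observed, expected, total) mutations for the 5' deficit test.

    Observed counts CDS mutations within the first ``up_to_codon`` codons
    after the start codon (codons 2..up_to_codon+1); the expectation is the
    bp share of that span among all CDS sequence (codons >= 2) times the
    total CDS mutation count. Feed into stats_tests.chi2_gof_two_cell.
    """
    records = [r for r in cds_set if getattr(r, "valid", True)]
    span_bp = total_bp = 0
    for rec in records:
        n_codons = len(rec.sequence) // 3
        total_bp += 3 * max(n_codons - 1, 0)
        span_bp += 3 * max(min(n_codons, up_to_codon + 1) - 1, 0)
    index = _GeneIndex(records)
    observed = total = 0
    for m in catalog:
        hits = [c for _, c in index.codon_hits(m.contig, m.position) if c >= 2]
        if hits:
            total += 1
            if any(c <= up_to_codon + 1 for c in hits):
                observed += 1
    expected = total * span_bp / total_bp if total_bp else 0.0
    return observed, expected, total


# ---------------------------------------------------------------------------
# context mutability


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _region_slices(genome: dict[str, str], region):
    if region is None:
        return [(c, 0, len(s)) for c, s in genome.items()]
    return [(iv.contig, iv.start, iv.end) for iv in region]


def trinuc_occurrences(genome: dict[str, str], region=None) -> dict[str, int]:
    """Sliding trinucleotide occurrence counts on the reference strand."""
    counts = np.zeros(64, dtype=np.int64)
    for contig, s, e in _region_slices(genome, region):
        if e - s < 3:
            continue
        enc = _encode(genome[contig][s:e])
        code = 16 * enc[:-2].astype(np.int64) + 4 * enc[1:-1] + enc[2:]
        valid = (enc[:-2] != 255) & (enc[1:-1] != 255) & (enc[2:] != 255)
        counts += np.bincount(code[valid], minlength=64)
    return {t: int(counts[i]) for i, t in enumerate(TRINUCS)}


def _in_region(region, contig: str, pos: int) -> bool:
    return any(iv.contig == contig and iv.start <= pos < iv.end for iv in region)


def trinuc_mutability(catalog, genome: dict[str, str], region=None) -> TrinucProfile:
    """Mutations at the central base per ancestral trinucleotide occurrence.

    A mutation contributes only if both flanking bases exist within the
    region (contig-edge mutations drop); occurrences slide by one.
    """
    for _, s, e in _region_slices(genome, region):
        if e - s < 3:
            raise ValueError("region smaller than 3 bp")
    occ = trinuc_occurrences(genome, region)
    counts = {t: 0 for t in TRINUCS}
    for m in catalog:
        p = m.position
        seq = genome[m.contig]
        if p - 1 < 0 or p + 1 >= len(seq):
            continue
        if region is not None and not (
            _in_region(region, m.contig, p - 1)
            and _in_region(region, m.contig, p)
            and _in_region(region, m.contig, p + 1)
        ):
            continue
        tri = seq[p - 1] + m.ancestral + seq[p + 1]
        if tri in counts:
            counts[tri] += 1
    return TrinucProfile(
        {t: (counts[t], occ[t], counts[t] / occ[t] if occ[t] else math.nan) for t in TRINUCS}
    )


def mononuc_mutability(catalog, genome: dict[str, str], region=None) -> dict[str, tuple[int, int, float]]:
    """Mutations per ancestral-base occurrence (4 entries)."""
    occ = {b: 0 for b in BASES}
    for contig, s, e in _region_slices(genome, region):
        chunk = genome[contig][s:e]
        for b in BASES:
            occ[b] += chunk.count(b)
    counts = {b: 0 for b in BASES}
    for m in catalog:
        if region is not None and not _in_region(region, m.contig, m.position):
            continue
        counts[m.ancestral] += 1
    return {b: (counts[b], occ[b], counts[b] / occ[b] if occ[b] else math.nan) for b in BASES}


def expected_positional_rate(cds_set, profile, mode: str = "all_sites", max_codon: int = 150):
    """Expected mutations per codon position given context mutabilities.

    ``profile`` is either a TrinucProfile or a 4-entry mononucleotide
    mapping (base -> frequency or (count, occ, freq) tuple). In
    ``fourfold_third_central`` mode only trinucleotides whose central base
    is the third site of a 4-fold degenerate codon contribute.
    """
    if isinstance(profile, TrinucProfile):
        freq = {t: v[2] for t, v in profile.entries.items()}
        context_len = 3
    else:
        freq = {b: (v[2] if isinstance(v, tuple) else float(v)) for b, v in profile.items()}
        context_len = 1
    records = [r for r in cds_set if getattr(r, "valid", True)]
    if not records:
        raise ValueError("empty CDS set")
    samples: dict[int, list[float]] = {}
    for rec in records:
        seq = rec.sequence
        cods = codons_of(seq)
        for pos in range(1, min(len(cods), max_codon) + 1):
            codon = cods[pos - 1]
            base0 = 3 * (pos - 1)
            if mode == "fourfold_third_central":
                if codon not in FOURFOLD_CODONS or base0 + 3 >= len(seq):
                    continue
                if context_len == 3:
                    ctx = seq[base0 + 1 : base0 + 4]
                else:
                    ctx = codon[2]
                val = freq.get(ctx, 0.0)
            else:
                val = 0.0
                for i in range(3):
                    g = base0 + i
                    if context_len == 1:
                        val += freq.get(seq[g], 0.0)
                    elif 1 <= g <= len(seq) - 2:
                        val += freq.get(seq[g - 1 : g + 2], 0.0)
            if not math.isnan(val):
                samples.setdefault(pos, []).append(val)
    from .positional_profiles import _profile_from_samples

    return _profile_from_samples(samples)


def genic_intergenic_profiles(catalog, genic_region, intergenic_region, genome):
    """Trinucleotide mutability in genic vs intergenic sequence, with a
    paired t test over the 64 matched entries (entries lacking occurrences
    in either class are excluded pairwise)."""
    genic = trinuc_mutability(catalog, genome, genic_region)
    inter = trinuc_mutability(catalog, genome, intergenic_region)
    g, i = [], []
    for t in TRINUCS:
        fg, fi = genic.entries[t][2], inter.entries[t][2]
        if not (math.isnan(fg) or math.isnan(fi)):
            g.append(fg)
            i.append(fi)
    tstat, p = stats.ttest_rel(i, g)
    return genic, inter, {"t": float(tstat), "p_value": float(p), "n_pairs": len(g)}


def weak_trinuc_content_by_position(cds_set, max_codon: int = 150):
    """Fraction of third-site-centred trinucleotides with A/T on both flanks.

    The context of codon p's third site is (second site, third site, first
    site of codon p+1); patterns ANA, ANT, TNA, TNT count.
    """
    records = [r for r in cds_set if getattr(r, "valid", True)]
    if not records:
        raise ValueError("empty CDS set")
    samples: dict[int, list[float]] = {}
    for rec in records:
        seq = rec.sequence
        n_codons = len(seq) // 3
        for pos in range(1, min(n_codons - 1, max_codon) + 1):
            b0 = 3 * (pos - 1)
            left, nxt = seq[b0 + 1], seq[b0 + 3]
            samples.setdefault(pos, []).append(1.0 if left in "AT" and nxt in "AT" else 0.0)
    from .positional_profiles import _profile_from_samples

    return _profile_from_samples(samples)
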