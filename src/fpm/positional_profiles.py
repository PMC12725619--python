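"""Per-codon-position composition profiles and region summaries.

Profiles average an indicator (e.g. "this base is A or T") across genes at
each codon position; the SEM is taken across genes at that position, so
positions reached by fewer (long enough) genes carry larger errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._codons import (
    AMINO_ACIDS,
    BASES,
    CODON_TO_AA,
    FOURFOLD_CODONS,
    SENSE_CODONS,
    codons_of,
)

_NT_CLASS = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "AT": {"A", "T"},
    "GC": {"G", "C"},
}


@dataclass(frozen=True)
class PositionalProfile:
    """A per-position statistic (codon positions, start codon = 1)."""

    positions: np.ndarray
    values: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.positions.tolist(), self.values.tolist()))


@dataclass(frozen=True)
class RegionSummary:
    region: str
    at: float
    at3: float
    at3_max: float


def _profile_from_samples(samples: dict[int, list[float]]) -> PositionalProfile:
    positions = sorted(p for p, v in samples.items() if v)
    vals, sems, ns = [], [], []
    for p in positions:
        x = np.asarray(samples[p], dtype=float)
        vals.append(x.mean())
        sems.append(x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0)
        ns.append(len(x))
    return PositionalProfile(
        np.asarray(positions), np.asarray(vals), np.asarray(sems), np.asarray(ns, dtype=int)
    )


def content_by_position(cds_set, nucleotide="AT", site_filter="3", max_codon=150) -> PositionalProfile:
    """Mean content of a nucleotide class per codon position across genes.

    ``site_filter`` selects codon site 1, 2 or 3, or ``all`` for the mean
    over the three sites of each codon. Genes shorter than a position simply
    drop out of that position's denominator.
    """
    cls = _NT_CLASS[nucleotide.upper()]
    site = str(site_filter)
    records = [r for r in cds_set if getattr(r, "valid", True)]
    if not records:
        raise ValueError("empty CDS set")
    samples: dict[int, list[float]] = {}
    for rec in records:
        for pos, codon in enumerate(codons_of(rec.sequence), start=1):
            if pos > max_codon:
                break
            if site == "all":
                val = sum(b in cls for b in codon) / 3.0
            else:
                val = 1.0 if codon[int(site) - 1] in cls else 0.0
            samples.setdefault(pos, []).append(val)
    return _profile_from_samples(samples)


def fourfold_content_by_position(cds_set, nucleotide="AT", max_codon=150) -> PositionalProfile:
    """Third-site content per position, restricted to 4-fold degenerate codons.

    Positions at which a gene carries no 4-fold codon contribute nothing for
    that gene; positions with no qualifying codon in any gene are absent from
    the profile rather than reported as zero.
    """
    cls = _NT_CLASS[nucleotide.upper()]
    records = [r for r in cds_set if getattr(r, "valid", True)]
    if not records:
        raise ValueError("empty CDS set")
    samples: dict[int, list[float]] = {}
    for rec in records:
        for pos, codon in enumerate(codons_of(rec.sequence), start=1):
            if pos > max_codon:
                break
            if codon in FOURFOLD_CODONS:
                samples.setdefault(pos, []).append(1.0 if codon[2] in cls else 0.0)
    return _profile_from_samples(samples)


def _at_fraction(seq: str) -> float:
    seq = seq.upper()
    n = sum(seq.count(b) for b in "ACGT")
    return (seq.count("A") + seq.count("T")) / n if n else float("nan")


def _region_stats(records, first: int, last: int | None) -> RegionSummary | None:
    """AT / third-site AT / per-position max third-site AT over codons [first, last]."""
    all_bases_at, third_at = [], []
    per_pos_third: dict[int, list[float]] = {}
    for rec in records:
        for pos, codon in enumerate(codons_of(rec.sequence), start=1):
            if pos < first or (last is not None and pos > last):
                continue
            all_bases_at.extend(1.0 if b in "AT" else 0.0 for b in codon)
            t = 1.0 if codon[2] in "AT" else 0.0
            third_at.append(t)
            per_pos_third.setdefault(pos, []).append(t)
    if not third_at:
        return None
    at3_by_pos = [float(np.mean(v)) for v in per_pos_third.values()]
    label = f"codons_{first}_{last}" if last is not None else f"codons_{first}_plus"
    return RegionSummary(label, float(np.mean(all_bases_at)), float(np.mean(third_at)), max(at3_by_pos))


def region_summaries(cds_set, intergenic_seqs=(), genome_seqs=()) -> list[RegionSummary]:
    """Table-style summary: AT/AT3/AT3max for codons 2-11, 12-60, 61+, plus
    plain AT for intergenic sequence and the whole genome."""
    records = [r for r in cds_set if getattr(r, "valid", True)]
    out = []
    for first, last in ((2, 11), (12, 60), (61, None)):
        rs = _region_stats(records, first, last)
        if rs is not None:
            out.append(rs)
    if intergenic_seqs:
        at = _at_fraction("".join(intergenic_seqs))
        out.append(RegionSummary("intergenic", at, float("nan"), float("nan")))
    if genome_seqs:
        at = _at_fraction("".join(genome_seqs))
        out.append(RegionSummary("genomic", at, float("nan"), float("nan")))
    return out


def third_site_mononucleotide_probs(cds_set) -> dict[str, float]:
    """Mononucleotide probabilities from third sites of 4-fold codons."""
    counts = {b: 0 for b in BASES}
    for rec in cds_set:
        if not getattr(rec, "valid", True):
            continue
        for codon in codons_of(rec.sequence):
            if codon in FOURFOLD_CODONS:
                counts[codon[2]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no 4-fold degenerate codons in CDS set")
    return {b: c / total for b, c in counts.items()}


def expected_aa_frequencies(mono_probs: dict[str, float]) -> dict[str, float]:
    """Amino-acid frequencies implied by independent per-site base probabilities.

    Codon probability is the product of its three base probabilities; stop
    codons are excluded and the remainder renormalized.
    """
    weights = {aa: 0.0 for aa in AMINO_ACIDS}
    total = 0.0
    for codon in SENSE_CODONS:
        p = mono_probs[codon[0]] * mono_probs[codon[1]] * mono_probs[codon[2]]
        weights[CODON_TO_AA[codon]] += p
        total += p
    return {aa: w / total for aa, w in weights.items()}


def aa_property_profile(cds_set, scale: dict[str, float], max_codon=150):
    """Observed vs composition-expected amino-acid property profile.

    Observed: frequency-weighted mean property value at each codon position.
    Expected: a flat profile at the mean property under amino-acid
    frequencies implied by the third-site mononucleotide composition of
    4-fold codons (codon probability = product of positional base
    probabilities, stops excluded).
    """
    missing = set(AMINO_ACIDS) - set(scale)
    if missing:
        raise KeyError(f"scale missing amino acids: {sorted(missing)}")
    records = [r for r in cds_set if getattr(r, "valid", True)]
    if not records:
        raise ValueError("empty CDS set")
    samples: dict[int, list[float]] = {}
    for rec in records:
        for pos, codon in enumerate(codons_of(rec.sequence), start=1):
            if pos > max_codon:
                break
            aa = CODON_TO_AA.get(codon)
            if aa is not None:
                samples.setdefault(pos, []).append(scale[aa])
    observed = _profile_from_samples(samples)

    mono = third_site_mononucleotide_probs(records)
    aa_freqs = expected_aa_frequencies(mono)
    exp_val = sum(aa_freqs[aa] * scale[aa] for aa in AMINO_ACIDS)
    expected = PositionalProfile(
        observed.positions.copy(),
        np.full(len(observed.positions), exp_val),
        np.zeros(len(observed.positions)),
        observed.n.copy(),
    )
    return observed, expected


#: Kyte-Doolittle hydropathy (low = hydrophilic)
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
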