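"""Synthetic genomes, mutation catalogs and diverged ortholog triples.

Every generator is a pure function of (spec, seed) and emits artifacts that
pass the consuming module's validators. Defaults encode the empirical
shapes the analyses assume for E. coli-like data: third-site AT ~0.62 in
codons 2-11 decaying to ~0.46 in the gene body, a synonymous-rate ramp
rising from the start codon to a plateau near codon 60, and context-
dependent mutabilities favouring GC-rich trinucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._codons import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    revcomp,
)
from .equilibrium import MonoRateMatrix, stationary_mono
from .mutation_analysis import TRINUCS, MutationRecord
from .sequence_io import CdsRecord, GenomicInterval, validate_cds
from .substitution_rates import OrthologTriple

_AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _a in CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_a, []).append(_c)

#: single-base synonymous neighbours of each sense codon
_SYN_NEIGHBOURS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    nb = []
    for _i in range(3):
        for _b in BASES:
            if _b != _c[_i]:
                alt = _c[:_i] + _b + _c[_i + 1 :]
                if CODON_TO_AA.get(alt) == CODON_TO_AA[_c]:
                    nb.append(alt)
    _SYN_NEIGHBOURS[_c] = nb

_HYDROPHILIC = set("RNDQEKH")  # strongly negative Kyte-Doolittle


@dataclass(frozen=True)
class GeneratorSpec:
    """Stated world for the synthetic E. coli-like data.

    ``at5`` is the target third-site AT in codons 2-11 (0.62, the maximum
    AT3 reported for the E. coli 5' region); ``at_core`` the gene-body value
    (0.46). The composition interpolates linearly from codon 11 down to
    ``ramp_end_codon``. Divergence uses ``positional_subst_multiplier``
    (per-codon scaling of the synonymous substitution probability
    ``syn_prob`` per branch); mutation catalogs use ``trinuc_mutability``
    relative weights.
    """

    seed: int = 0
    n_genes: int = 500
    gene_length_codons: tuple[int, int] = (180, 320)
    at5: float = 0.62
    at_core: float = 0.46
    ramp_end_codon: int = 15
    syn_prob: float = 0.15
    nonsyn_prob: float = 0.0
    outgroup_factor: float = 2.0
    trinuc_mutability: dict[str, float] | None = None
    positional_subst_multiplier: dict[int, float] | None = None
    n_mutations: int = 50_000
    hydrophilic_5prime: bool = False
    indel_prob: float = 0.0

    def third_site_at_target(self, codon_position: int) -> float:
        """The stated third-site AT at a codon position."""
        if not 0.0 <= self.at5 <= 1.0 or not 0.0 <= self.at_core <= 1.0:
            raise ValueError("infeasible composition target")
        if codon_position <= 11:
            return self.at5
        if codon_position >= self.ramp_end_codon:
            return self.at_core
        frac = (codon_position - 11) / (self.ramp_end_codon - 11)
        return self.at5 + frac * (self.at_core - self.at5)

    def multiplier(self, codon_position: int) -> float:
        if self.positional_subst_multiplier is None:
            return 1.0
        return self.positional_subst_multiplier.get(codon_position, 1.0)


def ramp_multiplier(low: float = 0.25, high: float = 1.0, start: int = 2, end: int = 60,
                    max_codon: int = 400) -> dict[int, float]:
    """Linear multiplier ramp (the Ks-profile shape: low 5', plateau at 60)."""
    out = {}
    for p in range(1, max_codon + 1):
        if p < start:
            out[p] = low
        elif p >= end:
            out[p] = high
        else:
            out[p] = low + (high - low) * (p - start) / (end - start)
    return out


# ---------------------------------------------------------------------------
# CDS sets


def _draw_codon(rng, aa: str, at_target: float) -> str:
    """Codon for an amino acid with third-base A/T probability ``at_target``."""
    codons = _AA_TO_CODONS[aa]
    at_ending = [c for c in codons if c[2] in "AT"]
    gc_ending = [c for c in codons if c[2] in "GC"]
    if at_ending and gc_ending:
        pool = at_ending if rng.random() < at_target else gc_ending
    else:
        pool = codons
    return pool[rng.integers(len(pool))]


def gen_cds_set(spec: GeneratorSpec) -> list[CdsRecord]:
    """Generate validated CDS records with the stated 5' AT3 gradient.

    Amino acids are drawn independently of the nucleotide target (uniform
    over the 20, optionally hydrophilic-enriched in codons 2-11), so
    second-site composition is controlled separately from third-site AT.
    """
    rng = np.random.default_rng(spec.seed)
    aas = sorted(_AA_TO_CODONS)
    records = []
    lo, hi = spec.gene_length_codons
    for g in range(spec.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        parts = ["ATG"]
        for pos in range(2, n_codons):
            if spec.hydrophilic_5prime and pos <= 11 and rng.random() < 0.5:
                aa = sorted(_HYDROPHILIC)[rng.integers(len(_HYDROPHILIC))]
            else:
                aa = aas[rng.integers(len(aas))]
            parts.append(_draw_codon(rng, aa, spec.third_site_at_target(pos)))
        parts.append(("TAA", "TGA", "TAG")[rng.integers(3)])
        seq = "".join(parts)
        ok, reasons = validate_cds(seq)
        assert ok, f"generator produced invalid CDS: {reasons}"
        records.append(CdsRecord(gene_id=f"g{g:05d}", sequence=seq))
    return records


def build_toy_genome(records, seed: int = 0, spacer_bp: int = 150, spacer_at: float = 0.55,
                     overlap_fraction: float = 0.0, overlap_bp: int = 3,
                     minus_fraction: float = 0.4, contig: str = "chr"):
    """Embed CDS records in a single-contig toy genome with intergenic spacers.

    A ``overlap_fraction`` of genes is placed so its 5' end overlaps the
    previous gene's 3' end by ``overlap_bp`` (exercising overlap filters);
    ``minus_fraction`` of genes go on the minus strand (reverse-complemented
    into the genome).
    """
    rng = np.random.default_rng(seed)
    p = [spacer_at / 2, (1 - spacer_at) / 2, (1 - spacer_at) / 2, spacer_at / 2]

    def spacer():
        return "".join(rng.choice(list("ACGT"), size=spacer_bp, p=p))

    buf: list[str] = []

    def write_at(start: int, s: str):
        if len(buf) < start + len(s):
            buf.extend("N" * (start + len(s) - len(buf)))
        buf[start : start + len(s)] = list(s)

    placed: list[CdsRecord] = []
    cursor = 0
    for i, rec in enumerate(records):
        if i > 0 and rng.random() < overlap_fraction and cursor >= overlap_bp:
            # next gene's 5' end is written over the previous gene's 3' tail;
            # the previous record keeps its own coding sequence (toy overlap
            # exercises interval geometry, not dual-frame coding)
            start = cursor - overlap_bp
        else:
            write_at(cursor, spacer())
            start = cursor + spacer_bp
        strand = "-" if rng.random() < minus_fraction else "+"
        embedded = revcomp(rec.sequence) if strand == "-" else rec.sequence
        write_at(start, embedded)
        end = start + len(embedded)
        placed.append(
            CdsRecord(rec.gene_id, rec.sequence, GenomicInterval(contig, start, end, strand),
                      rec.valid, rec.failure_reasons)
        )
        cursor = end
    write_at(cursor, spacer())
    genome = {contig: "".join(buf)}
    return genome, placed


def write_genome_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(placed_records, contig_lengths, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for rec in placed_records:
            iv = rec.interval
            fh.write(
                f"{iv.contig}\tfpm\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID=gene-{rec.gene_id}\n"
                f"{iv.contig}\tfpm\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t0\tID={rec.gene_id};Parent=gene-{rec.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# mutation catalogs


def simulate_mutations(genome: dict[str, str], spec: GeneratorSpec, cds_set=None,
                       derived_probs: dict[str, dict[str, float]] | None = None) -> list[MutationRecord]:
    """Draw point mutations with context- and position-dependent weights.

    Site weight = trinucleotide mutability of the site's context times the
    positional multiplier of any containing gene's codon index. Contig-edge
    bases (no full context) never mutate. The derived base is uniform over
    the three alternatives unless ``derived_probs`` conditions it on the
    ancestral base.
    """
    mut = spec.trinuc_mutability or {t: 1.0 for t in TRINUCS}
    if set(mut) != set(TRINUCS):
        raise ValueError("trinuc_mutability must cover all 64 contexts")
    rng = np.random.default_rng(spec.seed + 1)
    weights_all, sites = [], []
    tri_w = np.array([mut[t] for t in TRINUCS])
    from .mutation_analysis import _encode

    for contig, seq in genome.items():
        enc = _encode(seq)
        code = 16 * enc[:-2].astype(np.int64) + 4 * enc[1:-1] + enc[2:]
        w = np.zeros(len(seq))
        valid = (enc[:-2] != 255) & (enc[1:-1] != 255) & (enc[2:] != 255)
        w[1:-1][valid] = tri_w[code[valid]]
        if cds_set is not None and spec.positional_subst_multiplier is not None:
            for rec in cds_set:
                iv = rec.interval
                if iv is None or iv.contig != contig:
                    continue
                for off in range(len(iv)):
                    g = iv.start + off if iv.strand == "+" else iv.end - 1 - off
                    w[g] *= spec.multiplier(off // 3 + 1)
        weights_all.append(w)
        sites.extend((contig, i) for i in range(len(seq)))
    w = np.concatenate(weights_all)
    if w.sum() <= 0:
        raise ValueError("zero total mutation weight")
    idx = rng.choice(len(w), size=spec.n_mutations, replace=True, p=w / w.sum())
    records = []
    for i in idx:
        contig, pos = sites[i]
        anc = genome[contig][pos]
        if derived_probs is not None:
            alts = [b for b in BASES if b != anc]
            probs = np.array([derived_probs[anc].get(b, 0.0) for b in alts])
            der = alts[rng.choice(3, p=probs / probs.sum())]
        else:
            alts = [b for b in BASES if b != anc]
            der = alts[rng.integers(3)]
        records.append(MutationRecord(contig, int(pos), anc, der))
    return records


# ---------------------------------------------------------------------------
# diverged ortholog triples


def _evolve(seq: str, spec: GeneratorSpec, rng, branch_factor: float = 1.0) -> str:
    """One branch of codon evolution: synonymous single-base swaps (and
    optional non-synonymous changes), rate scaled per codon position."""
    cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for pos in range(2, len(cods)):  # keep start codon; stop is last, untouched below
        c = cods[pos - 1]
        if c in STOP_CODONS or c not in CODON_TO_AA:
            continue
        scale = spec.multiplier(pos) * branch_factor
        if rng.random() < spec.syn_prob * scale and _SYN_NEIGHBOURS[c]:
            c = _SYN_NEIGHBOURS[c][rng.integers(len(_SYN_NEIGHBOURS[c]))]
        if spec.nonsyn_prob > 0 and rng.random() < spec.nonsyn_prob * scale:
            alts = []
            for i in range(3):
                for b in BASES:
                    alt = c[:i] + b + c[i + 1 :]
                    if alt != c and alt in CODON_TO_AA and CODON_TO_AA[alt] != CODON_TO_AA[c]:
                        alts.append(alt)
            if alts:
                c = alts[rng.integers(len(alts))]
        cods[pos - 1] = c
    return "".join(cods)


def _insert_indels(aligned: list[str], rng, prob: float) -> list[str]:
    """Insert rare 3-bp gap columns into one lineage (alignment stays framed)."""
    if prob <= 0:
        return aligned
    n_codons = len(aligned[0]) // 3
    out = [list(s) for s in aligned]
    offset = 0
    for pos in range(2, n_codons):
        if rng.random() < prob:
            lineage = int(rng.integers(3))
            i = 3 * (pos - 1) + offset
            out[lineage][i : i + 3] = list("---")
    return ["".join(s) for s in out]


def simulate_divergence(cds_set, spec: GeneratorSpec):
    """Evolve each CDS into a (focal, sister, outgroup) codon-aligned triple.

    Focal and sister diverge independently from the ancestor with
    per-codon synonymous substitution probability ``syn_prob`` x positional
    multiplier; the outgroup branch is ``outgroup_factor`` x longer. Returns
    the triples and the per-position truth (expected focal-branch
    substitution probability, the quantity the Ks profile should track).
    """
    rng = np.random.default_rng(spec.seed + 2)
    triples = []
    for rec in cds_set:
        anc = rec.sequence
        focal = _evolve(anc, spec, rng, 1.0)
        sister = _evolve(anc, spec, rng, 1.0)
        outgroup = _evolve(anc, spec, rng, spec.outgroup_factor)
        aligned = [focal, sister, outgroup]
        if spec.indel_prob > 0:
            aligned = _insert_indels(aligned, rng, spec.indel_prob)
        triples.append(OrthologTriple(rec.gene_id, *aligned))
    max_len = max(len(t.focal) for t in triples) // 3
    truth = {pos: spec.syn_prob * spec.multiplier(pos) for pos in range(2, max_len + 1)}
    return triples, truth


def write_triples_fasta(triples, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in triples:
        with open(directory / f"{t.ortholog_id}.fasta", "w") as fh:
            for name, seq in (("focal", t.focal), ("sister", t.sister), ("outgroup", t.outgroup)):
                fh.write(f">{name}\n{seq}\n")


def read_triples_fasta(directory):
    from Bio import SeqIO

    triples = []
    for path in sorted(Path(directory).glob("*.fasta")):
        recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        triples.append(OrthologTriple(path.stem, recs["focal"], recs["sister"], recs["outgroup"]))
    return triples


# ---------------------------------------------------------------------------
# mutation matrices with a prescribed stationary AT


def gen_mutation_matrix(target_at_star: float, seed: int = 0) -> MonoRateMatrix:
    """Random reversible 12-flux matrix whose stationary A+T equals the target.

    Construction: draw a stationary vector pi with pi_A + pi_T =
    ``target_at_star`` (random skew within each pair), draw symmetric
    exchangeabilities s(N,M), set rate(N->M) = s * pi_M and rescale so every
    row's total flux stays below 1. Detailed balance makes pi stationary
    exactly; verified against the solver at generation time.
    """
    if not 0.0 < target_at_star < 1.0:
        raise ValueError("target_at_star must be in (0, 1)")
    rng = np.random.default_rng(seed)
    u, v = rng.uniform(0.35, 0.65, size=2)
    pi = {
        "A": u * target_at_star,
        "T": (1 - u) * target_at_star,
        "G": v * (1 - target_at_star),
        "C": (1 - v) * (1 - target_at_star),
    }
    rates = {}
    for i, a in enumerate(BASES):
        for b in BASES[i + 1 :]:
            s = rng.uniform(0.5, 1.5)
            rates[(a, b)] = s * pi[b]
            rates[(b, a)] = s * pi[a]
    row_max = max(sum(rates[(a, b)] for b in BASES if b != a) for a in BASES)
    rates = {k: 0.2 * r / row_max for k, r in rates.items()}
    matrix = MonoRateMatrix(rates)
    f = stationary_mono(matrix)
    assert abs(f["A"] + f["T"] - target_at_star) < 1e-9
    return matrix


def gen_random_genome(length: int, at: float = 0.5, seed: int = 0,
                      contig: str = "chr") -> dict[str, str]:
    rng = np.random.default_rng(seed)
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return {contig: "".join(rng.choice(list("ACGT"), size=length, p=p))}


def simulate_mutations_from_matrix(matrix: MonoRateMatrix, genome: dict[str, str],
                                   n_mutations: int, seed: int = 0) -> list[MutationRecord]:
    """Catalog drawn from a 4-state flux matrix: site probability is the
    ancestral base's total outflux, derived base follows the relative fluxes."""
    rng = np.random.default_rng(seed)
    contig = list(genome)[0]
    seq = genome[contig]
    outflux = {a: sum(matrix.rate(a, b) for b in BASES if b != a) for a in BASES}
    w = np.array([outflux[b] for b in seq])
    idx = rng.choice(len(seq), size=n_mutations, replace=True, p=w / w.sum())
    records = []
    for pos in idx:
        anc = seq[pos]
        alts = [b for b in BASES if b != anc]
        probs = np.array([matrix.rate(anc, b) for b in alts])
        der = alts[rng.choice(3, p=probs / probs.sum())]
        records.append(MutationRecord(contig, int(pos), anc, der))
    return records
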