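"""CDS extraction, validation, overlap detection and genic/intergenic partitioning.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the boundary. Codon numbering throughout the package: the start
codon is codon 1, so "the first 10 codons after the start codon" are codons
2-11.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import START_CODONS, STOP_CODONS, revcomp

logger = logging.getLogger(__name__)

# validation failure codes
BAD_START = "bad_start_codon"
NO_TERMINAL_STOP = "no_terminal_stop"
NOT_MULTIPLE_OF_3 = "not_multiple_of_3"
NON_CANONICAL_BASE = "non_canonical_base"
INTERNAL_STOP = "internal_stop"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CdsRecord:
    """A coding sequence on its coding strand, with validation outcome."""

    gene_id: str
    sequence: str
    interval: GenomicInterval | None = None
    valid: bool = True
    failure_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class OverlapReport:
    gene_id: str
    has_5prime_overlap: bool
    overlap_bp: int


def validate_cds(sequence: str) -> tuple[bool, list[str]]:
    """Apply the five structural checks for a bacterial CDS.

    Checks: table-11 initiator, terminal stop, length a multiple of three,
    canonical bases only, no internal stop. Every violated check contributes
    a code; the sequence is valid iff none are violated.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    reasons: list[str] = []
    if any(b not in "ACGT" for b in seq):
        reasons.append(NON_CANONICAL_BASE)
    if len(seq) % 3 != 0:
        reasons.append(NOT_MULTIPLE_OF_3)
    if len(seq) < 3 or seq[:3] not in START_CODONS:
        reasons.append(BAD_START)
    n_full = len(seq) // 3
    last = seq[3 * (n_full - 1) : 3 * n_full] if n_full else ""
    if len(seq) % 3 != 0 or last not in STOP_CODONS:
        reasons.append(NO_TERMINAL_STOP)
    internal = [seq[3 * i : 3 * i + 3] for i in range(1, max(n_full - 1, 0))]
    if any(c in STOP_CODONS for c in internal):
        reasons.append(INTERNAL_STOP)
    return (not reasons, reasons)


def _gff_db(gff_path):
    return gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def load_cds_set(fasta_path, gff_path) -> list[CdsRecord]:
    """Extract one validated CdsRecord per GFF3 CDS feature.

    Minus-strand features are reverse-complemented onto the coding strand.
    A CDS whose contig is missing from the FASTA is fatal; otherwise
    malformed features are skipped with a warning.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = _gff_db(gff_path)
    records: list[CdsRecord] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contigs:
            raise KeyError(f"contig {feat.seqid!r} referenced by GFF but absent from FASTA")
        contig_seq = contigs[feat.seqid]
        start, end = feat.start - 1, feat.end  # GFF 1-based inclusive -> half-open
        if not (0 <= start < end <= len(contig_seq)):
            logger.warning("skipping CDS with out-of-bounds coordinates: %s", feat.id)
            continue
        strand = feat.strand if feat.strand in "+-" else "+"
        raw = contig_seq[start:end]
        seq = revcomp(raw) if strand == "-" else raw
        gene_id = feat.attributes.get("ID", [feat.id or f"{feat.seqid}:{start}-{end}"])[0]
        ok, reasons = validate_cds(seq)
        records.append(
            CdsRecord(
                gene_id=gene_id,
                sequence=seq,
                interval=GenomicInterval(feat.seqid, start, end, strand),
                valid=ok,
                failure_reasons=tuple(reasons),
            )
        )
    return records


def write_cds_fasta(records, path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def _five_prime_overlap_bp(rec: CdsRecord, other: GenomicInterval) -> int:
    """Contiguous run of rec's 5'-most bases genomically covered by `other`.

    Coverage is strand-agnostic: any CDS occupying the focal gene's 5' bases
    counts, whichever strand it is encoded on.
    """
    iv = rec.interval
    if iv is None or other.contig != iv.contig:
        return 0
    lo, hi = max(iv.start, other.start), min(iv.end, other.end)
    if lo >= hi:
        return 0
    if iv.strand == "+":
        return hi - iv.start if other.start <= iv.start else 0
    return iv.end - lo if other.end >= iv.end else 0


def detect_5prime_overlaps(cds_set) -> list[OverlapReport]:
    """Per-gene maximal 5' overlap with any other CDS feature."""
    recs = [r for r in cds_set if r.interval is not None]
    reports = []
    for rec in recs:
        bp = max(
            (_five_prime_overlap_bp(rec, o.interval) for o in recs if o is not rec),
            default=0,
        )
        reports.append(OverlapReport(rec.gene_id, bp > 0, bp))
    return reports


def overlap_summary(reports) -> dict:
    overlapping = [r.overlap_bp for r in reports if r.has_5prime_overlap]
    return {
        "n_genes": len(reports),
        "n_overlapping": len(overlapping),
        "median_overlap_bp": statistics.median(overlapping) if overlapping else 0.0,
    }


def intergenic_intervals(features, contig_lengths) -> list[GenomicInterval]:
    """Complement of the union of annotated feature intervals per contig.

    ``features`` is an iterable of GenomicInterval covering every annotated
    gene (CDS and RNA alike -- anything annotated counts as genic).
    """
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for iv in features:
        if iv.contig in by_contig:
            by_contig[iv.contig].append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for contig, length in contig_lengths.items():
        ivs = sorted(by_contig[contig])
        pos = 0
        for s, e in ivs:
            if s > pos:
                out.append(GenomicInterval(contig, pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append(GenomicInterval(contig, pos, length))
    return out


def annotated_intervals_from_gff(gff_path) -> list[GenomicInterval]:
    """All annotated feature intervals (gene, CDS and *RNA types) from a GFF3."""
    db = _gff_db(gff_path)
    wanted = {t for t in db.featuretypes() if t == "gene" or t == "CDS" or t.endswith("RNA")}
    out = []
    for t in wanted:
        for feat in db.features_of_type(t):
            out.append(
                GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, feat.strand if feat.strand in "+-" else "+"
                )
            )
    return out


def _merge(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class PositionClassifier:
    """Classify genomic positions as genic or intergenic (merged-interval bisect)."""

    def __init__(self, features, contig_lengths):
        raw: dict[str, list[tuple[int, int]]] = {}
        for iv in features:
            raw.setdefault(iv.contig, []).append((iv.start, iv.end))
        self._genic = {c: _merge(ivs) for c, ivs in raw.items()}
        self.contig_lengths = dict(contig_lengths)

    def is_genic(self, contig: str, position: int) -> bool:
        import bisect

        ivs = self._genic.get(contig, [])
        i = bisect.bisect_right(ivs, (position, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= position < ivs[i][1]
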