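"""Shared genetic-code constants (bacterial translation table 11).

Everything here is derived at import time from Biopython's codon tables so
the code never hand-maintains its own copy of the genetic code.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid, stop codons excluded
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

#: initiators permitted under table 11 (ATG, GTG, TTG, CTG, ATT, ATC, ATA)
START_CODONS: frozenset[str] = frozenset(_TABLE11.start_codons)

ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product(BASES, repeat=3))
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))


def _fourfold_codons() -> frozenset[str]:
    """Codons whose third site is fully degenerate.

    A codon qualifies when all four third-base variants encode the same
    amino acid. This captures the Ala/Gly/Pro/Thr/Val families plus the
    4-fold sub-blocks of the 6-fold amino acids (Leu CTN, Arg CGN, Ser TCN);
    the 2-fold halves of 6-fold families are excluded.
    """
    out = set()
    for c in SENSE_CODONS:
        family = [c[:2] + b for b in BASES]
        aas = {CODON_TO_AA.get(f) for f in family}
        if len(aas) == 1 and None not in aas:
            out.add(c)
    return frozenset(out)


FOURFOLD_CODONS: frozenset[str] = _fourfold_codons()

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codons_of(seq: str) -> list[str]:
    """Split an in-frame coding sequence into codons (truncates remainder)."""
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def translate(seq: str) -> str:
    return "".join(CODON_TO_AA.get(c, "*") for c in codons_of(seq))
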