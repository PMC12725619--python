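"""Nucleotide content at neutral mutational equilibrium.

Three estimators of the AT fraction a sequence would drift to under the
observed mutation process alone (AT*):

* ``at_star_simple`` -- the two-class ratio of occurrence-normalized
  G/C->A/T flux to total non-neutral flux.
* ``stationary_mono`` -- the 4-state balance equations
  f_N * (total outflux of N) = sum_M f_M * rate(M->N), solved directly with
  the normalization sum(f) = 1 substituted for one balance equation.
* ``stationary_dinuc`` -- the 16-state dinucleotide extension (256 flux
  parameters); AT* is the stationary-frequency-weighted A/T base share.

Fluxes are mutations per ancestral occurrence over the experiment, so they
are proportions, not instantaneous rates; a global rescaling leaves the
stationary distribution unchanged. Because strand of origin is unknowable,
only the A+T aggregate is interpreted, never the four bases separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._codons import BASES
from .mutation_analysis import TRINUCS  # noqa: F401  (shared base order)

DINUCS = tuple(a + b for a in BASES for b in BASES)


@dataclass(frozen=True)
class MonoRateMatrix:
    """12 off-diagonal fluxes keyed (ancestral, derived)."""

    rates: dict[tuple[str, str], float]

    def rate(self, a: str, d: str) -> float:
        return self.rates.get((a, d), 0.0)

    @property
    def states(self):
        return BASES


@dataclass(frozen=True)
class DinucRateMatrix:
    """16x16 off-diagonal fluxes keyed (ancestral dinuc, derived dinuc)."""

    rates: dict[tuple[str, str], float]

    def rate(self, a: str, d: str) -> float:
        return self.rates.get((a, d), 0.0)

    @property
    def states(self):
        return DINUCS


@dataclass(frozen=True)
class EquilibriumEstimate:
    at_star: float
    method: str
    region: str = "genomic"
    boot_mean: float = math.nan
    boot_sd: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_boot: int = 0
    seed: int | None = None
    failed_fraction: float = 0.0
    flagged: bool = False


def at_star_simple(n_at2gc: int, n_gc2at: int, genomic_at: float) -> float:
    """Two-class equilibrium AT from occurrence-normalized opposing fluxes.

    r1 = n_gc2at / (1 - genomic_at) and r2 = n_at2gc / genomic_at are the
    per-occurrence rates of the two directions; AT* = r1 / (r1 + r2).
    """
    if not 0.0 < genomic_at < 1.0:
        raise ValueError("genomic_at must be strictly between 0 and 1")
    if n_at2gc < 0 or n_gc2at < 0 or (n_at2gc == 0 and n_gc2at == 0):
        raise ValueError("need at least one non-neutral mutation")
    r1 = n_gc2at / (1.0 - genomic_at)
    r2 = n_at2gc / genomic_at
    return r1 / (r1 + r2)


def _stationary(matrix, states) -> np.ndarray:
    n = len(states)
    A = np.zeros((n, n))
    for j, src in enumerate(states):
        out = 0.0
        for i, dst in enumerate(states):
            if i == j:
                continue
            r = matrix.rate(src, dst)
            A[i, j] += r
            out += r
        A[j, j] -= out
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        f = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"degenerate mutation matrix (singular balance system): {err}")
    if not np.all(np.isfinite(f)) or np.any(f < -1e-9):
        raise ValueError("degenerate mutation matrix: no valid stationary distribution")
    return np.clip(f, 0.0, None) / np.clip(f, 0.0, None).sum()


def stationary_mono(matrix: MonoRateMatrix) -> dict[str, float]:
    """Stationary base frequencies of the 4-state mutation flux matrix."""
    f = _stationary(matrix, BASES)
    return dict(zip(BASES, f.tolist()))


def at_star_mono(matrix: MonoRateMatrix) -> float:
    f = stationary_mono(matrix)
    return f["A"] + f["T"]


def stationary_dinuc(matrix: DinucRateMatrix) -> tuple[dict[str, float], float]:
    """Stationary dinucleotide frequencies and the implied AT* (each
    dinucleotide contributes half its A/T base count)."""
    f = _stationary(matrix, DINUCS)
    freqs = dict(zip(DINUCS, f.tolist()))
    at = sum(v * sum(b in "AT" for b in d) / 2.0 for d, v in freqs.items())
    return freqs, at


# ---------------------------------------------------------------------------
# estimating flux matrices from catalogs


def _region_seq(genome: dict[str, str], region) -> list[str]:
    if region is None:
        return list(genome.values())
    return [genome[iv.contig][iv.start : iv.end] for iv in region]


def _in_region(region, contig: str, pos: int) -> bool:
    if region is None:
        return True
    return any(iv.contig == contig and iv.start <= pos < iv.end for iv in region)


def region_at_fraction(genome: dict[str, str], region=None) -> float:
    seqs = _region_seq(genome, region)
    at = sum(s.count("A") + s.count("T") for s in seqs)
    n = sum(sum(s.count(b) for b in BASES) for s in seqs)
    return at / n


def _dinuc_transitions(m, genome, convention: str):
    """Dinucleotide transitions induced by one point mutation (1 or 2)."""
    seq = genome[m.contig]
    p = m.position
    out = []
    if p - 1 >= 0:
        out.append((seq[p - 1] + m.ancestral, seq[p - 1] + m.derived))
    if convention == "both" and p + 1 < len(seq):
        out.append((m.ancestral + seq[p + 1], m.derived + seq[p + 1]))
    return out


def rates_from_catalog(
    catalog, genome: dict[str, str], region=None, granularity: str = "mono",
    dinuc_convention: str = "both",
):
    """Flux matrix (counts per ancestral occurrence) from a mutation catalog.

    ``granularity='dinuc'`` counts each point mutation as the dinucleotide
    transitions it induces -- both overlapping dinucleotides by default, or
    only the left one under ``dinuc_convention='left_only'`` -- each
    normalized by its own ancestral dinucleotide occurrence.
    """
    seqs = _region_seq(genome, region)
    if granularity == "mono":
        occ = {b: sum(s.count(b) for s in seqs) for b in BASES}
        counts: dict[tuple[str, str], int] = {}
        for m in catalog:
            if not _in_region(region, m.contig, m.position):
                continue
            counts[(m.ancestral, m.derived)] = counts.get((m.ancestral, m.derived), 0) + 1
        rates = {}
        for (a, d), c in counts.items():
            if occ[a] == 0:
                raise ValueError(f"observed flux from {a} but no occurrence in region")
            rates[(a, d)] = c / occ[a]
        return MonoRateMatrix(rates)
    if granularity != "dinuc":
        raise ValueError("granularity must be 'mono' or 'dinuc'")
    occ = {d: 0 for d in DINUCS}
    for s in seqs:
        for i in range(len(s) - 1):
            d = s[i : i + 2]
            if d in occ:
                occ[d] += 1
    counts = {}
    for m in catalog:
        if not _in_region(region, m.contig, m.position):
            continue
        for a, d in _dinuc_transitions(m, genome, dinuc_convention):
            counts[(a, d)] = counts.get((a, d), 0) + 1
    rates = {}
    for (a, d), c in counts.items():
        if occ[a] == 0:
            raise ValueError(f"observed flux from {a} but no occurrence in region")
        rates[(a, d)] = c / occ[a]
    return DinucRateMatrix(rates)


# ---------------------------------------------------------------------------
# bootstrap


def _simple_counts(catalog, region):
    at2gc = gc2at = 0
    keys = []
    for m in catalog:
        if not _in_region(region, m.contig, m.position):
            continue
        if m.ancestral in "AT" and m.derived in "GC":
            keys.append(0)
            at2gc += 1
        elif m.ancestral in "GC" and m.derived in "AT":
            keys.append(1)
            gc2at += 1
        else:
            keys.append(2)
    return keys, at2gc, gc2at


def bootstrap_at_star(
    catalog, genome: dict[str, str], region=None, method: str = "mono",
    n_boot: int = 1000, seed: int | None = None, dinuc_convention: str = "both",
    region_label: str = "genomic",
) -> EquilibriumEstimate:
    """Point estimate of AT* with percentile bootstrap over mutation records.

    Records are resampled with replacement at the original catalog size.
    Since every estimator depends on the catalog only through per-class
    counts (occurrences are fixed by the reference), resampling is collapsed
    to a multinomial draw over classes. Replicates where the solver fails
    are dropped; the estimate is flagged when more than 5% fail.
    """
    catalog = [m for m in catalog if _in_region(region, m.contig, m.position)]
    if not catalog:
        raise ValueError("no mutations in region")
    rng = np.random.default_rng(seed)

    if method == "simple":
        genomic_at = region_at_fraction(genome, region)
        _, at2gc, gc2at = _simple_counts(catalog, None)
        point = at_star_simple(at2gc, gc2at, genomic_at)
        classes = [("AT2GC",), ("GC2AT",), ("other",)]
        counts = np.array(
            [at2gc, gc2at, len(catalog) - at2gc - gc2at], dtype=float
        )

        def estimate(c):
            return at_star_simple(int(c[0]), int(c[1]), genomic_at)

    elif method == "mono":
        occ = {b: sum(s.count(b) for s in _region_seq(genome, region)) for b in BASES}
        keymap: dict[tuple[str, str], int] = {}
        key_idx = []
        for m in catalog:
            k = (m.ancestral, m.derived)
            key_idx.append(keymap.setdefault(k, len(keymap)))
        classes = list(keymap)
        counts = np.bincount(key_idx, minlength=len(classes)).astype(float)

        def estimate(c):
            rates = {k: c[i] / occ[k[0]] for i, k in enumerate(classes) if c[i] > 0}
            return at_star_mono(MonoRateMatrix(rates))

        point = estimate(counts)

    elif method == "dinuc":
        seqs = _region_seq(genome, region)
        # str.count misses overlapping pairs like "AA" in "AAA"; count manually
        occ = {d: 0 for d in DINUCS}
        for s in seqs:
            for i in range(len(s) - 1):
                dd = s[i : i + 2]
                if dd in occ:
                    occ[dd] += 1
        keymap = {}
        key_idx = []
        for m in catalog:
            k = tuple(_dinuc_transitions(m, genome, dinuc_convention))
            key_idx.append(keymap.setdefault(k, len(keymap)))
        classes = list(keymap)
        counts = np.bincount(key_idx, minlength=len(classes)).astype(float)

        def estimate(c):
            rates: dict[tuple[str, str], float] = {}
            for i, trans in enumerate(classes):
                if c[i] == 0:
                    continue
                for a, d in trans:
                    rates[(a, d)] = rates.get((a, d), 0.0) + c[i] / occ[a]
            return stationary_dinuc(DinucRateMatrix(rates))[1]

        point = estimate(counts)
    else:
        raise ValueError("method must be 'simple', 'mono' or 'dinuc'")

    n = int(counts.sum())
    boots = []
    failures = 0
    p = counts / counts.sum()
    for _ in range(n_boot):
        c = rng.multinomial(n, p)
        try:
            boots.append(estimate(c))
        except (ValueError, ZeroDivisionError):
            failures += 1
    frac_fail = failures / n_boot if n_boot else 0.0
    arr = np.asarray(boots, dtype=float)
    return EquilibriumEstimate(
        at_star=float(point),
        method=method,
        region=region_label,
        boot_mean=float(arr.mean()) if arr.size else math.nan,
        boot_sd=float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
        ci_low=float(np.percentile(arr, 2.5)) if arr.size else math.nan,
        ci_high=float(np.percentile(arr, 97.5)) if arr.size else math.nan,
        n_boot=len(boots),
        seed=seed,
        failed_fraction=frac_fail,
        flagged=frac_fail > 0.05,
    )
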