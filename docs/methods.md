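# Methods

`fpm` implements the analysis chain used to ask whether the depressed
synonymous substitution rate (Ks) at bacterial gene 5′ ends reflects
purifying selection on synonymous sites or simply a locally depressed
mutation rate. This note documents the models, conventions, numerical
choices and limitations; nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and numbering conventions

* Genomic intervals are 0-based half-open internally; GFF3 (1-based
  inclusive) is converted at the I/O boundary only.
* The start codon is codon 1. "The first 10 codons" therefore means codons
  2–11, and the 5′ region used for equilibrium estimation is codons 2–21
  (first 20 codons after the start).
* Mutation positions are 0-based internally, 1-based in TSV files, and the
  ancestral base must equal the reference base — a mismatch is a hard
  error, not a warning.
* Mutation windows tile codons from codon 2 onward; the start codon sits in
  no window, and all window totals (bp and mutation counts) are taken over
  codons ≥ 2 so that window bp sums to the tiled CDS length exactly.

## CDS validation

A CDS is valid iff it (a) begins with a table-11 initiator
({ATG, GTG, TTG, CTG, ATT, ATC, ATA}), (b) ends with TAA/TAG/TGA, (c) has
length a multiple of 3, (d) contains only A/C/G/T, and (e) has no internal
stop. All violated checks are reported, not just the first. 5′ overlap of a
gene is the longest contiguous run of its 5′-most bases genomically covered
by any other CDS, regardless of the other gene's strand.

## Composition profiles

Profiles average an indicator per codon position across genes; the SEM is
across genes, so positions reached by fewer genes carry wider errors.
"4-fold degenerate sites" means third sites of codons whose third base is
fully degenerate — the Ala/Gly/Pro/Thr/Val families plus the 4-fold
sub-blocks of Leu (CTN), Arg (CGN) and Ser (TCN); the 2-fold halves of
6-fold amino acids are excluded, consistent with the D-statistic blocks.
Region summaries report AT3 over *all* third sites; the 4-fold-restricted
variant is available separately (`fourfold_content_by_position`) since the
two differ (Met and Trp dilute the all-sites figure). Amino-acid property
profiles compare the observed frequency-weighted property per position with
the expectation under codon probabilities formed as products of positional
mononucleotide probabilities estimated from 4-fold third sites, stops
excluded and renormalized.

## Optimal-codon usage deviation (D)

For each synonymous block with a nominated optimal codon, with `O_d`
optimal and `T_d` qualifying codons of degeneracy `d`,

    D_d = (O_d − T_d/d) / (T_d/d),
    D   = Σ_d D_d·T_d / Σ_d T_d  (classes with T_d > 0).

D is 0 under proportional use, −1 when the optimal codon is never used, and
insensitive to codons outside the table. Per-block positional trends use an
ordinary least-squares slope of relative usage (optimal/qualifying) against
codon position, with significance from the Pearson correlation p of the
same points; the 5′ window is codons 2–11. The shipped optimal-codon tables
are **synthetic stand-ins**: the published nominations are not reprinted in
the source material, so the tables reproduce only the published block
structure (E. coli: 17 blocks, 4 A/T-ending optimal; B. subtilis: 14
blocks, 4 G/C-ending). Real analyses should supply the genuine table as
YAML.

## Substitution rates

Ancestral codons are inferred by 2-of-3 parsimony on (focal, sister,
outgroup) columns: the majority codon wins; columns where all three differ
are excluded (ancestor ambiguous), as are columns with gaps or ambiguity
codes. This replaces likelihood reconstruction deliberately: at the
divergences targeted ("sweet spot" species trios) the two agree except at
exactly the columns excluded anyway.

Rates use Nei–Gojobori (1986) counting: synonymous site counts per codon
(changes creating stops count as non-synonymous sites), differences
averaged with equal weight over minimal mutational pathways excluding paths
through stop codons (all-blocked pathways fall back to the unrestricted
average), and the Jukes–Cantor correction K = −(3/4)·ln(1 − 4p/3), which is
undefined (flagged as saturated) at p ≥ 3/4. Absolute values are therefore
not comparable to codon-model ML estimates; only the positional *shape* is
interpreted, and acceptance is via recovery of a generator-defined ramp.
Codon position is assigned by alignment column; an option deletes
focal-lineage indel columns first (the two differ negligibly at the ≤ 0.2%
indel rates simulated). Orthologs shorter than 180 codons (ungapped focal)
are excluded to avoid 3′ effects; the profile spans positions 2–151.

## Mutation-catalog statistics

Window density is pooled mutations per pooled bp (per kb) per fixed-size
codon window (default 10 codons = 30 bp); deviation is (O − E)/E with
E proportional to the window's bp share, which cancels catalog size.
Mutations inside overlapping genes count once in each containing gene's
frame, each gene contributing its own bp denominator. Trinucleotide
mutability is central-base mutations per sliding occurrence of the
ancestral trinucleotide, on the reference strand as given — no
reverse-complement collapsing, since strand ambiguity is deferred to the
equilibrium stage where only A+T aggregates are reported. Expected
positional rates multiply per-position context occurrences by the genomic
context mutabilities; the 4-fold mode restricts to trinucleotides whose
central base is a 4-fold third site. Genic/intergenic classification treats
every annotated feature (CDS, gene, *RNA — including pseudo-genes) as
genic; the intergenic set is the complement of their union.

## Equilibrium AT (AT*)

* Simple method: r1 = n(G/C→A/T)/(1 − AT_genomic), r2 = n(A/T→G/C)/AT_genomic,
  AT* = r1/(r1 + r2).
* 4-state: the balance equations f_N·(total outflux of N) = Σ_M f_M·rate(M→N)
  with Σf = 1 substituted for one equation, solved directly
  (`numpy.linalg.solve`); a power-iteration solver exists only as a test
  oracle. Singular systems (absorbing or unreachable states) raise.
* 16-state: the same balance on dinucleotide states. A point mutation at
  position i updates both the (i−1,i) and (i,i+1) dinucleotides (default)
  or only the left one under the `left_only` flag; contig-edge mutations
  contribute their single existing neighbour. Each transition is normalized
  by its own ancestral dinucleotide occurrence. AT* is the stationary
  frequency weighted by each dinucleotide's A/T base share. Note the
  dinucleotide "chain" is a mean-field summary (the two updates of one
  mutation are not independent); it is used exactly as in the source
  analysis, not as a generative sequence model.

Bootstraps resample mutation records with replacement at the original
catalog size (1,000 replicates, percentile 95% CI). Since every estimator
depends on the catalog only through per-class counts, resampling is
implemented as a multinomial draw over classes — exactly equivalent and
orders of magnitude faster. Replicates whose solver fails are dropped; more
than 5% failures flags the estimate. All randomness flows from a single
seed recorded in the output.

## Bespoke tests

The exact binomial sign test doubles the smaller tail of the exact pmf
(capped at 1); at p0 = 0.5 this coincides with the minimum-likelihood
convention. The implied p for 16 successes of 17 is 0.00027466 — printed
reports round this to 0.00028, and tests compare at one unit in the last
printed digit. The two-cell goodness of fit is
χ² = (O−E)²/E + (O−E)²/(T−E), df = 1, no continuity correction (the
published statistic is only reproduced without it; the printed inputs give
16.580 against a printed 16.583, matched at |Δ| ≤ 0.01). Z-normalization
uses the sample SD (ddof = 1).

## The synthetic world

Generator defaults state the emulated conditions:

| parameter | default | meaning |
|---|---|---|
| `at5` | 0.62 | third-site AT, codons 2–11 (the reported 5′ AT3 maximum) |
| `at_core` | 0.46 | gene-body third-site AT |
| `ramp_end_codon` | 15 | composition reaches the core value here |
| `syn_prob` | 0.15 | synonymous substitution probability per codon per branch |
| `outgroup_factor` | 2.0 | outgroup branch length multiple |
| `gene_length_codons` | (180, 320) | uniform length range, satisfying the ≥180-codon filter |
| `n_mutations` | 50,000 | catalog size (the scale of the MA + MMR-deficient catalogs) |

Amino acids are drawn uniformly (optionally hydrophilic-enriched at the 5′
end), independently of the nucleotide targets, so second-site composition
is controlled separately from third-site AT. The third-site AT target is
enforced wherever a synonymous ending choice exists; Met and Trp have fixed
G-ending codons, so the *all-sites* AT3 of generated genes is 0.9× the
4-fold target under the uniform amino-acid draw (e.g. 0.56 when the 4-fold
target is 0.62) — tests against the all-sites summary use this dilution-
corrected truth, while 4-fold profiles hit the target exactly. Divergence
is simulated as single-base synonymous codon swaps (optionally plus
non-synonymous changes), never creating stops, so synonymous-only mode has
Ka = 0 by construction. Toy genomes embed genes on both strands with
random-composition spacers and optional engineered 3-bp 5′ overlaps; in an
overlap the later gene's 5′ bases overwrite the earlier gene's 3′ tail in
the genome (the overlap fixtures exercise interval geometry, not dual-frame
coding, and consistency tests use overlap-free fixtures). Mutation
matrices with a prescribed stationary AT are built reversibly
(rate(N→M) = s_NM·π_M with symmetric s), making the stationary distribution
exact by detailed balance.

What a green synthetic test does *not* establish: realism of bacterial gene
content, selection, demography, sequencing error, rate heterogeneity beyond
the stated multipliers, or agreement with any genome-scale published value
that depends on real data.

## Known limitations

* NG86 + Jukes–Cantor ignores transition/transversion and codon-frequency
  biases; saturated pools (p ≥ 3/4) return NaN rather than a rate.
* The parsimony ancestor is biased toward the majority codon; at high
  divergence this underestimates change on the focal branch.
* mRNA-stability scanning is out of scope; profiles accept externally
  computed per-window score tables only.
* The 6-fold Ser block's 2-fold half (AGT/AGC) never counts as 4-fold
  degenerate; one published block nomination ("serine's TGC") is
  internally inconsistent in the source and is not resolved here.
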