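# SYNTHETIC example optimal-codon table, E. coli-like.
# 17 synonymous blocks with a nominated optimal codon, of which 4 are
# A/T-ending, matching the published block tallies for E. coli; the
# individual nominations are illustrative stand-ins, not the published list.
blocks:
  - {block_id: Phe, codons: [TTT, TTC], optimal: TTC, degeneracy: 2}
  - {block_id: Tyr, codons: [TAT, TAC], optimal: TAC, degeneracy: 2}
  - {block_id: His, codons: [CAT, CAC], optimal: CAC, degeneracy: 2}
  - {block_id: Asn, codons: [AAT, AAC], optimal: AAC, degeneracy: 2}
  - {block_id: Asp, codons: [GAT, GAC], optimal: GAC, degeneracy: 2}
  - {block_id: Cys, codons: [TGT, TGC], optimal: TGC, degeneracy: 2}
  - {block_id: Gln, codons: [CAA, CAG], optimal: CAG, degeneracy: 2}
  - {block_id: Lys, codons: [AAA, AAG], optimal: AAA, degeneracy: 2}
  - {block_id: Glu, codons: [GAA, GAG], optimal: GAA, degeneracy: 2}
  - {block_id: Ile, codons: [ATT, ATC, ATA], optimal: ATC, degeneracy: 3}
  - {block_id: Val, codons: [GTT, GTC, GTA, GTG], optimal: GTT, degeneracy: 4}
  - {block_id: Ala, codons: [GCT, GCC, GCA, GCG], optimal: GCG, degeneracy: 4}
  - {block_id: Gly, codons: [GGT, GGC, GGA, GGG], optimal: GGT, degeneracy: 4}
  - {block_id: Pro, codons: [CCT, CCC, CCA, CCG], optimal: CCG, degeneracy: 4}
  - {block_id: Thr, codons: [ACT, ACC, ACA, ACG], optimal: ACC, degeneracy: 4}
  - {block_id: Leu4, codons: [CTT, CTC, CTA, CTG], optimal: CTG, degeneracy: 4}
  - {block_id: Arg4, codons: [CGT, CGC, CGA, CGG], optimal: CGC, degeneracy: 4}
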