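# SYNTHETIC example optimal-codon table, B. subtilis-like.
# 14 synonymous blocks (2- and 4-fold only) with a nominated optimal codon,
# of which 4 are G/C-ending, matching the published block tallies for
# B. subtilis; the individual nominations are illustrative stand-ins.
blocks:
  - {block_id: Phe, codons: [TTT, TTC], optimal: TTT, degeneracy: 2}
  - {block_id: Tyr, codons: [TAT, TAC], optimal: TAT, degeneracy: 2}
  - {block_id: His, codons: [CAT, CAC], optimal: CAT, degeneracy: 2}
  - {block_id: Lys, codons: [AAA, AAG], optimal: AAA, degeneracy: 2}
  - {block_id: Glu, codons: [GAA, GAG], optimal: GAA, degeneracy: 2}
  - {block_id: Gln, codons: [CAA, CAG], optimal: CAA, degeneracy: 2}
  - {block_id: Asp, codons: [GAT, GAC], optimal: GAT, degeneracy: 2}
  - {block_id: Asn, codons: [AAT, AAC], optimal: AAC, degeneracy: 2}
  - {block_id: Cys, codons: [TGT, TGC], optimal: TGC, degeneracy: 2}
  - {block_id: Val, codons: [GTT, GTC, GTA, GTG], optimal: GTA, degeneracy: 4}
  - {block_id: Ala, codons: [GCT, GCC, GCA, GCG], optimal: GCA, degeneracy: 4}
  - {block_id: Thr, codons: [ACT, ACC, ACA, ACG], optimal: ACA, degeneracy: 4}
  - {block_id: Pro, codons: [CCT, CCC, CCA, CCG], optimal: CCG, degeneracy: 4}
  - {block_id: Gly, codons: [GGT, GGC, GGA, GGG], optimal: GGC, degeneracy: 4}
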