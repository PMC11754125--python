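# SpCas9 sgRNA scaffold sequences (RNA, 5'->3', everything 3' of the spacer).
#
# "standard" is the canonical published SpCas9 sgRNA scaffold.
# "optimized" is CONSTRUCTED BY RULE from the standard scaffold: the
# repeat:antirepeat duplex is extended by a 5-bp complementary insertion
# (UGCUG / CAGCA) flanking the GAAA tetraloop, and the continuous run of
# four uracils in the repeat is interrupted by a single U->C substitution
# at the run's central position (see grammar.fix_poly_u).  It is a
# documented synthetic fallback for the published optimized backbone, which
# this package does not ship verbatim.
#
# Annotation intervals are 1-based and closed.
version: 1
scaffolds:
  standard:
    sequence: GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC
    annotations:
      repeat: [1, 12]
      tetraloop: [13, 16]
      antirepeat: [17, 30]
      stem_loop_1: [1, 30]
      repeat_antirepeat_duplex: [1, 30]
      stem_loop_2: [31, 48]
      stem_loop_3: [49, 76]
  optimized:
    sequence: GUUCUAGAGCUAUGCUGGAAACAGCAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGC
    annotations:
      repeat: [1, 17]
      tetraloop: [18, 21]
      antirepeat: [22, 40]
      stem_loop_1: [1, 40]
      repeat_antirepeat_duplex: [1, 40]
      stem_loop_2: [41, 58]
      stem_loop_3: [59, 86]
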