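# Four-tester panels derived from the dikaryotic isolates.
# Tester order is the conventional meiotic layout: AxBx, AxBy, AyBx, AyBy.
# M-38 is the reference (collection) strain; the others are natural isolates.
# Genotype labels follow the mutual mon-mon crossing table (post-deduction:
# the M-13 panel shares its matB alleles B3/B4 with the M-8 panel).
reference: M-38
panels:
  - isolate: M-38
    testers: [M-38.m1, M-38.m2, M-38.m3, M-38.m4]
    genotypes: [A1B1, A1B2, A2B1, A2B2]
  - isolate: M-8
    testers: [M-8.m1, M-8.m2, M-8.m3, M-8.m4]
    genotypes: [A3B3, A3B4, A4B3, A4B4]
  - isolate: M-9
    testers: [M-9.m1, M-9.m2, M-9.m3, M-9.m4]
    genotypes: [A5B5, A5B6, A6B5, A6B6]
  - isolate: M-13
    testers: [M-13.m1, M-13.m2, M-13.m3, M-13.m4]
    genotypes: [A7B3, A7B4, A8B3, A8B4]
  - isolate: M-14
    testers: [M-14.m1, M-14.m2, M-14.m3, M-14.m4]
    genotypes: [A9B9, A9B10, A10B9, A10B10]
  - isolate: M-17
    testers: [M-17.m1, M-17.m2, M-17.m3, M-17.m4]
    genotypes: [A11B11, A11B12, A12B11, A12B12]
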