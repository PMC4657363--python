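name: LHON-MaeIII
enzyme:
  name: MaeIII
  recognition: GTNAC
  cut_offset_top: 0
  cut_offset_bottom: 0
size_tolerance: 3
targets:
- name: G3460A
  position: 3460
  ref: G
  alt: A
  fwd: CCCCTACGGGCTACTACAACCCTTCGCTGtC
  rev: GATAGTAGAATGATGGCTAG
  product_size: 333
- name: G11778A
  position: 11778
  ref: G
  alt: A
  fwd: AGCAAACTCAAACTACGAACG
  rev: TTACTAGCACAGAGAGTTCTC
  product_size: 164
- name: T14484C
  position: 14484
  ref: T
  alt: C
  fwd: AATAGCCATCGCTGTAGTATATCCAAAGACAgtCA
  rev: GTGCGAGAATAATGATGTATGC
  product_size: 236
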