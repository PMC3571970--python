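# Consensus binding-site motifs (IUPAC) for the nucleoid-associated
# proteins retained in reduced enterobacterial genomes, and the two-box
# sigma-32 promoter model.
motifs:
  FIS: GNTYAWWWWWTRANC
  IHF: WATCAANNNNTTR
  H-NS: TCGWTWAAWW
sigma32:
  box1: CTTGAAAA
  box2: CCCCTNT
  spacer_min: 11
  spacer_max: 15
  min_similarity: 0.5
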