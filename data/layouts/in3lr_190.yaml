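# In(3LR)190 heterokaryotype: marker map with breakpoint/centromere placements
# lengths_cM are fitted H1 heterokaryotype map estimates
marker_names:
- ve
- h
- th
- cu
- bx
- e
- ro
- ca
karyotype: hetero
left_breakpoint:
  interval: 1
  fraction: 0.5
centromere:
  interval: 2
  fraction: 0.5
right_breakpoint:
  interval: 3
  fraction: 0.5
lengths_cM:
- 16.2
- 21.4
- 1.0
- 0.7
- 21.5
- 21.0
- 11.3
homokaryotype_lengths_cM:
- 27.6
- 18.4
- 4.5
- 9.0
- 15.8
- 23.0
- 11.4
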