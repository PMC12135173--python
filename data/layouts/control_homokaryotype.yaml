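marker_names:
- ve
- h
- th
- cu
- bx
- e
- ro
- ca
karyotype: homo
lengths_cM:
- 27.6
- 18.4
- 4.5
- 9.0
- 15.8
- 23.0
- 11.4
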