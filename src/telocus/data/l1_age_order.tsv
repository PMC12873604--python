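# L1 subfamily chronology, youngest first (rank 0 = human-specific L1HS)
L1HS	0
L1PA2	1
L1PA3	2
L1PA4	3
L1PA5	4
L1PA6	5
L1PA7	6
L1PA8	7
L1PA10	8
L1PA11	9
L1PA12	10
L1PA13	11
L1PA14	12
L1PA15	13
L1PA16	14
L1PA17	15
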