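subfamily	active
L1Hs	True
L1PA2	False
L1PA3	False
L1PA4	False
L1PA5	False
L1PA6	False
L1PA7	False
L1PA8	False
L1PA9	False
L1PA10	False
L1PA11	False
L1PA12	False
L1PA13	False
L1PA14	False
L1PA15	False
L1PA16	False
L1PA17	False
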