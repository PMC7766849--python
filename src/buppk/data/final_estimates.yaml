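KA: 2.54
K12: 2.34
K14: 1.29
K23: 0.0643
K24: 0.128
K26: 0.218
K62: 0.041
K35: 0.123
K45: 0.873
K30: 0.00381
K50: 0.127
V2: 861
V3: 702
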