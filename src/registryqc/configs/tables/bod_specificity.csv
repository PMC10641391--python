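morpho
8070
8090
8120
8260
8312
8330
8441
8500
8520
9061
9064
9440
9510
9680
9732
9823
9861
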