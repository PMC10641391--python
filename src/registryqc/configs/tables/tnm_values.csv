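axis;value
T;0
T;1
T;1a
T;1b
T;1c
T;2
T;2a
T;2b
T;3
T;3a
T;3b
T;4
T;4a
T;4b
T;X
T;is
N;0
N;1
N;1a
N;1b
N;1biv
N;1c
N;2
N;2a
N;2b
N;3
N;3a
N;X
M;0
M;1
M;1a
M;1b
M;X
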