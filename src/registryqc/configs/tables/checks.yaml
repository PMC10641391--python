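non_microscopic_bod:
- '0'
- '1'
- '2'
- '4'
mpt_behaviour_floor: 3
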