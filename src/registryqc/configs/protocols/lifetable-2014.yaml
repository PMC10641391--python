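id: lifetable-2014
file_kind: lifetable
version: 2014
delimiter: ;
has_header: true
variables:
- name: Year
  datatype: count
  allowed:
    range:
    - 1900
    - 2035
  required: true
  position: 1
- name: Sex
  datatype: integer-code
  allowed:
    set:
    - '1'
    - '2'
    - '3'
    - '9'
  missing:
  - '9'
  required: true
  position: 2
- name: Age
  datatype: count
  allowed:
    range:
    - 0
    - 125
  required: true
  position: 3
- name: DeathProb
  datatype: probability
  allowed:
    range:
    - 0.0
    - 1.0
  required: true
  position: 4
rules: []
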