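id: population-2020-age-range
file_kind: population
version: 2020
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
- name: AgeGroup
  datatype: text-code
  allowed:
    pattern: ^[0-9]{1,3}-[0-9]{1,3}$|^85\+$
  required: true
  position: 3
- name: GeoCode
  datatype: text-code
  allowed:
    pattern: ^[A-Z0-9]{1,12}$
  required: true
  position: 4
- name: GeoLabel
  datatype: text-code
  allowed:
    pattern: ^.{1,60}$
  required: true
  position: 5
- name: Residents
  datatype: count
  allowed:
    range:
    - 0
    - 100000000
  required: true
  position: 6
rules: []
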