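id: incidence-2020
file_kind: incidence
version: 2020
delimiter: ;
has_header: true
variables:
- name: Pat
  datatype: text-code
  allowed:
    pattern: ^[A-Za-z0-9_-]{1,24}$
  required: true
  position: 1
- name: Tum
  datatype: text-code
  allowed:
    pattern: ^[A-Za-z0-9_-]{1,24}$
  required: true
  position: 2
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
  position: 3
- name: DoB
  datatype: date
  required: true
  position: 4
- name: DoI
  datatype: date
  required: true
  position: 5
- name: YoI
  datatype: count
  allowed:
    range:
    - 1900
    - 2035
  required: true
  position: 6
- name: Age
  datatype: count
  allowed:
    range:
    - 0
    - 125
  required: false
  position: 7
- name: BoD
  datatype: integer-code
  allowed:
    set:
    - '0'
    - '1'
    - '2'
    - '4'
    - '5'
    - '6'
    - '7'
    - '9'
  missing:
  - '9'
  required: true
  position: 8
- name: Topo
  datatype: text-code
  allowed:
    table: topo
  required: true
  position: 9
- name: Morpho
  datatype: text-code
  allowed:
    table: morpho
  required: true
  position: 10
- name: Beh
  datatype: integer-code
  allowed:
    set:
    - '0'
    - '1'
    - '2'
    - '3'
  required: true
  position: 11
- name: Grade
  datatype: integer-code
  allowed:
    set:
    - '1'
    - '2'
    - '3'
    - '4'
    - '9'
  missing:
  - '9'
  required: false
  position: 12
- name: Stage
  datatype: text-code
  allowed:
    set:
    - '0'
    - I
    - IA
    - IB
    - II
    - IIA
    - IIB
    - III
    - IIIA
    - IIIB
    - IIIC
    - IV
    - IVA
    - IVB
    - X
    - '9'
  missing:
  - X
  - '9'
  required: true
  position: 13
- name: TNMEdition
  datatype: integer-code
  allowed:
    set:
    - '5'
    - '6'
    - '7'
    - '8'
    - '9'
  missing:
  - '9'
  required: false
  position: 14
- name: cT
  datatype: text-code
  allowed:
    table: tnm_T
  required: false
  position: 15
- name: cN
  datatype: text-code
  allowed:
    table: tnm_N
  required: false
  position: 16
- name: cM
  datatype: text-code
  allowed:
    table: tnm_M
  required: false
  position: 17
- name: pT
  datatype: text-code
  allowed:
    table: tnm_T
  required: false
  position: 18
- name: pN
  datatype: text-code
  allowed:
    table: tnm_N
  required: false
  position: 19
- name: pM
  datatype: text-code
  allowed:
    table: tnm_M
  required: false
  position: 20
- name: VitalStatus
  datatype: integer-code
  allowed:
    set:
    - '1'
    - '2'
    - '9'
  missing:
  - '9'
  required: false
  position: 21
- name: DoF
  datatype: date
  required: false
  position: 22
- name: GeoCode
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 23
- name: Laterality
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 24
- name: ICD10
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 25
- name: SurgeryFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 26
- name: RadiotherapyFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 27
- name: ChemotherapyFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 28
- name: ImmunotherapyFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 29
- name: HormoneTherapyFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 30
- name: TargetedTherapyFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 31
- name: OtherTreatmentFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 32
- name: TreatmentStart
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 33
- name: AutopsyFlag
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 34
- name: MetsAtDiagnosis
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 35
- name: TumourSize
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 36
- name: NodesExamined
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 37
- name: NodesPositive
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 38
- name: Comments
  datatype: text-code
  allowed:
    pattern: ^.{0,60}$
  required: false
  position: 39
rules:
- MPT
acceptance_criteria:
  MPT:
  - - Pat
    - E-MISS
  - - Pat
    - E-FORM
  - - Tum
    - E-MISS
  - - Tum
    - E-FORM
  - - YoI
    - E-MISS
  - - YoI
    - E-FORM
  - - YoI
    - E-OUTR
  - - DoI
    - E-MISS
  - - DoI
    - E-FORM
  - - Topo
    - E-MISS
  - - Topo
    - E-FORM
  - - Topo
    - E-OUTR
  - - Morpho
    - E-MISS
  - - Morpho
    - E-FORM
  - - Morpho
    - E-OUTR
  - - Beh
    - E-MISS
  - - Beh
    - E-FORM
  - - Beh
    - E-OUTR
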