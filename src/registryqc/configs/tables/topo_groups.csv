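code;group_id
C07;SALIVARY
C16;STOMACH
C18;COLORECTAL
C19;COLORECTAL
C20;COLORECTAL
C32;LARYNX
C34;LUNG
C42;HAEMATOPOIETIC
C44;SKIN
C50;BREAST
C53;CERVIX
C56;OVARY
C61;PROSTATE
C62;TESTIS
C64;KIDNEY
C67;BLADDER
C69;EYE
C71;BRAIN
C73;THYROID
C77;LYMPH_NODES
C80;UNKNOWN_PRIMARY
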