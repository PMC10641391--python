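code;family_id
8000;NOS
8010;CARCINOMA_NOS
8041;SMALL_CELL
8070;SQUAMOUS
8077;SQUAMOUS
8090;BASAL
8120;TRANSITIONAL
8140;ADENO
8260;ADENO
8312;RENAL_CELL
8330;ADENO
8441;ADENO
8500;ADENO
8520;ADENO
8720;MELANOMA
9061;GERM_CELL
9064;GERM_CELL
9380;GLIOMA
9440;GLIOMA
9510;RETINOBLASTOMA
9590;LYMPHOMA
9650;LYMPHOMA
9680;LYMPHOMA
9732;PLASMA_CELL
9823;LEUK_LYMPHOID
9861;LEUK_MYELOID
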