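edition;site_group;T;N;M;stage
7;BREAST;1;0;0;IA
7;BREAST;0;1;0;IIA
7;BREAST;1;1;0;IIA
7;BREAST;2;0;0;IIA
7;BREAST;2;1;0;IIB
7;BREAST;3;0;0;IIB
7;BREAST;0;2;0;IIIA
7;BREAST;1;2;0;IIIA
7;BREAST;2;2;0;IIIA
7;BREAST;3;1;0;IIIA
7;BREAST;3;2;0;IIIA
7;BREAST;4;0;0;IIIB
7;BREAST;4;1;0;IIIB
7;BREAST;4;2;0;IIIB
7;BREAST;*;3;0;IIIC
7;BREAST;*;*;1;IV
7;COLORECTAL;1;0;0;I
7;COLORECTAL;2;0;0;I
7;COLORECTAL;3;0;0;IIA
7;COLORECTAL;4;0;0;IIB
7;COLORECTAL;*;1;0;IIIB
7;COLORECTAL;*;2;0;IIIC
7;COLORECTAL;*;*;1;IV
7;LUNG;1;0;0;IA
7;LUNG;2;0;0;IB
7;LUNG;1;1;0;IIA
7;LUNG;2;1;0;IIB
7;LUNG;3;0;0;IIB
7;LUNG;3;1;0;IIIA
7;LUNG;4;0;0;IIIA
7;LUNG;4;1;0;IIIA
7;LUNG;*;2;0;IIIA
7;LUNG;*;3;0;IIIB
7;LUNG;*;*;1;IV
7;PROSTATE;1;0;0;I
7;PROSTATE;2;0;0;II
7;PROSTATE;3;0;0;III
7;PROSTATE;4;0;0;IV
7;PROSTATE;*;1;0;IV
7;PROSTATE;*;*;1;IV
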