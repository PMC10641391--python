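code;behaviours;label
8000;0,1,2,3;Neoplasm NOS
8010;2,3;Carcinoma NOS
8041;3;Small cell carcinoma NOS
8070;2,3;Squamous cell carcinoma NOS
8077;2;Squamous intraepithelial neoplasia
8090;3;Basal cell carcinoma NOS
8120;2,3;Transitional cell carcinoma NOS
8140;2,3;Adenocarcinoma NOS
8260;3;Papillary adenocarcinoma NOS
8312;3;Renal cell carcinoma NOS
8330;3;Follicular adenocarcinoma NOS
8441;2,3;Serous carcinoma NOS
8500;2,3;Infiltrating duct carcinoma NOS
8520;2,3;Lobular carcinoma NOS
8720;0,2,3;Malignant melanoma NOS
9061;3;Seminoma NOS
9064;3;Germinoma
9380;3;Glioma NOS
9440;3;Glioblastoma NOS
9510;3;Retinoblastoma NOS
9590;3;Malignant lymphoma NOS
9650;3;Hodgkin lymphoma NOS
9680;3;Diffuse large B-cell lymphoma NOS
9732;3;Multiple myeloma
9823;3;Chronic lymphocytic leukaemia
9861;3;Acute myeloid leukaemia NOS
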