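code;label
C079;Parotid gland
C160;Cardia
C161;Fundus of stomach
C169;Stomach NOS
C180;Cecum
C182;Ascending colon
C184;Transverse colon
C187;Sigmoid colon
C189;Colon NOS
C199;Rectosigmoid junction
C209;Rectum NOS
C320;Glottis
C329;Larynx NOS
C340;Main bronchus
C341;Upper lobe lung
C343;Lower lobe lung
C349;Lung NOS
C420;Blood
C421;Bone marrow
C424;Haematopoietic system
C440;Skin of lip
C443;Skin of face
C446;Skin of trunk
C449;Skin NOS
C500;Nipple
C502;Upper-inner breast
C504;Upper-outer breast
C508;Overlapping breast
C509;Breast NOS
C530;Endocervix
C539;Cervix uteri NOS
C569;Ovary
C619;Prostate gland
C621;Descended testis
C629;Testis NOS
C649;Kidney NOS
C670;Trigone of bladder
C679;Bladder NOS
C692;Retina
C710;Cerebrum
C719;Brain NOS
C739;Thyroid gland
C770;Head/neck lymph nodes
C778;Multi-region lymph nodes
C779;Lymph node NOS
C809;Unknown primary site
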