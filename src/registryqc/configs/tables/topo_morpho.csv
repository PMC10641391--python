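topo;morpho
C079;8000
C079;8010
C079;8140
C160;8000
C160;8010
C160;8140
C160;8260
C161;8000
C161;8010
C161;8140
C161;8260
C169;8000
C169;8010
C169;8140
C169;8260
C180;8000
C180;8010
C180;8140
C180;8260
C182;8000
C182;8010
C182;8140
C182;8260
C184;8000
C184;8010
C184;8140
C184;8260
C187;8000
C187;8010
C187;8140
C187;8260
C189;8000
C189;8010
C189;8140
C189;8260
C199;8000
C199;8010
C199;8140
C199;8260
C209;8000
C209;8010
C209;8140
C209;8260
C320;8000
C320;8010
C320;8070
C320;8077
C329;8000
C329;8010
C329;8070
C329;8077
C340;8000
C340;8010
C340;8041
C340;8070
C340;8140
C340;8260
C341;8000
C341;8010
C341;8041
C341;8070
C341;8140
C341;8260
C343;8000
C343;8010
C343;8041
C343;8070
C343;8140
C343;8260
C349;8000
C349;8010
C349;8041
C349;8070
C349;8140
C349;8260
C420;9590
C420;9680
C420;9732
C420;9823
C420;9861
C421;9590
C421;9680
C421;9732
C421;9823
C421;9861
C424;9590
C424;9680
C424;9732
C424;9823
C424;9861
C440;8000
C440;8070
C440;8090
C440;8720
C443;8000
C443;8070
C443;8090
C443;8720
C446;8000
C446;8070
C446;8090
C446;8720
C449;8000
C449;8070
C449;8090
C449;8720
C500;8000
C500;8010
C500;8140
C500;8500
C500;8520
C502;8000
C502;8010
C502;8140
C502;8500
C502;8520
C504;8000
C504;8010
C504;8140
C504;8500
C504;8520
C508;8000
C508;8010
C508;8140
C508;8500
C508;8520
C509;8000
C509;8010
C509;8140
C509;8500
C509;8520
C530;8000
C530;8010
C530;8070
C530;8077
C530;8140
C539;8000
C539;8010
C539;8070
C539;8077
C539;8140
C569;8000
C569;8010
C569;8140
C569;8441
C619;8000
C619;8010
C619;8140
C621;8000
C621;9061
C621;9064
C629;8000
C629;9061
C629;9064
C649;8000
C649;8010
C649;8312
C670;8000
C670;8010
C670;8120
C679;8000
C679;8010
C679;8120
C692;8000
C692;8720
C692;9510
C710;8000
C710;9380
C710;9440
C719;8000
C719;9380
C719;9440
C739;8000
C739;8010
C739;8140
C739;8260
C739;8330
C770;9590
C770;9650
C770;9680
C778;9590
C778;9650
C778;9680
C779;9590
C779;9650
C779;9680
C809;8000
C809;8010
C809;8041
C809;8070
C809;8140
C809;8441
C809;8500
C809;8720
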