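age_min;age_max;topo_prefixes;morpho_codes
0;14;C56,C62;8010,8041,8070,8090,8120,8140,8260,8312,8330,8441,8500,8520
15;125;C69;9510
0;34;C61;8010,8041,8070,8090,8120,8140,8260,8312,8330,8441,8500,8520
0;14;C50;8010,8041,8070,8090,8120,8140,8260,8312,8330,8441,8500,8520
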