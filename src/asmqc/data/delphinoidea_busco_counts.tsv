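species	single	duplicated	missing	fragmented
Phocoena sinus	12072	80	59	23
Lagenorhynchus cruciger	12056	96	48	34
Stenella coeruleoalba	12055	87	73	19
Delphinus delphis	12049	94	69	22
Orcinus orca	12048	129	41	16
Lagenorhynchus obliquidens	12043	112	53	26
Tursiops truncatus	12028	119	61	26
Lagenorhynchus albirostris	12013	135	55	31
Globicephala melas	12002	148	62	22
Tursiops aduncus	11969	157	67	41
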